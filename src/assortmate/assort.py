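"""Per-locus mate-assortment statistic and permutation test.

For each biallelic SNP, a mate pair's genotypes (as minor-allele dosages
d1, d2 in {0, 1, 2}) share two, one, or zero allele classes; the sharing
score is the closed form 2 - |d1 - d2|. The observed statistic is the
mean score over all pairs with both members genotyped at the locus. The
null distribution is built by re-pairing: in each replicate every female
in the pair set is assigned a male drawn uniformly at random, with
replacement, from the multiset of males appearing in the pair set, and
the replicate's mean score is recorded under the same both-genotyped
rule. The observed mean's percentile within the replicate means (mid-rank
for ties) classifies the locus: below the lower cutoff is negative
(disassortative) mating, above the upper cutoff positive (assortative).

Genotypes are held fixed throughout; only the pairing is randomized, so
the null inherits the group's allele frequencies at each SNP.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .types import (
    MISSING,
    Classification,
    GenotypeMatrix,
    Locus,
    LocusAssortResult,
    MatePairSet,
)

logger = logging.getLogger(__name__)

#: Replicate-mean null (default) or single-pair-score null.
NULL_SCHEMES = ("replicate-means", "single-pairs")

_EQ_TOL = 1e-12  # two replicate means of the same rational value may differ in the last bit


@dataclass
class AssortConfig:
    """Parameters of the permutation test.

    n_permutations defaults to 50,000 replicates; the cutoffs 0.025 / 0.975
    flag the 5% of loci deviating most strongly from random pairing (no
    multiple-testing correction — the tails are reported raw).
    """

    n_permutations: int = 50_000
    lower_cutoff: float = 0.025
    upper_cutoff: float = 0.975
    min_pairs_per_locus: int = 2
    rng_seed: int = 0
    null_scheme: str = "replicate-means"

    def __post_init__(self) -> None:
        if not 0.0 < self.lower_cutoff < self.upper_cutoff < 1.0:
            raise ValueError("need 0 < lower_cutoff < upper_cutoff < 1")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.null_scheme not in NULL_SCHEMES:
            raise ValueError(f"null_scheme must be one of {NULL_SCHEMES}")


@dataclass
class NullDistribution:
    """Monte-Carlo null for one locus."""

    locus: Optional[Locus]
    replicate_means: np.ndarray
    n_redrawn: int = 0

    @property
    def mean(self) -> float:
        return float(np.mean(self.replicate_means)) if self.replicate_means.size else float("nan")

    @property
    def sd(self) -> float:
        return float(np.std(self.replicate_means)) if self.replicate_means.size else float("nan")


# ---------------------------------------------------------------------------
# the statistic
# ---------------------------------------------------------------------------

def shared_alleles(d_female: int, d_male: int) -> int:
    """Number of allele classes (0, 1, or 2) a mate pair shares at a locus.

    Equals 2 - |d_female - d_male| for dosages in {0, 1, 2}; returns
    MISSING if either genotype is missing.
    """
    for d in (d_female, d_male):
        if d not in (0, 1, 2, MISSING):
            raise ValueError(f"dosage {d!r} outside {{0, 1, 2, MISSING}}")
    if d_female == MISSING or d_male == MISSING:
        return MISSING
    return 2 - abs(d_female - d_male)


def _locus_index(matrix: GenotypeMatrix, locus: Union[Locus, int]) -> int:
    if isinstance(locus, (int, np.integer)):
        if not 0 <= locus < matrix.n_loci:
            raise KeyError(f"locus index {locus} out of range")
        return int(locus)
    try:
        return matrix.locus_ids.index(locus)
    except ValueError:
        raise KeyError(f"locus {locus} absent from matrix") from None


def _pair_dosages(pairs: MatePairSet, matrix: GenotypeMatrix,
                  j: int) -> tuple[np.ndarray, np.ndarray]:
    idx = matrix.individual_index()
    f_idx = np.array([idx[f] for f in pairs.females()], dtype=np.intp)
    m_idx = np.array([idx[m] for m in pairs.males()], dtype=np.intp)
    return matrix.dosage[f_idx, j], matrix.dosage[m_idx, j]


def observed_mean_sharing(pairs: MatePairSet, matrix: GenotypeMatrix,
                          locus: Union[Locus, int]) -> tuple[float, int]:
    """Mean sharing score over pairs with both members genotyped at the locus.

    Returns (NaN, 0) when no pair is fully genotyped there.
    """
    j = _locus_index(matrix, locus)
    fd, md = _pair_dosages(pairs, matrix, j)
    valid = (fd != MISSING) & (md != MISSING)
    n = int(valid.sum())
    if n == 0:
        return float("nan"), 0
    scores = 2 - np.abs(fd[valid].astype(np.int32) - md[valid].astype(np.int32))
    return float(scores.mean()), n


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------

def _locus_rng(seed: int, locus_ordinal: int) -> np.random.Generator:
    # per-locus stream: results independent of locus processing order
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(locus_ordinal,)))


def _replicate_means(fd: np.ndarray, male_pool: np.ndarray, n_perm: int,
                     min_pairs: int, rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """Replicate means under random male re-assignment, with redraws for
    replicates that leave fewer than min_pairs fully genotyped slots."""
    fd = fd.astype(np.int16)
    pool = male_pool.astype(np.int16)
    f_ok = fd != MISSING
    if f_ok.sum() == 0 or (pool != MISSING).sum() == 0:
        return np.empty(0), 0

    n_pairs = fd.size

    def batch(n: int) -> tuple[np.ndarray, np.ndarray]:
        md = pool[rng.integers(0, pool.size, size=(n, n_pairs))]
        valid = f_ok[None, :] & (md != MISSING)
        sums = np.where(valid, 2 - np.abs(fd[None, :] - md), 0).sum(axis=1)
        counts = valid.sum(axis=1)
        return sums.astype(float), counts

    sums, counts = batch(n_perm)
    n_redrawn = 0
    for _ in range(1000):
        bad = counts < min_pairs
        n_bad = int(bad.sum())
        if n_bad == 0:
            break
        n_redrawn += n_bad
        sums[bad], counts[bad] = batch(n_bad)
    else:
        raise RuntimeError("could not draw enough fully genotyped re-pairings; "
                           "data too sparse at this locus")
    return sums / counts, n_redrawn


def _single_pair_scores(fd: np.ndarray, male_pool: np.ndarray, n_perm: int,
                        rng: np.random.Generator) -> np.ndarray:
    """Null of single random-pair scores (sensitivity-analysis scheme)."""
    female_pool = fd[fd != MISSING].astype(np.int16)
    mp = male_pool[male_pool != MISSING].astype(np.int16)
    if female_pool.size == 0 or mp.size == 0:
        return np.empty(0)
    f = female_pool[rng.integers(0, female_pool.size, size=n_perm)]
    m = mp[rng.integers(0, mp.size, size=n_perm)]
    return (2 - np.abs(f - m)).astype(float)


def permutation_null(pairs: MatePairSet, matrix: GenotypeMatrix,
                     locus: Union[Locus, int], config: AssortConfig) -> NullDistribution:
    """Monte-Carlo null distribution of the mean sharing score at one locus.

    Reproducible: the RNG stream is derived from (config.rng_seed, locus
    ordinal in the matrix), independent of processing order.
    """
    if len(set(pairs.males())) < 2:
        raise ValueError("permutation null needs at least 2 distinct males in the pair set")
    j = _locus_index(matrix, locus)
    fd, md_pool = _pair_dosages(pairs, matrix, j)
    rng = _locus_rng(config.rng_seed, j)
    if config.null_scheme == "single-pairs":
        means = _single_pair_scores(fd, md_pool, config.n_permutations, rng)
        n_redrawn = 0
    else:
        means, n_redrawn = _replicate_means(fd, md_pool, config.n_permutations,
                                            config.min_pairs_per_locus, rng)
    locus_obj = matrix.locus_ids[j]
    return NullDistribution(locus=locus_obj, replicate_means=means, n_redrawn=n_redrawn)


def percentile_of_observed(observed_mean: float, null: NullDistribution) -> float:
    """Mid-rank percentile of the observed mean within the null replicate means.

    (count strictly below + 0.5 x count equal) / n; ties keep a degenerate
    null at 0.5 and avoid direction bias.
    """
    vals = null.replicate_means
    if vals.size == 0:
        raise ValueError("empty null distribution")
    below = np.count_nonzero(vals < observed_mean - _EQ_TOL)
    equal = np.count_nonzero(np.abs(vals - observed_mean) <= _EQ_TOL)
    return (below + 0.5 * equal) / vals.size


def classify_locus(percentile: float, config: AssortConfig) -> Classification:
    """negative below the lower cutoff, positive above the upper, else none
    (strict inequalities: a percentile exactly at a cutoff is 'none')."""
    if not 0.0 <= percentile <= 1.0:
        raise ValueError(f"percentile {percentile} outside [0, 1]")
    if percentile < config.lower_cutoff:
        return Classification.negative
    if percentile > config.upper_cutoff:
        return Classification.positive
    return Classification.none


# ---------------------------------------------------------------------------
# per-group driver
# ---------------------------------------------------------------------------

def run_group_assortment(pairs: MatePairSet, matrix: GenotypeMatrix,
                         config: Optional[AssortConfig] = None) -> list[LocusAssortResult]:
    """Run the permutation test at every locus for one mating group.

    Loci with fewer than min_pairs_per_locus fully genotyped pairs are
    emitted with classification none and the low_pairs flag set.
    """
    config = config or AssortConfig()
    if len(pairs) == 0:
        raise ValueError("empty mate pair set")
    if matrix.n_loci == 0:
        return []
    if len(set(pairs.males())) < 2:
        raise ValueError("permutation null needs at least 2 distinct males in the pair set")

    idx = matrix.individual_index()
    f_idx = np.array([idx[f] for f in pairs.females()], dtype=np.intp)
    m_idx = np.array([idx[m] for m in pairs.males()], dtype=np.intp)
    logger.info("assortment scan: %d pairs (%s), %d loci, %d permutations, scheme=%s",
                len(pairs), pairs.group_label, matrix.n_loci,
                config.n_permutations, config.null_scheme)

    results: list[LocusAssortResult] = []
    for j in range(matrix.n_loci):
        fd = matrix.dosage[f_idx, j]
        md = matrix.dosage[m_idx, j]
        valid = (fd != MISSING) & (md != MISSING)
        n_used = int(valid.sum())
        if n_used < config.min_pairs_per_locus:
            results.append(LocusAssortResult(
                locus=matrix.locus_ids[j], n_pairs_used=n_used,
                observed_mean=float("nan"), percentile=float("nan"),
                classification=Classification.none,
                null_mean=float("nan"), null_sd=float("nan"), low_pairs=True))
            continue
        obs = float((2 - np.abs(fd[valid].astype(np.int32)
                                - md[valid].astype(np.int32))).mean())
        rng = _locus_rng(config.rng_seed, j)
        if config.null_scheme == "single-pairs":
            means = _single_pair_scores(fd, md, config.n_permutations, rng)
        else:
            means, _ = _replicate_means(fd, md, config.n_permutations,
                                        config.min_pairs_per_locus, rng)
        null = NullDistribution(locus=matrix.locus_ids[j], replicate_means=means)
        pct = percentile_of_observed(obs, null)
        results.append(LocusAssortResult(
            locus=matrix.locus_ids[j], n_pairs_used=n_used, observed_mean=obs,
            percentile=pct, classification=classify_locus(pct, config),
            null_mean=null.mean, null_sd=null.sd))
        if (j + 1) % 1000 == 0:
            logger.info("  ... %d / %d loci done", j + 1, matrix.n_loci)
    return results
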
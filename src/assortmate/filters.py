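"""Post-calling site and individual filters.

The chain mirrors the downstream cleanup used for reduced-representation
SNP panels: an HDplot-style paralog blacklist, removal of individuals with
excess missing data, then per-site mean-depth and missingness filters. All
threshold comparisons are strict ("more than", "less than", "exceeds"), so
a site sitting exactly on a bound is retained.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .types import MISSING, GenotypeMatrix, Locus

logger = logging.getLogger(__name__)


@dataclass
class FilterConfig:
    """Thresholds for the filter chain; set a field to None to skip a stage.

    Defaults: individuals with more than 20% missing genotypes are dropped;
    sites with mean depth below 5 or above 30, or with more than 80%
    missing genotypes, are removed; the paralog blacklist flags loci with
    heterozygosity above 0.6 or pooled read-ratio deviation D outside
    [-5, 7].
    """

    max_individual_missing: Optional[float] = 0.20
    min_mean_depth: Optional[float] = 5.0
    max_mean_depth: Optional[float] = 30.0
    max_site_missing: Optional[float] = 0.80
    hd_max_heterozygosity: Optional[float] = 0.6
    hd_min_D: Optional[float] = -5.0
    hd_max_D: Optional[float] = 7.0
    # whether missing-genotype cells contribute zero depth to the site mean
    # (False: they are excluded from the mean)
    depth_missing_as_zero: bool = False

    def __post_init__(self) -> None:
        for frac in (self.max_individual_missing, self.max_site_missing,
                     self.hd_max_heterozygosity):
            if frac is not None and not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction threshold {frac} outside [0, 1]")
        if (self.min_mean_depth is not None and self.max_mean_depth is not None
                and self.min_mean_depth > self.max_mean_depth):
            raise ValueError("min_mean_depth > max_mean_depth")
        if (self.hd_min_D is not None and self.hd_max_D is not None
                and self.hd_min_D > self.hd_max_D):
            raise ValueError("hd_min_D > hd_max_D")


@dataclass
class FilterReport:
    """Bookkeeping for one run of the filter chain.

    Each site is counted by the first stage that removes it, so
    ``n_sites_out = n_sites_in - paralog - depth - missing`` always holds.
    """

    n_sites_in: int
    n_individuals_removed: int
    n_sites_removed_paralog: int
    n_sites_removed_depth: int
    n_sites_removed_missing: int
    n_sites_out: int

    def __post_init__(self) -> None:
        expected = (self.n_sites_in - self.n_sites_removed_paralog
                    - self.n_sites_removed_depth - self.n_sites_removed_missing)
        if self.n_sites_out != expected:
            raise ValueError(
                f"inconsistent FilterReport: {self.n_sites_in} in minus removals "
                f"gives {expected}, not {self.n_sites_out}"
            )

    @classmethod
    def from_stage_counts(cls, n_sites_in: int, n_individuals_removed: int = 0,
                          n_sites_removed_paralog: int = 0,
                          n_sites_removed_depth: int = 0,
                          n_sites_removed_missing: int = 0) -> "FilterReport":
        """Build a report from per-stage removal counts, deriving n_sites_out."""
        return cls(
            n_sites_in=n_sites_in,
            n_individuals_removed=n_individuals_removed,
            n_sites_removed_paralog=n_sites_removed_paralog,
            n_sites_removed_depth=n_sites_removed_depth,
            n_sites_removed_missing=n_sites_removed_missing,
            n_sites_out=(n_sites_in - n_sites_removed_paralog
                         - n_sites_removed_depth - n_sites_removed_missing),
        )

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# individual stages
# ---------------------------------------------------------------------------

def filter_individuals(matrix: GenotypeMatrix,
                       max_individual_missing: float) -> tuple[GenotypeMatrix, list[str]]:
    """Drop individuals whose fraction of missing genotypes strictly exceeds
    the threshold; survivor order is preserved."""
    if matrix.n_individuals == 0 or matrix.n_loci == 0:
        raise ValueError("empty genotype matrix")
    miss_frac = (matrix.dosage == MISSING).mean(axis=1)
    keep = miss_frac <= max_individual_missing
    if not keep.any():
        raise ValueError("all individuals exceed the missingness threshold")
    removed = [matrix.individual_ids[i] for i in np.flatnonzero(~keep)]
    return matrix.subset_individuals(keep), removed


def site_mean_depth(matrix: GenotypeMatrix, missing_as_zero: bool = False) -> np.ndarray:
    """Per-site mean total read depth (ref + alt).

    By default individuals with a missing genotype are excluded from the
    mean; with ``missing_as_zero`` they contribute zero depth.
    """
    if matrix.allele_depths is None:
        raise ValueError("allele depths absent: skip the depth filter explicitly "
                         "(set min/max_mean_depth to None)")
    total = matrix.allele_depths.sum(axis=2).astype(float)
    if missing_as_zero:
        return total.mean(axis=0)
    genotyped = matrix.dosage != MISSING
    with np.errstate(invalid="ignore"):
        return np.where(genotyped.sum(axis=0) > 0,
                        np.where(genotyped, total, 0).sum(axis=0)
                        / np.maximum(genotyped.sum(axis=0), 1),
                        np.nan)


def filter_sites_depth(matrix: GenotypeMatrix, min_mean_depth: float,
                       max_mean_depth: float,
                       missing_as_zero: bool = False) -> tuple[GenotypeMatrix, list[Locus]]:
    """Remove sites whose mean depth is strictly below min or above max."""
    mean_depth = site_mean_depth(matrix, missing_as_zero)
    with np.errstate(invalid="ignore"):
        remove = (mean_depth < min_mean_depth) | (mean_depth > max_mean_depth)
    remove &= ~np.isnan(mean_depth) | np.zeros_like(remove)  # NaN mean -> keep
    removed = [matrix.locus_ids[j] for j in np.flatnonzero(remove)]
    return matrix.subset_loci(~remove), removed


def filter_sites_missing(matrix: GenotypeMatrix,
                         max_site_missing: float) -> tuple[GenotypeMatrix, list[Locus]]:
    """Remove sites whose fraction of missing genotypes strictly exceeds the threshold."""
    miss_frac = (matrix.dosage == MISSING).mean(axis=0)
    remove = miss_frac > max_site_missing
    removed = [matrix.locus_ids[j] for j in np.flatnonzero(remove)]
    return matrix.subset_loci(~remove), removed


def hdplot_statistics(matrix: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus heterozygosity H and read-ratio deviation D.

    H is the fraction of genotyped individuals that are heterozygous.
    D = (a - b) / sqrt(a + b), where a and b are the ref- and alt-allele
    read counts summed over heterozygous individuals at the locus: under
    unbiased sequencing of a single locus the heterozygote read split is
    Binomial(n, 1/2) and D is approximately standard normal, so collapsed
    paralogs show up as excess |D| and/or excess H. Loci with no
    heterozygote reads get D = 0 and are judged on H alone.
    """
    if matrix.allele_depths is None:
        raise ValueError("allele depths absent: cannot compute HDplot statistics")
    genotyped = matrix.dosage != MISSING
    het = matrix.dosage == 1
    n_genotyped = genotyped.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        H = np.where(n_genotyped > 0, het.sum(axis=0) / np.maximum(n_genotyped, 1), 0.0)
    a = np.where(het, matrix.allele_depths[:, :, 0], 0).sum(axis=0).astype(float)
    b = np.where(het, matrix.allele_depths[:, :, 1], 0).sum(axis=0).astype(float)
    tot = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(tot > 0, (a - b) / np.sqrt(np.maximum(tot, 1e-300)), 0.0)
    return H, D


def hdplot_paralog_blacklist(matrix: GenotypeMatrix, hd_max_heterozygosity: float = 0.6,
                             hd_min_D: float = -5.0, hd_max_D: float = 7.0) -> list[Locus]:
    """Loci flagged as putative paralogs: H > max, or D outside [min, max]."""
    H, D = hdplot_statistics(matrix)
    flagged = (H > hd_max_heterozygosity) | (D < hd_min_D) | (D > hd_max_D)
    return [matrix.locus_ids[j] for j in np.flatnonzero(flagged)]


def write_blacklist(loci: list[Locus], path) -> None:
    """Two-column (chromosome, position) exclusion list."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("chrom\tpos\n")
        for locus in loci:
            fh.write(f"{locus.chrom}\t{locus.pos}\n")


# ---------------------------------------------------------------------------
# chain
# ---------------------------------------------------------------------------

def run_filter_chain(matrix: GenotypeMatrix,
                     config: FilterConfig) -> tuple[GenotypeMatrix, FilterReport]:
    """Run paralog blacklist -> individual missingness -> depth -> site
    missingness, returning the filtered matrix and a consistent report.

    Each stage is skipped when its thresholds are None. The chain is a
    single-pass approximation of the two-pass call-blacklist-recall
    procedure used with a genotype caller; re-running it on its own output
    is a no-op.
    """
    n_in = matrix.n_loci
    n_paralog = n_depth = n_missing = 0
    removed_individuals: list[str] = []

    if (config.hd_max_heterozygosity is not None and config.hd_min_D is not None
            and config.hd_max_D is not None):
        blacklist = hdplot_paralog_blacklist(matrix, config.hd_max_heterozygosity,
                                             config.hd_min_D, config.hd_max_D)
        black = set(blacklist)
        keep = np.array([l not in black for l in matrix.locus_ids])
        n_paralog = int((~keep).sum())
        matrix = matrix.subset_loci(keep)
        logger.info("paralog blacklist removed %d loci", n_paralog)

    if config.max_individual_missing is not None:
        matrix, removed_individuals = filter_individuals(matrix, config.max_individual_missing)
        logger.info("removed %d individuals for missingness", len(removed_individuals))

    if config.min_mean_depth is not None and config.max_mean_depth is not None:
        matrix, removed = filter_sites_depth(matrix, config.min_mean_depth,
                                             config.max_mean_depth,
                                             config.depth_missing_as_zero)
        n_depth = len(removed)
        logger.info("depth filter removed %d sites", n_depth)

    if config.max_site_missing is not None:
        matrix, removed = filter_sites_missing(matrix, config.max_site_missing)
        n_missing = len(removed)
        logger.info("site-missingness filter removed %d sites", n_missing)

    if matrix.n_loci == 0:
        logger.warning("filter chain removed every site")

    report = FilterReport.from_stage_counts(
        n_sites_in=n_in,
        n_individuals_removed=len(removed_individuals),
        n_sites_removed_paralog=n_paralog,
        n_sites_removed_depth=n_depth,
        n_sites_removed_missing=n_missing,
    )
    return matrix, report
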
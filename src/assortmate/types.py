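"""Core domain types for the mate-assortment pipeline.

The central objects are a :class:`GenotypeMatrix` of minor-allele dosages
(individuals x biallelic SNP loci, with explicit missingness and optional
per-cell allele depths), a :class:`Cohort` of individuals with sex and
origin metadata, and a :class:`MatePairSet` of observed (female, male)
mate pairs belonging to one mating category.

Dosage convention: each cell counts copies of the locus's *minor* allele,
so 0 = homozygous major, 1 = heterozygous, 2 = homozygous minor, and
``MISSING`` (-1) marks an uncalled genotype. The minor allele is fixed
once per locus over all genotyped individuals in the loaded cohort; on an
exact 0.5 frequency tie the alternate allele is designated minor (the
sharing statistic is invariant to the choice, since d -> 2 - d leaves
|d1 - d2| unchanged).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np

#: Sentinel for an uncalled genotype in dosage arrays (int8).
MISSING: int = -1


class Sex(str, enum.Enum):
    female = "female"
    male = "male"


class Origin(str, enum.Enum):
    wild = "wild"
    hatchery = "hatchery"
    unknown = "unknown"


@dataclass(frozen=True, order=True)
class Locus:
    """A biallelic SNP keyed by (chromosome, 1-based position, ref, alt)."""

    chrom: str
    pos: int  # 1-based, inclusive coordinates throughout
    ref: str
    alt: str

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass
class Individual:
    id: str
    sex: Optional[Sex] = None
    origin: Origin = Origin.unknown


class Cohort:
    """A set of individuals with unique IDs."""

    def __init__(self, individuals: Iterable[Individual]):
        self.individuals: list[Individual] = list(individuals)
        self._by_id: dict[str, Individual] = {}
        for ind in self.individuals:
            if ind.id in self._by_id:
                raise ValueError(f"duplicate individual id {ind.id!r} in cohort")
            self._by_id[ind.id] = ind

    def __len__(self) -> int:
        return len(self.individuals)

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self._by_id

    def __getitem__(self, ind_id: str) -> Individual:
        return self._by_id[ind_id]

    def ids(self) -> list[str]:
        return [ind.id for ind in self.individuals]

    def subset(self, ids: Sequence[str]) -> "Cohort":
        return Cohort(self._by_id[i] for i in ids)


@dataclass
class GenotypeMatrix:
    """Individuals x loci minor-allele dosage matrix.

    Attributes
    ----------
    locus_ids
        Ordered loci.
    individual_ids
        Ordered sample IDs (rows of ``dosage``).
    dosage
        int8 array of shape (n_individuals, n_loci) with values in
        {0, 1, 2, MISSING}.
    allele_depths
        Optional int32 array of shape (n_individuals, n_loci, 2) holding
        (ref, alt) read counts per genotype call; required by the depth
        and paralog filters.
    minor_is_alt
        Boolean per locus: True when the dosage counts the alternate
        allele (i.e., alt is the designated minor allele).
    """

    locus_ids: list[Locus]
    individual_ids: list[str]
    dosage: np.ndarray
    allele_depths: Optional[np.ndarray] = None
    minor_is_alt: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.individual_ids), len(self.locus_ids)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.locus_ids)} loci"
            )
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosage values must be in {0, 1, 2, MISSING}")
        if self.allele_depths is not None:
            self.allele_depths = np.asarray(self.allele_depths, dtype=np.int32)
            if self.allele_depths.shape != self.dosage.shape + (2,):
                raise ValueError("allele_depths shape must be dosage shape + (2,)")
            if (self.allele_depths < 0).any():
                raise ValueError("allele_depths must be non-negative")
        if self.minor_is_alt is None:
            self.minor_is_alt = np.ones(len(self.locus_ids), dtype=bool)
        else:
            self.minor_is_alt = np.asarray(self.minor_is_alt, dtype=bool)
            if self.minor_is_alt.shape != (len(self.locus_ids),):
                raise ValueError("minor_is_alt must have one entry per locus")

    # -- basic shape ------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def individual_index(self) -> dict[str, int]:
        return {ind: i for i, ind in enumerate(self.individual_ids)}

    # -- subsetting -------------------------------------------------------
    def subset_individuals(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Return a copy restricted to the given individual row selector."""
        keep = np.asarray(keep)
        ids = [self.individual_ids[i] for i in np.arange(self.n_individuals)[keep]] \
            if keep.dtype == bool else [self.individual_ids[i] for i in keep]
        ad = self.allele_depths[keep] if self.allele_depths is not None else None
        return GenotypeMatrix(self.locus_ids, ids, self.dosage[keep], ad,
                              self.minor_is_alt.copy())

    def subset_loci(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Return a copy restricted to the given locus column selector."""
        keep = np.asarray(keep)
        idx = np.arange(self.n_loci)[keep] if keep.dtype == bool else keep
        loci = [self.locus_ids[j] for j in idx]
        ad = self.allele_depths[:, idx] if self.allele_depths is not None else None
        return GenotypeMatrix(loci, list(self.individual_ids),
                              self.dosage[:, idx], ad, self.minor_is_alt[idx])

    # -- allele bookkeeping ----------------------------------------------
    def counted_allele_frequency(self) -> np.ndarray:
        """Frequency of the currently counted allele among genotyped calls.

        Loci with no genotyped individual get NaN.
        """
        nonmiss = self.dosage != MISSING
        counts = nonmiss.sum(axis=0)
        sums = np.where(nonmiss, self.dosage, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(counts > 0, sums / np.maximum(counts, 1) / 2.0, np.nan)

    def encode_minor(self) -> "GenotypeMatrix":
        """Re-derive the minor allele per locus and flip dosages as needed.

        The minor allele is the one with frequency <= 0.5 over all genotyped
        individuals; on an exact tie the alternate allele is designated
        minor. Idempotent: applying it twice never flips a locus again.
        """
        freq = self.counted_allele_frequency()
        alt_freq = np.where(self.minor_is_alt, freq, 1.0 - freq)
        # tie at exactly 0.5 -> alt is the minor allele
        new_minor_is_alt = ~(alt_freq > 0.5)
        # untyped loci (all missing): keep current orientation
        new_minor_is_alt[np.isnan(alt_freq)] = self.minor_is_alt[np.isnan(alt_freq)]
        flip = new_minor_is_alt != self.minor_is_alt
        dosage = self.dosage.copy()
        if flip.any():
            cols = dosage[:, flip]
            nonmiss = cols != MISSING
            cols[nonmiss] = 2 - cols[nonmiss]
            dosage[:, flip] = cols
        ad = self.allele_depths.copy() if self.allele_depths is not None else None
        return GenotypeMatrix(list(self.locus_ids), list(self.individual_ids),
                              dosage, ad, new_minor_is_alt)


@dataclass
class MatePairSet:
    """Observed (female, male) mate pairs in one mating category."""

    group_label: str
    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("mate pairs must be unique within a MatePairSet")

    def __len__(self) -> int:
        return len(self.pairs)

    def females(self) -> list[str]:
        return [f for f, _ in self.pairs]

    def males(self) -> list[str]:
        return [m for _, m in self.pairs]

    def validate(self, cohort: Cohort) -> None:
        """Check every member exists in the cohort with the right sex."""
        for f, m in self.pairs:
            if f not in cohort:
                raise ValueError(f"pair ({f}, {m}): unknown female id {f!r}")
            if m not in cohort:
                raise ValueError(f"pair ({f}, {m}): unknown male id {m!r}")
            if cohort[f].sex is not Sex.female:
                raise ValueError(f"pair ({f}, {m}): {f!r} is not recorded as female")
            if cohort[m].sex is not Sex.male:
                raise ValueError(f"pair ({f}, {m}): {m!r} is not recorded as male")


class Classification(str, enum.Enum):
    negative = "negative"
    positive = "positive"
    none = "none"


@dataclass
class LocusAssortResult:
    """Per-locus outcome of the mate-assortment permutation test."""

    locus: Locus
    n_pairs_used: int
    observed_mean: float  # NaN when undefined
    percentile: float  # NaN when undefined
    classification: Classification
    null_mean: float
    null_sd: float
    low_pairs: bool = False  # too few genotyped pairs to test


@dataclass(frozen=True)
class GeneFeature:
    """A gene span from a GFF3 file; 1-based inclusive coordinates."""

    seqid: str
    start: int
    end: int
    strand: str
    gene_id: str
    gene_name: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start {self.start} > end {self.end}")

    def contains(self, seqid: str, pos: int) -> bool:
        return seqid == self.seqid and self.start <= pos <= self.end


__all__ = [
    "MISSING", "Sex", "Origin", "Locus", "Individual", "Cohort",
    "GenotypeMatrix", "MatePairSet", "Classification", "LocusAssortResult",
    "GeneFeature", "replace",
]
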
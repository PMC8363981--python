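import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from assortmate.types import (
    Cohort,
    GenotypeMatrix,
    Individual,
    Locus,
    MatePairSet,
    Origin,
    Sex,
)

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None,
)
settings.load_profile("suite")


def make_loci(n: int, chrom: str = "chr1", start: int = 100) -> list[Locus]:
    return [Locus(chrom, start + 50 * j, "A", "G") for j in range(n)]


def make_matrix(dosage, depths=None, chrom: str = "chr1") -> GenotypeMatrix:
    dosage = np.asarray(dosage, dtype=np.int8)
    n_ind, n_loci = dosage.shape
    ids = [f"S{i}" for i in range(n_ind)]
    return GenotypeMatrix(make_loci(n_loci, chrom), ids, dosage, depths)


def make_cohort(n_females: int, n_males: int) -> Cohort:
    inds = [Individual(f"F{i}", Sex.female, Origin.wild) for i in range(n_females)]
    inds += [Individual(f"M{i}", Sex.male, Origin.wild) for i in range(n_males)]
    return Cohort(inds)


@pytest.fixture
def toy_cohort() -> Cohort:
    return make_cohort(3, 3)


@pytest.fixture
def toy_pairs(toy_cohort) -> MatePairSet:
    return MatePairSet("wild", [("F0", "M0"), ("F1", "M1"), ("F2", "M2")])
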
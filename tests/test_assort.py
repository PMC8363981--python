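"""Sharing statistic, permutation null, percentile, and classification."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from assortmate.assort import (
    AssortConfig,
    NullDistribution,
    classify_locus,
    observed_mean_sharing,
    percentile_of_observed,
    permutation_null,
    run_group_assortment,
    shared_alleles,
)
from assortmate.types import MISSING, Classification, MatePairSet
from conftest import make_matrix

M = MISSING


def _verbal_sharing(d1: int, d2: int) -> int:
    """Sharing classes spelled out genotype by genotype: AA/Aa/aa as dosage
    0/1/2 of the minor allele a; count shared allele classes."""
    alleles = {0: {"A"}, 1: {"A", "a"}, 2: {"a"}}
    common = alleles[d1] & alleles[d2]
    if not common:
        return 0
    if alleles[d1] == alleles[d2]:
        return 2
    return 1


@pytest.mark.parametrize("d1,d2", list(itertools.product([0, 1, 2], repeat=2)))
def test_shared_alleles_matches_verbal_classes(d1, d2):
    """2 - |d1 - d2| reproduces the two/one/zero shared-allele classes for
    all 9 genotype combinations."""
    assert shared_alleles(d1, d2) == _verbal_sharing(d1, d2)


def test_shared_alleles_symmetry_relabeling_and_missing():
    for d1, d2 in itertools.product([0, 1, 2], repeat=2):
        assert shared_alleles(d1, d2) == shared_alleles(d2, d1)
        # swapping which allele is 'minor' maps d -> 2 - d on both sides
        assert shared_alleles(d1, d2) == shared_alleles(2 - d1, 2 - d2)
    assert shared_alleles(M, 1) == M
    assert shared_alleles(1, M) == M
    with pytest.raises(ValueError, match="dosage"):
        shared_alleles(3, 0)


def test_observed_mean_skips_pairs_with_missing_members(toy_pairs):
    # pairwise sharing scores: (0,2)->0, (1,1)->2, (1,0)->1  => mean 1.0, n 3
    dosage = np.array([[0], [1], [1], [2], [1], [0]], dtype=np.int8)
    matrix = make_matrix(dosage)
    matrix.individual_ids = ["F0", "F1", "F2", "M0", "M1", "M2"]
    assert observed_mean_sharing(toy_pairs, matrix, 0) == (1.0, 3)

    dosage[0, 0] = M  # female of the score-0 pair ungenotyped -> mean over {2, 1}
    assert observed_mean_sharing(toy_pairs, matrix, 0) == (1.5, 2)

    all_missing = make_matrix(np.full((6, 1), M))
    all_missing.individual_ids = matrix.individual_ids
    mean, n = observed_mean_sharing(toy_pairs, all_missing, 0)
    assert np.isnan(mean) and n == 0

    with pytest.raises(KeyError):
        observed_mean_sharing(toy_pairs, matrix, 5)


def test_percentile_extremes_and_degenerate_tie():
    null = NullDistribution(None, np.array([1.0, 1.2, 1.4]))
    assert percentile_of_observed(0.5, null) == 0.0
    assert percentile_of_observed(1.9, null) == 1.0
    degenerate = NullDistribution(None, np.full(100, 2.0))
    assert percentile_of_observed(2.0, degenerate) == 0.5


@given(st.floats(0, 2), st.floats(0, 2))
def test_percentile_is_monotone_in_observed_mean(a, b):
    null = NullDistribution(None, np.linspace(0.5, 1.8, 200))
    lo, hi = sorted((a, b))
    assert percentile_of_observed(lo, null) <= percentile_of_observed(hi, null)


def test_classification_cutoffs_are_strict():
    config = AssortConfig(n_permutations=10)
    assert classify_locus(0.01, config) is Classification.negative
    assert classify_locus(0.98, config) is Classification.positive
    assert classify_locus(0.025, config) is Classification.none
    assert classify_locus(0.975, config) is Classification.none
    with pytest.raises(ValueError):
        classify_locus(1.5, config)


def test_permutation_null_is_deterministic_given_seed(toy_pairs):
    rng = np.random.default_rng(8)
    dosage = rng.choice([0, 1, 2], size=(6, 3)).astype(np.int8)
    matrix = make_matrix(dosage)
    matrix.individual_ids = ["F0", "F1", "F2", "M0", "M1", "M2"]
    config = AssortConfig(n_permutations=500, rng_seed=42)
    a = permutation_null(toy_pairs, matrix, 1, config)
    b = permutation_null(toy_pairs, matrix, 1, config)
    np.testing.assert_array_equal(a.replicate_means, b.replicate_means)


def test_monomorphic_heterozygotes_give_degenerate_null(toy_pairs):
    matrix = make_matrix(np.ones((6, 1), dtype=np.int8))
    matrix.individual_ids = ["F0", "F1", "F2", "M0", "M1", "M2"]
    null = permutation_null(toy_pairs, matrix, 0, AssortConfig(n_permutations=200))
    assert np.all(null.replicate_means == 2.0)
    obs, _ = observed_mean_sharing(toy_pairs, matrix, 0)
    assert percentile_of_observed(obs, null) == 0.5


def test_null_mean_converges_to_two_by_two_enumeration():
    """2 females x 2 males: the replicate-mean expectation equals the average
    of the four possible pair scores, computed by exhaustive enumeration."""
    pairs = MatePairSet("wild", [("F0", "M0"), ("F1", "M1")])
    dosage = np.array([[0], [1], [2], [1]], dtype=np.int8)  # F0, F1, M0, M1
    matrix = make_matrix(dosage)
    matrix.individual_ids = ["F0", "F1", "M0", "M1"]
    scores = [shared_alleles(df, dm) for df in (0, 1) for dm in (2, 1)]
    expected = np.mean(scores)
    n_perm = 20_000
    null = permutation_null(pairs, matrix, 0, AssortConfig(n_permutations=n_perm, rng_seed=1))
    se = null.sd / np.sqrt(n_perm)
    assert abs(null.mean - expected) < 3 * se


def test_permutation_requires_two_distinct_males():
    pairs = MatePairSet("wild", [("F0", "M0"), ("F1", "M0")])
    matrix = make_matrix(np.ones((4, 1), dtype=np.int8))
    matrix.individual_ids = ["F0", "F1", "M0", "M1"]
    with pytest.raises(ValueError, match="distinct males"):
        permutation_null(pairs, matrix, 0, AssortConfig(n_permutations=10))


def test_run_group_assortment_flags_sparse_loci_and_handles_empty(toy_pairs):
    dosage = np.array([  # locus 0 informative, locus 1 fully missing
        [0, M], [1, M], [2, M], [2, M], [1, M], [0, M]], dtype=np.int8)
    matrix = make_matrix(dosage)
    matrix.individual_ids = ["F0", "F1", "F2", "M0", "M1", "M2"]
    results = run_group_assortment(toy_pairs, matrix, AssortConfig(n_permutations=100))
    assert len(results) == 2
    assert not results[0].low_pairs
    assert results[1].low_pairs and results[1].classification is Classification.none
    assert np.isnan(results[1].percentile)

    empty = matrix.subset_loci(np.zeros(2, dtype=bool))
    assert run_group_assortment(toy_pairs, empty, AssortConfig(n_permutations=10)) == []
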
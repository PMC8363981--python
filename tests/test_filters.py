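"""Site/individual filter chain and HDplot paralog statistics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from assortmate.filters import (
    FilterConfig,
    FilterReport,
    filter_individuals,
    filter_sites_depth,
    filter_sites_missing,
    hdplot_paralog_blacklist,
    hdplot_statistics,
    run_filter_chain,
)
from assortmate.types import MISSING
from conftest import make_matrix

M = MISSING


def _depths(total):
    """(ref, alt) depth array with an even split from per-cell totals."""
    total = np.asarray(total)
    ref = total // 2
    return np.stack([ref, total - ref], axis=2).astype(np.int32)


def test_individual_missingness_is_strictly_more_than():
    dosage = np.zeros((3, 10), dtype=np.int8)
    dosage[0, :3] = M  # 30% missing -> removed
    dosage[1, :2] = M  # exactly 20% -> retained
    filtered, removed = filter_individuals(make_matrix(dosage), 0.20)
    assert removed == ["S0"]
    assert filtered.individual_ids == ["S1", "S2"]

    clean, removed = filter_individuals(make_matrix(np.ones((2, 4))), 0.20)
    assert removed == [] and clean.n_individuals == 2
    with pytest.raises(ValueError, match="all individuals"):
        filter_individuals(make_matrix(np.full((2, 2), M)), 0.0)


def test_depth_filter_boundaries_are_strict():
    dosage = np.ones((3, 3), dtype=np.int8)
    totals = np.array([[4, 5, 40]] * 3)  # means 4 (cut), 5 (kept), 40 (cut)
    matrix = make_matrix(dosage, _depths(totals))
    filtered, removed = filter_sites_depth(matrix, 5, 30)
    assert filtered.n_loci == 1 and filtered.locus_ids[0].pos == matrix.locus_ids[1].pos
    assert len(removed) == 2


def test_depth_filter_requires_depths_and_handles_missing_cells():
    with pytest.raises(ValueError, match="depths absent"):
        filter_sites_depth(make_matrix(np.ones((2, 2))), 5, 30)
    # one missing genotype excluded from the site mean by default
    dosage = np.array([[1, 1], [M, 1]], dtype=np.int8)
    matrix = make_matrix(dosage, _depths(np.array([[6, 6], [0, 6]])))
    filtered, removed = filter_sites_depth(matrix, 5, 30)
    assert filtered.n_loci == 2  # mean over genotyped cells = 6 at both sites
    # counting the missing cell as zero depth drops site 0 (mean 3 < 5)
    filtered, removed = filter_sites_depth(matrix, 5, 30, missing_as_zero=True)
    assert filtered.n_loci == 1


def test_site_missingness_is_strictly_greater_than():
    dosage = np.ones((10, 3), dtype=np.int8)
    dosage[:9, 0] = M   # 90% -> removed
    dosage[:8, 1] = M   # exactly 80% -> retained
    filtered, removed = filter_sites_missing(make_matrix(dosage), 0.80)
    assert filtered.n_loci == 2 and len(removed) == 1

    clean, removed = filter_sites_missing(make_matrix(np.zeros((4, 4))), 0.80)
    assert removed == [] and clean.n_loci == 4


def test_hdplot_blacklists_on_heterozygosity_or_read_ratio():
    # locus 0: H = 0.7 -> blacklisted regardless of D
    # locus 1: balanced het reads (50, 50), H = 0.5 -> D = 0, kept
    # locus 2: pooled het reads a=90, b=10 -> D = 80/sqrt(100) = 8 > 7 -> blacklisted
    dosage = np.zeros((10, 3), dtype=np.int8)
    dosage[:7, 0] = 1
    dosage[:5, 1] = 1
    dosage[:5, 2] = 1
    depths = np.zeros((10, 3, 2), dtype=np.int32)
    depths[:7, 0] = (10, 10)
    depths[:5, 1] = (10, 10)
    depths[:5, 2] = (18, 2)
    matrix = make_matrix(dosage, depths)
    H, D = hdplot_statistics(matrix)
    assert H[0] == pytest.approx(0.7)
    assert D[1] == pytest.approx(0.0)
    assert D[2] == pytest.approx(8.0)
    black = hdplot_paralog_blacklist(matrix)
    assert [l.pos for l in black] == [matrix.locus_ids[0].pos, matrix.locus_ids[2].pos]


def test_hdplot_no_heterozygotes_judged_on_h_alone():
    dosage = np.array([[0, 0], [2, 2]], dtype=np.int8)
    matrix = make_matrix(dosage, _depths(np.full((2, 2), 10)))
    assert hdplot_paralog_blacklist(matrix) == []


def test_chain_passthrough_is_identity_and_reports_zero():
    matrix = make_matrix(np.ones((4, 5), dtype=np.int8))
    out, report = run_filter_chain(matrix, FilterConfig(
        max_individual_missing=None, min_mean_depth=None, max_mean_depth=None,
        max_site_missing=None, hd_max_heterozygosity=None, hd_min_D=None, hd_max_D=None))
    np.testing.assert_array_equal(out.dosage, matrix.dosage)
    assert report.n_sites_out == 5
    assert (report.n_sites_removed_depth == report.n_sites_removed_missing
            == report.n_sites_removed_paralog == 0)


def test_chain_is_idempotent_and_arithmetic_consistent():
    # realistic missingness (well below the 20% individual cutoff): removing
    # sites in pass 1 then leaves no individual straddling the threshold
    rng = np.random.default_rng(1)
    dosage = rng.choice([0, 1, 2, M], size=(20, 40), p=[0.45, 0.3, 0.2, 0.05]).astype(np.int8)
    depths = _depths(rng.integers(0, 40, size=(20, 40)))
    config = FilterConfig()
    once, report1 = run_filter_chain(make_matrix(dosage, depths), config)
    assert report1.n_sites_out == once.n_loci
    twice, report2 = run_filter_chain(once, config)
    np.testing.assert_array_equal(once.dosage, twice.dosage)
    assert report2.n_sites_out == report2.n_sites_in
    assert report2.n_individuals_removed == 0


def test_chain_degenerate_all_sites_fail_depth():
    matrix = make_matrix(np.ones((3, 4), dtype=np.int8), _depths(np.full((3, 4), 2)))
    out, report = run_filter_chain(matrix, FilterConfig(hd_max_heterozygosity=None,
                                                        hd_min_D=None, hd_max_D=None))
    assert out.n_loci == 0 and report.n_sites_removed_depth == 4


def test_report_rejects_inconsistent_counts():
    with pytest.raises(ValueError, match="inconsistent"):
        FilterReport(n_sites_in=10, n_individuals_removed=0, n_sites_removed_paralog=0,
                     n_sites_removed_depth=1, n_sites_removed_missing=0, n_sites_out=10)


@given(
    hnp.arrays(np.int8, st.tuples(st.integers(2, 8), st.integers(1, 15)),
               elements=st.sampled_from([0, 1, 2, M])),
    st.floats(0.1, 0.9),
)
def test_report_arithmetic_identity_on_random_matrices(dosage, max_missing):
    rng = np.random.default_rng(0)
    depths = _depths(rng.integers(0, 40, size=dosage.shape))
    try:
        out, report = run_filter_chain(
            make_matrix(dosage, depths), FilterConfig(max_individual_missing=max_missing))
    except ValueError:
        return  # every individual removed: valid error path
    assert report.n_sites_out == out.n_loci
    assert report.n_sites_in - report.n_sites_out == (
        report.n_sites_removed_paralog + report.n_sites_removed_depth
        + report.n_sites_removed_missing)


@given(st.floats(0.0, 0.8))
def test_tightening_site_missingness_never_keeps_more_sites(threshold):
    rng = np.random.default_rng(3)
    dosage = rng.choice([1, M], size=(10, 30), p=[0.6, 0.4]).astype(np.int8)
    loose, _ = filter_sites_missing(make_matrix(dosage), 0.9)
    tight, _ = filter_sites_missing(make_matrix(dosage), threshold)
    assert tight.n_loci <= loose.n_loci
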
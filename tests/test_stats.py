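"""Statistics module against independent oracles.

The Wilcoxon oracle enumerates all 2^n sign assignments; the BH oracle is a
hand-coded step-up; point-biserial is checked against scipy's dedicated
implementations.
"""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from headig.attribution import HeadAttributionMap
from headig.stats import (
    HeadStatMatrix,
    TestConfig as StatsConfig,  # aliased so pytest does not try to collect it
    aggregate_correlations,
    bh_adjust,
    correlate_protein,
    count_hypothesis_tests,
    HeadAnnotationAnalysis,
    mask_overlay,
    point_biserial,
    positive_relevance_test,
    summed_relevance,
    wilcoxon_positive,
)

rng = np.random.default_rng(7)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def wilcoxon_exact_enumeration(values: np.ndarray) -> float:
    """Exact one-sided signed-rank p by enumerating all 2^n sign vectors."""
    v = np.asarray(values, dtype=float)
    v = v[v != 0]
    ranks = sps.rankdata(np.abs(v))
    w_obs = ranks[v > 0].sum()
    n = len(v)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = ranks[np.array(signs, dtype=bool)].sum()
        if w >= w_obs - 1e-12:
            count += 1
    return count / 2**n


def bh_step_up_reference(p: np.ndarray) -> np.ndarray:
    """Independent BH implementation: sort, scale by m/rank, enforce monotone."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, p[idx] * m / rank_from_top)
        adj[idx] = running_min
    return np.minimum(adj, 1.0)


# ---------------------------------------------------------------------------
# point-biserial
# ---------------------------------------------------------------------------

def test_point_biserial_perfect_separation():
    assert point_biserial([2, 0, 2, 0], [1, 0, 1, 0]) == pytest.approx(1.0)


def test_point_biserial_degenerate_annotation_is_missing():
    assert np.isnan(point_biserial([1.0, 2.0, 3.0], [1, 1, 1]))
    assert np.isnan(point_biserial([1.0, 2.0, 3.0], [0, 0, 0]))
    assert np.isnan(point_biserial([2.0, 2.0, 2.0], [0, 1, 0]))


def test_point_biserial_rejects_mismatch_and_nonbinary():
    with pytest.raises(ValueError, match="length mismatch"):
        point_biserial([1.0, 2.0], [0, 1, 1])
    with pytest.raises(ValueError, match="binary"):
        point_biserial([1.0, 2.0, 3.0], [0, 1, 2])


def test_point_biserial_equals_pearson_and_scipy():
    for _ in range(200):
        n = rng.integers(5, 60)
        x = rng.normal(size=n)
        y = np.zeros(n, dtype=int)
        y[rng.choice(n, size=rng.integers(1, n), replace=False)] = 1
        if y.min() == y.max():
            continue
        r = point_biserial(x, y)
        assert abs(r - sps.pearsonr(x, y.astype(float)).statistic) < 1e-12
        assert abs(r - sps.pointbiserialr(y, x).correlation) < 1e-12


# ---------------------------------------------------------------------------
# Wilcoxon
# ---------------------------------------------------------------------------

def test_wilcoxon_six_distinct_positive_values_is_one_in_64():
    p = wilcoxon_positive(np.array([0.3, 1.2, 2.4, 0.7, 5.0, 3.3]))
    assert p == pytest.approx(1 / 64)


def test_wilcoxon_symmetric_pairs_not_significant():
    p = wilcoxon_positive(np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0]))
    assert p >= 0.5


def test_wilcoxon_all_negative_is_near_one():
    p = wilcoxon_positive(-np.abs(rng.normal(size=8)) - 0.1)
    assert p > 0.95


def test_wilcoxon_small_n_missing():
    assert np.isnan(wilcoxon_positive(np.array([1.0, 2.0, 3.0, 4.0])))
    # zeros are discarded before the n check under the default policy
    assert np.isnan(wilcoxon_positive(np.array([1.0, 2.0, 3.0, 4.0, 0.0])))


def test_wilcoxon_matches_exact_enumeration():
    for n in range(5, 11):
        for _ in range(30):
            v = rng.normal(size=n)
            while np.unique(np.abs(v)).size < n:
                v = rng.normal(size=n)
            p = wilcoxon_positive(v)
            p_oracle = wilcoxon_exact_enumeration(v)
            assert p == pytest.approx(p_oracle, abs=1e-12), v


# ---------------------------------------------------------------------------
# BH
# ---------------------------------------------------------------------------

def test_bh_stepup_worked_example():
    np.testing.assert_allclose(bh_adjust([0.01, 0.04]), [0.02, 0.04])


def test_bh_single_and_constant_inputs_unchanged():
    np.testing.assert_allclose(bh_adjust([0.3]), [0.3])
    np.testing.assert_allclose(bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])


def test_bh_matches_independent_reference_and_dominates_raw():
    for _ in range(50):
        p = rng.uniform(size=rng.integers(1, 40))
        adj = bh_adjust(p)
        np.testing.assert_allclose(adj, bh_step_up_reference(p), atol=1e-12)
        assert np.all(adj >= p - 1e-15)


def test_bh_preserves_missing_entries():
    p = np.array([0.01, np.nan, 0.04])
    adj = bh_adjust(p)
    assert np.isnan(adj[1])
    np.testing.assert_allclose(adj[[0, 2]], [0.02, 0.04])


# ---------------------------------------------------------------------------
# grid machinery
# ---------------------------------------------------------------------------

def test_hypothesis_test_count():
    assert count_hypothesis_tests(30, 16) == 480
    assert count_hypothesis_tests(1, 1) == 1
    assert count_hypothesis_tests(2, 4) == 8


def _head_maps(values_by_layer, special=None):
    maps = []
    for l, vals in enumerate(values_by_layer):
        vals = np.asarray(vals, dtype=float)
        mask = np.zeros(vals.shape[0], dtype=bool) if special is None else special
        maps.append(HeadAttributionMap(l, vals, mask))
    return maps


def test_correlate_protein_shape_and_determinism():
    ann = np.array([1, 0, 1, 0, 0, 1, 0, 0])
    vals = [rng.normal(size=(8, 4)) for _ in range(2)]
    grid = correlate_protein(_head_maps(vals), ann)
    assert grid.shape == (2, 4)
    grid2 = correlate_protein(_head_maps(vals), ann)
    np.testing.assert_array_equal(grid.values, grid2.values)


def test_correlate_protein_rejects_length_mismatch():
    with pytest.raises(ValueError, match="residues"):
        correlate_protein(_head_maps([rng.normal(size=(8, 4))]), np.ones(5, dtype=int))


def test_correlate_protein_excludes_special_tokens():
    special = np.zeros(10, dtype=bool)
    special[[0, 9]] = True
    vals = rng.normal(size=(10, 2))
    ann = rng.integers(0, 2, size=8)
    ann[0] = 1
    ann[1] = 0
    grid = correlate_protein(_head_maps([vals], special), ann)
    expected = point_biserial(vals[1:9, 0], ann)
    assert grid.values[0, 0] == pytest.approx(expected)


def test_aggregate_single_loaded_cell_survives():
    """One cell carries consistent positive r; the rest is centered noise."""
    mats = []
    for _ in range(30):
        grid = rng.normal(0.0, 0.05, size=(2, 4))
        grid[1, 2] = 0.5 + rng.normal(0.0, 0.05)
        mats.append(HeadStatMatrix(np.clip(grid, -1, 1), "correlation_r"))
    res = aggregate_correlations(mats)
    assert res.significant[1, 2]
    assert res.n_significant <= 2  # the loaded cell, possibly one fluke


def test_aggregate_alpha_one_keeps_every_testable_cell():
    mats = [HeadStatMatrix(rng.uniform(-1, 1, size=(2, 4)), "correlation_r")
            for _ in range(10)]
    res = aggregate_correlations(mats, StatsConfig(alpha=1.0))
    assert res.significant.all()


def test_aggregate_too_few_proteins_gives_missing_not_zero():
    mats = [HeadStatMatrix(rng.uniform(-1, 1, size=(2, 4)), "correlation_r")
            for _ in range(3)]
    res = aggregate_correlations(mats)
    assert np.all(np.isnan(res.p_adjusted.values))
    assert not res.significant.any()


def test_summed_relevance_conserves_totals():
    vals = [rng.normal(size=(8, 4)) for _ in range(2)]
    maps = _head_maps(vals)
    grid = summed_relevance(maps)
    assert grid.shape == (2, 4)
    assert grid.sum() == pytest.approx(sum(v.sum() for v in vals))


def test_positive_relevance_flags_constant_positive_head():
    summed = []
    for _ in range(20):
        g = rng.normal(0.0, 0.3, size=(2, 4))
        g[0, 1] = 2.0 + rng.normal(0.0, 0.1)
        summed.append(g)
    res = positive_relevance_test(summed)
    assert res.significant[0, 1]
    flipped = positive_relevance_test([-s for s in summed])
    assert not flipped.significant[0, 1]


def test_mask_overlay_limits():
    mats = []
    for _ in range(20):
        g = rng.normal(0.0, 0.05, size=(2, 4))
        g[0, 0] = 0.6 + rng.normal(0.0, 0.05)
        mats.append(HeadStatMatrix(np.clip(g, -1, 1), "correlation_r"))
    corr = aggregate_correlations(mats)
    rel_all = positive_relevance_test(
        [np.abs(rng.normal(size=(2, 4))) + 1.0 for _ in range(20)]
    )
    rel_none = positive_relevance_test(
        [-np.abs(rng.normal(size=(2, 4))) - 1.0 for _ in range(20)]
    )
    full = mask_overlay(corr, rel_all)
    empty = mask_overlay(corr, rel_none)
    np.testing.assert_array_equal(full.values, corr.neglog10.values)
    assert np.nansum(empty.values) == 0.0


def test_analysis_facade_summary_reports_joint_cells():
    mats, summed = [], []
    for _ in range(25):
        g = rng.normal(0.0, 0.05, size=(2, 4))
        g[1, 3] = 0.5 + rng.normal(0.0, 0.05)
        mats.append(HeadStatMatrix(np.clip(g, -1, 1), "correlation_r"))
        s = rng.normal(0.0, 0.2, size=(2, 4))
        s[1, 3] = 1.5 + rng.normal(0.0, 0.1)
        summed.append(s)
    res = HeadAnnotationAnalysis(mats, summed).fit()
    assert res.joint_mask[1, 3]
    assert "jointly significant cells" in res.summary()
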
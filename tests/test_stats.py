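"""Statistical primitives against independent oracles and their invariants."""

import itertools
import math

import numpy as np
import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

from dcismir.stats import (
    DegenerateTableError,
    bh_adjust,
    chi_square_independence,
    mann_whitney_u,
    midrank,
    pearson_r,
    spearman_rho,
    welch_t_test,
)

finite_floats = st.floats(-1e3, 1e3, allow_nan=False)


# ---------------------------------------------------------------------------
# Pearson / Spearman


@pytest.mark.parametrize(
    "x, y, expected_r",
    [
        ([1, 2, 3, 4], [3, 5, 7, 9], 1.0),  # y = 2x + 1 exactly
        ([0, 1, 2], [0, 1, 4], 0.9607689228305228),  # hand-computed: cov 2, sds 1, 2.0817
        ([1, 2, 3, 4], [9, 7, 5, 3], -1.0),
    ],
)
def test_pearson_known_values(x, y, expected_r):
    res = pearson_r(x, y)
    assert res.estimate == pytest.approx(expected_r, abs=1e-12)
    assert res.method == "pearson"


def test_pearson_constant_input_not_testable():
    res = pearson_r([5, 5, 5, 5], [1, 2, 3, 4])
    assert not res.testable
    assert math.isnan(res.estimate)


def test_pearson_input_validation():
    with pytest.raises(ValueError):
        pearson_r([1, 2], [1, 2, 3])
    with pytest.raises(ValueError):
        pearson_r([1, 2], [3, 4])


@pytest.mark.parametrize("seed", range(5))
def test_pearson_matches_scipy(seed):
    rng = np.random.default_rng(seed)
    x, y = rng.standard_normal((2, 20))
    res = pearson_r(x, y)
    ref = scipy.stats.pearsonr(x, y)
    assert res.estimate == pytest.approx(ref.statistic, abs=1e-12)
    assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)


def test_pearson_null_rejection_rate_calibrated():
    """Under independent normals (n=32) the 5% test rejects ~5% of the time."""
    rng = np.random.default_rng(11)
    reps = 5000
    rejections = sum(
        pearson_r(rng.standard_normal(32), rng.standard_normal(32)).p_value < 0.05
        for _ in range(reps)
    )
    rate = rejections / reps
    assert abs(rate - 0.05) <= 3 * math.sqrt(0.05 * 0.95 / reps)


@given(
    st.lists(finite_floats, min_size=5, max_size=15),
    st.floats(0.1, 10.0),
    st.floats(-100.0, 100.0),
)
def test_pearson_affine_invariance(values, a, b):
    rng = np.random.default_rng(7)
    x = np.asarray(values)
    y = rng.standard_normal(len(x))
    base = pearson_r(x, y)
    if not base.testable:
        return
    scaled = pearson_r(a * x + b, y)
    assert scaled.estimate == pytest.approx(base.estimate, abs=1e-9)


def test_spearman_monotone_and_ties():
    assert spearman_rho([1, 2, 3, 4], [10, 100, 1000, 10000]).estimate == pytest.approx(1.0)
    assert spearman_rho([1, 2, 3, 4], [5, 4, 3, 2]).estimate == pytest.approx(-1.0)
    # identical mid-rank vectors despite ties
    assert spearman_rho([1, 2, 2, 3], [10, 20, 20, 40]).estimate == pytest.approx(1.0)


@pytest.mark.parametrize("seed", range(5))
def test_spearman_matches_scipy_with_ties(seed):
    rng = np.random.default_rng(seed)
    x = rng.integers(0, 6, size=25).astype(float)
    y = rng.integers(0, 6, size=25).astype(float)
    if len(set(x)) < 2 or len(set(y)) < 2:
        pytest.skip("degenerate draw")
    res = spearman_rho(x, y)
    ref = scipy.stats.spearmanr(x, y)
    assert res.estimate == pytest.approx(ref.statistic, abs=1e-12)


@given(st.permutations(list(range(8))))
def test_spearman_invariant_under_monotone_transform(perm):
    x = np.asarray(perm, dtype=float)
    y = np.arange(8.0)
    base = spearman_rho(x, y).estimate
    transformed = spearman_rho(np.exp(x / 3.0), y).estimate
    assert transformed == pytest.approx(base, abs=1e-12)


def test_midrank_averages_ties():
    assert midrank([10, 20, 20, 40]).tolist() == [1.0, 2.5, 2.5, 4.0]


# ---------------------------------------------------------------------------
# chi-square


def test_chi_square_uniform_table_is_null():
    res = chi_square_independence([[10, 10], [10, 10]])
    assert res.statistic == 0.0
    assert res.p_value == 1.0


def test_chi_square_2x2_closed_form():
    a, b, c, dd = 20, 5, 5, 20
    res = chi_square_independence([[a, b], [c, dd]])
    n = a + b + c + dd
    expected = (a * dd - b * c) ** 2 * n / ((a + b) * (c + dd) * (a + c) * (b + dd))
    assert res.statistic == pytest.approx(expected, abs=1e-12)
    assert res.df == 1


@pytest.mark.parametrize("seed", range(5))
def test_chi_square_matches_scipy(seed):
    rng = np.random.default_rng(seed)
    table = rng.integers(1, 40, size=(3, 4))
    res = chi_square_independence(table)
    stat, p, df, _ = scipy.stats.chi2_contingency(table, correction=False)
    assert res.statistic == pytest.approx(stat, rel=1e-12)
    assert res.p_value == pytest.approx(p, rel=1e-9)
    assert res.df == df


def test_chi_square_degenerate_marginal():
    with pytest.raises(DegenerateTableError):
        chi_square_independence([[0, 0], [3, 4]])


def test_chi_square_permutation_invariance():
    rng = np.random.default_rng(2)
    table = rng.integers(1, 30, size=(3, 3))
    base = chi_square_independence(table)
    shuffled = chi_square_independence(table[[2, 0, 1]][:, [1, 2, 0]])
    assert shuffled.statistic == pytest.approx(base.statistic, abs=1e-12)


# ---------------------------------------------------------------------------
# Welch t


def test_welch_identical_groups():
    res = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.statistic == 0.0
    assert res.p_value == 1.0


def test_welch_separated_groups():
    rng = np.random.default_rng(0)
    a = rng.normal(0, 0.01, 4)
    b = rng.normal(10, 0.01, 4)
    assert welch_t_test(a, b).p_value < 1e-3


@pytest.mark.parametrize("seed", range(5))
def test_welch_matches_scipy(seed):
    rng = np.random.default_rng(seed)
    a = rng.normal(0, 1, 8)
    b = rng.normal(0.5, 2, 12)
    res = welch_t_test(a, b)
    ref = scipy.stats.ttest_ind(a, b, equal_var=False)
    assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
    assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)


def test_welch_requires_two_per_group():
    with pytest.raises(ValueError):
        welch_t_test([1.0], [2.0, 3.0])


# ---------------------------------------------------------------------------
# Mann-Whitney


def test_mann_whitney_exact_example():
    res = mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(0.1)  # 2 of C(6,3)=20 labelings as extreme


def test_mann_whitney_identical_multisets():
    assert mann_whitney_u([1, 2, 2, 3], [1, 2, 2, 3]).p_value == 1.0


@pytest.mark.parametrize("na, nb", [(3, 3), (4, 3), (4, 4), (2, 5)])
def test_mann_whitney_exact_matches_scipy_exhaustively(na, nb):
    """Every no-tie arrangement at small n agrees with scipy's exact p."""
    n = na + nb
    values = np.arange(1.0, n + 1.0)
    for positions in itertools.combinations(range(n), na):
        mask = np.zeros(n, dtype=bool)
        mask[list(positions)] = True
        a, b = values[mask], values[~mask]
        res = mann_whitney_u(a, b)
        ref = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)


@pytest.mark.parametrize("seed", range(5))
def test_mann_whitney_normal_approx_matches_scipy(seed):
    rng = np.random.default_rng(seed)
    a = rng.integers(0, 10, size=20).astype(float)
    b = rng.integers(0, 10, size=15).astype(float)
    res = mann_whitney_u(a, b)
    ref = scipy.stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg


def _bh_definition_oracle(p):
    """O(m^2) step-up straight from the definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    for i in range(m):
        candidates = [m * p[order[j]] / (j + 1) for j in range(i, m)]
        adjusted[order[i]] = min(1.0, min(candidates))
    return adjusted


def test_bh_known_vector():
    adj = bh_adjust([0.01, 0.02, 0.03, 0.04, 0.05])
    assert np.allclose(adj, 0.05)


def test_bh_single_value_identity():
    assert bh_adjust([0.2]).tolist() == [0.2]


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


@pytest.mark.parametrize("seed", range(10))
def test_bh_matches_definition_oracle(seed):
    rng = np.random.default_rng(seed)
    p = rng.uniform(size=rng.integers(1, 40))
    assert np.allclose(bh_adjust(p), _bh_definition_oracle(p), atol=1e-12)


@given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
def test_bh_properties(p):
    adj = bh_adjust(p)
    assert np.all(adj >= np.asarray(p) - 1e-15)  # never decreases a p-value
    assert np.all(adj <= 1.0)
    # permutation equivariance
    rng = np.random.default_rng(0)
    perm = rng.permutation(len(p))
    assert np.allclose(bh_adjust(np.asarray(p)[perm]), adj[perm], atol=1e-12)
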
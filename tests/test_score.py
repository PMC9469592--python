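"""z-standardization, the composite miRNA score and group discrimination."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

import dcismir as d
from dcismir.panel import MiRNAPanel, PanelMember
from dcismir.score import (
    mirna_composite_score,
    rank_extremity,
    score_group_discrimination,
    z_standardize,
)


def expr_frame(values, mirnas=None):
    values = np.asarray(values, dtype=float)
    mirnas = mirnas or [f"m{i}" for i in range(values.shape[0])]
    return pd.DataFrame(values, index=mirnas,
                        columns=[f"s{j}" for j in range(values.shape[1])])


def panel_of(directions):
    return MiRNAPanel(
        [PanelMember(f"m{i}", di) for i, di in enumerate(directions)]
    )


# ---------------------------------------------------------------------------
# z-standardization


def test_z_two_samples():
    z = z_standardize(expr_frame([[1.0, 3.0]]))
    assert np.allclose(z.z.values, [[-0.7071067811865475, 0.7071067811865475]])


def test_z_rows_have_mean_zero_sd_one():
    rng = np.random.default_rng(0)
    z = z_standardize(expr_frame(rng.normal(size=(5, 12))))
    assert np.allclose(z.z.mean(axis=1), 0.0, atol=1e-9)
    assert np.allclose(z.z.std(axis=1, ddof=1), 1.0, atol=1e-9)


def test_z_constant_row_excluded_with_warning():
    frame = expr_frame([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]])
    with pytest.warns(UserWarning, match="m1"):
        z = z_standardize(frame)
    assert z.excluded == ["m1"]
    assert list(z.z.index) == ["m0"]


@given(st.floats(0.1, 50.0), st.floats(-100.0, 100.0))
def test_z_affine_invariance(a, b):
    rng = np.random.default_rng(4)
    row = rng.normal(size=(1, 10))
    base = z_standardize(expr_frame(row)).z.values
    scaled = z_standardize(expr_frame(a * row + b)).z.values
    assert np.allclose(base, scaled, atol=1e-8)


# ---------------------------------------------------------------------------
# composite score


def test_single_down_mirna_negates_z():
    res = mirna_composite_score(expr_frame([[1.0, 3.0]]), panel_of(["down"]))
    assert np.allclose(res.scores.values, [0.7071067811865475, -0.7071067811865475])


def test_scores_sum_to_zero():
    rng = np.random.default_rng(2)
    res = mirna_composite_score(expr_frame(rng.normal(size=(6, 15))),
                                panel_of(["up", "down", "down", "up", "down", "up"]))
    assert res.scores.sum() == pytest.approx(0.0, abs=1e-9)


def test_sign_flip_identity():
    """Flipping one member's direction changes the score by -2 s_m z_m."""
    rng = np.random.default_rng(3)
    frame = expr_frame(rng.normal(size=(4, 10)))
    directions = ["down", "up", "down", "up"]
    base = mirna_composite_score(frame, panel_of(directions))
    flipped_dirs = ["up"] + directions[1:]
    flipped = mirna_composite_score(frame, panel_of(flipped_dirs))
    z_row = base.z.loc["m0"]
    s_m = -1.0  # original direction "down"
    assert np.allclose(flipped.scores, base.scores - 2 * s_m * z_row, atol=1e-9)


def test_ddct_scale_equivalence():
    rng = np.random.default_rng(5)
    ddct = expr_frame(rng.normal(size=(5, 12)))
    directions = ["down"] * 5
    on_ddct = mirna_composite_score(ddct, panel_of(directions), scale="delta_delta_ct")
    on_expr = mirna_composite_score(-ddct, panel_of(directions), scale="expression")
    assert np.allclose(on_ddct.scores, on_expr.scores, atol=1e-9)


def test_panel_validation():
    frame = expr_frame([[1.0, 2.0, 3.0]])
    with pytest.raises(KeyError):
        mirna_composite_score(frame, MiRNAPanel([PanelMember("absent", "down")]))
    with pytest.raises(ValueError):
        mirna_composite_score(frame, MiRNAPanel([]))


def test_composite_affine_invariance_per_mirna():
    rng = np.random.default_rng(6)
    frame = expr_frame(rng.normal(size=(3, 8)))
    base = mirna_composite_score(frame, panel_of(["down", "up", "down"]))
    transformed = frame.mul([2.0, 0.5, 7.0], axis=0).add([10.0, -3.0, 0.1], axis=0)
    again = mirna_composite_score(transformed, panel_of(["down", "up", "down"]))
    assert np.allclose(base.scores, again.scores, atol=1e-9)


def test_monotone_coupling_with_noiseless_decreasing_panel():
    """If every panel miRNA strictly decreases in the DX score, the composite
    score strictly increases with it."""
    dx = np.array([5.0, 12.0, 30.0, 41.0, 55.0, 70.0])
    frame = expr_frame(np.vstack([-dx * 0.5 + 20, -dx * 2.0 + 100, np.exp(-dx / 30)]))
    res = mirna_composite_score(frame, panel_of(["down", "down", "down"]))
    assert np.all(np.diff(res.scores.values) > 0)


# ---------------------------------------------------------------------------
# correlation and discrimination


def test_score_vs_dx_self_correlation(sim_reference):
    dx = sim_reference.clinical.dx_scores()
    res = d.score_vs_dx_correlation(dx, dx)
    assert res.estimate == pytest.approx(1.0)


def test_composite_score_correlates_with_dx_on_planted_cohort(sim_reference, norm_reference):
    comp = d.CompositeScoreModel(
        norm_reference.log2_expr, sim_reference.truth.default_panel()
    ).fit()
    res = comp.correlate_with(sim_reference.clinical.dx_scores())
    assert res.estimate > 0.5
    # discrimination: planted down/up panel pulls int+high away from low
    tests = comp.discriminate(sim_reference.clinical.risk_groups())
    ((_, result),) = tests.items()
    assert result["mann_whitney_u"].p_value < 0.05
    assert result["direction"] == "up"


def test_noise_panel_score_uncorrelated_with_dx(sim_reference, norm_reference):
    truth = sim_reference.truth
    null_mirnas = [
        m for i, m in enumerate(truth.mirna_ids)
        if not (truth.is_score_assoc[i] or truth.is_age_assoc[i])
    ][:10]
    panel = MiRNAPanel([PanelMember(m, "down") for m in null_mirnas])
    comp = d.CompositeScoreModel(norm_reference.log2_expr, panel).fit()
    res = comp.correlate_with(sim_reference.clinical.dx_scores())
    assert abs(res.estimate) < 2.58 / np.sqrt(res.n)


def test_discrimination_identical_scores():
    scores = pd.Series(np.tile([1.0, 2.0, 3.0, 4.0], 2),
                       index=[f"s{i}" for i in range(8)])
    groups = pd.Series(["low"] * 4 + ["high"] * 4, index=scores.index)
    ((_, res),) = score_group_discrimination(scores, groups).items()
    assert res["welch_t"].p_value == pytest.approx(1.0)


def test_discrimination_null_pvalues_uniform():
    """Welch p-values under label permutation look U(0,1) (KS at 0.01)."""
    rng = np.random.default_rng(10)
    scores = pd.Series(rng.normal(size=30), index=[f"s{i}" for i in range(30)])
    labels = np.array(["low"] * 15 + ["high"] * 15)
    pvals = []
    for _ in range(200):
        groups = pd.Series(rng.permutation(labels), index=scores.index)
        ((_, res),) = score_group_discrimination(scores, groups).items()
        pvals.append(res["welch_t"].p_value)
    assert scipy.stats.kstest(pvals, "uniform").pvalue > 0.01


def test_discrimination_pairwise_grouping(sim_reference, norm_reference):
    comp = d.CompositeScoreModel(
        norm_reference.log2_expr, sim_reference.truth.default_panel()
    ).fit()
    tests = comp.discriminate(sim_reference.clinical.risk_groups(), grouping="pairwise")
    assert set(tests) == {
        ("low", "intermediate"), ("intermediate", "high"), ("low", "high")
    }


def test_discrimination_rejects_tiny_groups():
    scores = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
    groups = pd.Series(["low", "low", "high"], index=scores.index)
    with pytest.raises(ValueError):
        score_group_discrimination(scores, groups)


# ---------------------------------------------------------------------------
# within-group ranking


def test_rank_extremity_orders_descending():
    scores = pd.Series({"a": 0.5, "b": 2.0, "c": -1.0, "d": 9.0})
    groups = pd.Series({"a": "low", "b": "low", "c": "low", "d": "high"})
    assert rank_extremity(scores, groups, "b") == 1
    assert rank_extremity(scores, groups, "a") == 2
    assert rank_extremity(scores, groups, "c") == 3
    assert rank_extremity(scores, groups, "d") == 1  # alone in its group


def test_rank_extremity_ties_break_by_sample_order():
    scores = pd.Series({"a": 1.0, "b": 1.0, "c": 1.0})
    groups = pd.Series({"a": "low", "b": "low", "c": "low"})
    assert [rank_extremity(scores, groups, s) for s in ["a", "b", "c"]] == [1, 2, 3]


def test_rank_extremity_unknown_sample():
    with pytest.raises(KeyError):
        rank_extremity(pd.Series({"a": 1.0}), pd.Series({"a": "low"}), "zz")
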
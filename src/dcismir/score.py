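"""The composite "miRNA score": a signed sum of z-standardized expression.

For each panel miRNA m with screen direction d_m, expression is
z-standardized across samples and summed with sign s_m = +1 for "up" and
-1 for "down" (on an expression scale):

    score_i = sum_m s_m * z_{m,i}

so the score rises with risk: a downregulated miRNA contributes positively
when its expression is below the cohort mean. On the ddCt scale (where a
larger value means *less* expression) the signs are flipped internally, so
scoring ddCt values and scoring -ddCt gives identical results.

Because each z row has zero mean, scores always sum to zero across samples;
the score is a relative, within-cohort quantity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import MiRNAPanel
from .stats import CorrelationResult, TestResult, mann_whitney_u, pearson_r, welch_t_test

__all__ = [
    "ZMatrix",
    "CompositeScoreResults",
    "CompositeScoreModel",
    "z_standardize",
    "mirna_composite_score",
    "score_vs_dx_correlation",
    "score_group_discrimination",
    "rank_extremity",
]

SCALES = ("expression", "delta_delta_ct")


@dataclass
class ZMatrix:
    """Row-wise z-standardized expression (sample SD, n-1 denominator).

    Constant rows cannot be standardized; they are listed in ``excluded``
    and dropped from ``z`` with a warning rather than raising, so panel
    scoring can proceed on the remaining members.
    """

    z: pd.DataFrame
    excluded: list[str] = field(default_factory=list)


def z_standardize(expr: pd.DataFrame, ddof: int = 1) -> ZMatrix:
    """Standardize each row of a miRNA x sample matrix to mean 0, SD 1."""
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 samples to standardize")
    values = expr.values.astype(float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=ddof, keepdims=True)
    constant = (sd == 0).ravel()
    excluded = list(expr.index[constant])
    if excluded:
        warnings.warn(
            f"excluding constant row(s) from z-standardization: {excluded}",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (values - mean) / sd
    out = pd.DataFrame(z, index=expr.index, columns=expr.columns)
    return ZMatrix(z=out[~constant], excluded=excluded)


@dataclass
class CompositeScoreResults:
    """Per-sample composite miRNA scores plus the panel that produced them."""

    scores: pd.Series
    panel: MiRNAPanel
    scale: str
    z: pd.DataFrame
    source: str = "expression-matrix"

    def correlate_with(self, dx_scores: pd.Series) -> CorrelationResult:
        return score_vs_dx_correlation(self.scores, dx_scores)

    def discriminate(
        self, groups: pd.Series, grouping: str = "low_vs_int_high"
    ) -> dict:
        return score_group_discrimination(self.scores, groups, grouping)

    def rank_extremity(self, groups: pd.Series, sample_id: str) -> int:
        return rank_extremity(self.scores, groups, sample_id)

    def summary(self) -> str:
        s = self.scores
        return (
            f"Composite miRNA score ({len(self.panel)}-miRNA panel, "
            f"{self.scale} scale, n = {len(s)})\n"
            f"  mean {s.mean():+.3g}  sd {s.std(ddof=1):.3f}  "
            f"range [{s.min():.3f}, {s.max():.3f}]"
        )

    def plot_by_group(self, groups: pd.Series, ax=None):
        """Box plot of composite scores per risk group."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 3))
        order = [g for g in ("low", "intermediate", "high") if g in set(groups)]
        data = [self.scores[groups[groups == g].index] for g in order]
        ax.boxplot(data, tick_labels=order)
        ax.set_ylabel("composite miRNA score")
        ax.set_xlabel("risk group")
        return ax


class CompositeScoreModel:
    """Builds composite miRNA scores from an expression (or ddCt) matrix.

    Parameters
    ----------
    expr : pd.DataFrame
        miRNA x sample values; must contain every panel member's row.
    panel : MiRNAPanel
    scale : {"expression", "delta_delta_ct"}
        On the ddCt scale larger values mean lower expression, so member
        signs are flipped internally.
    """

    def __init__(self, expr: pd.DataFrame, panel: MiRNAPanel, scale: str = "expression"):
        if scale not in SCALES:
            raise ValueError(f"scale must be one of {SCALES}")
        if len(panel) == 0:
            raise ValueError("panel is empty")
        missing = [m.mirna_id for m in panel if m.mirna_id not in expr.index]
        if missing:
            raise KeyError(f"panel member(s) absent from expression matrix: {missing}")
        self.expr = expr
        self.panel = panel
        self.scale = scale

    def fit(self) -> CompositeScoreResults:
        sub = self.expr.loc[self.panel.mirna_ids]
        zm = z_standardize(sub)
        flip = -1.0 if self.scale == "delta_delta_ct" else 1.0
        signs = pd.Series(
            {m.mirna_id: flip * m.sign for m in self.panel}, dtype=float
        ).reindex(zm.z.index)
        scores = zm.z.mul(signs, axis=0).sum(axis=0)
        scores.name = "mirna_score"
        return CompositeScoreResults(
            scores=scores, panel=self.panel, scale=self.scale, z=zm.z
        )


def mirna_composite_score(
    expr: pd.DataFrame, panel: MiRNAPanel, scale: str = "expression"
) -> CompositeScoreResults:
    """Functional wrapper around :class:`CompositeScoreModel`."""
    return CompositeScoreModel(expr, panel, scale).fit()


def score_vs_dx_correlation(scores: pd.Series, dx_scores: pd.Series) -> CorrelationResult:
    """Pearson correlation between composite scores and Oncotype DX scores."""
    common = scores.index.intersection(dx_scores.index)
    if len(common) < 3:
        raise ValueError("need at least 3 paired samples")
    return pearson_r(scores.loc[common].values, dx_scores.loc[common].astype(float).values)


def _pair_tests(a: np.ndarray, b: np.ndarray) -> dict:
    return {
        "welch_t": welch_t_test(a, b),
        "mann_whitney_u": mann_whitney_u(a, b),
        "direction": "up" if a.mean() < b.mean() else ("down" if a.mean() > b.mean() else "none"),
        "n": (len(a), len(b)),
    }


def score_group_discrimination(
    scores: pd.Series, groups: pd.Series, grouping: str = "low_vs_int_high"
) -> dict:
    """Welch t and Mann-Whitney comparisons of composite scores between groups.

    grouping = "low_vs_int_high" pools intermediate with high; "pairwise"
    compares low-intermediate, intermediate-high and low-high. The
    ``direction`` entry is "up" when the second group's mean score exceeds
    the first's (risk-increasing orientation).
    """
    common = scores.index.intersection(groups.index)
    s = scores.loc[common]
    g = groups.loc[common]

    def values(*names):
        return s[g.isin(names)].values

    out: dict = {}
    if grouping == "low_vs_int_high":
        pairs = [(("low",), ("intermediate", "high"))]
    elif grouping == "pairwise":
        pairs = [
            (("low",), ("intermediate",)),
            (("intermediate",), ("high",)),
            (("low",), ("high",)),
        ]
    else:
        raise ValueError("grouping must be 'low_vs_int_high' or 'pairwise'")
    for left, right in pairs:
        a, b = values(*left), values(*right)
        if len(a) < 2 or len(b) < 2:
            raise ValueError(
                f"group comparison {'+'.join(left)} vs {'+'.join(right)} "
                "needs at least 2 samples per side"
            )
        out[("+".join(left), "+".join(right))] = _pair_tests(a, b)
    return out


def rank_extremity(scores: pd.Series, groups: pd.Series, sample_id: str) -> int:
    """Rank of a sample within its risk group, 1 = highest composite score
    (most extreme toward high risk). Ties break by sample order."""
    if sample_id not in scores.index:
        raise KeyError(f"unknown sample {sample_id!r}")
    group = groups.loc[sample_id]
    members = [sid for sid in scores.index if groups.get(sid) == group]
    ordered = sorted(
        members, key=lambda sid: (-scores.loc[sid], members.index(sid))
    )
    return ordered.index(sample_id) + 1
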
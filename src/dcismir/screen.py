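"""Count-matrix normalization and genome-wide correlation screens.

The screens mirror a two-arm design: per-miRNA Pearson correlation of log2
normalized expression against the continuous Oncotype DX DCIS score, and
per-miRNA Spearman correlation against patient age. Raw p-values are
Benjamini-Hochberg adjusted across all testable miRNAs; direction labels
follow the field's reading ("down" = expression falls as score/age rises).

An optional batch adjustment residualizes both the expression rows and the
covariate on library-batch indicators before correlating (partial
correlation), since multiplexed small-RNA libraries are a known batch axis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import t as _t_dist

from .panel import MiRNAPanel, PanelMember
from .stats import bh_adjust, midrank

__all__ = [
    "CountMatrix",
    "NormalizedMatrix",
    "ScreenResults",
    "CorrelationScreen",
    "normalize_total_counts",
    "abundance_percent",
    "screen_vs_dx_score",
    "screen_vs_age",
    "bin_age",
    "select_panel",
    "AGE_GROUP_LABELS",
]

AGE_GROUP_LABELS = {1: "<=55", 2: "56-70", 3: ">70"}


@dataclass
class CountMatrix:
    """miRNA x sample matrix of non-negative integer read counts."""

    counts: pd.DataFrame
    batch: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValueError("mirna_ids and sample_ids must be unique")
        if self.batch is not None:
            missing = [s for s in self.counts.columns if s not in self.batch.index]
            if missing:
                raise ValueError(f"samples without a batch label: {missing}")
            self.batch = self.batch.reindex(self.counts.columns)

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @classmethod
    def from_tsv(cls, path, batch_csv=None) -> "CountMatrix":
        """Read a counts TSV (first column ``mirna_id``) plus an optional
        side-car CSV with columns ``sample_id,batch``."""
        counts = pd.read_csv(path, sep="\t", index_col="mirna_id")
        batch = None
        if batch_csv is not None:
            bdf = pd.read_csv(batch_csv)
            batch = bdf.set_index("sample_id")["batch"]
        return cls(counts=counts, batch=batch)

    def to_tsv(self, path, batch_csv=None) -> None:
        self.counts.rename_axis("mirna_id").to_csv(path, sep="\t")
        if batch_csv is not None and self.batch is not None:
            self.batch.rename_axis("sample_id").rename("batch").reset_index().to_csv(
                batch_csv, index=False
            )


@dataclass
class NormalizedMatrix:
    """Total-count normalized expression.

    ``fractions`` columns each sum to one; ``log2_expr`` is
    log2(fraction * scale + pseudocount) — with the defaults, log2(CPM + 1).
    The transform is a function of the fractions only, so it is exactly
    invariant to per-sample sequencing depth.
    """

    fractions: pd.DataFrame
    log2_expr: pd.DataFrame
    scale: float = 1e6
    pseudocount: float = 1.0
    batch: pd.Series | None = None

    @property
    def sample_ids(self) -> list[str]:
        return list(self.fractions.columns)

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.fractions.index)


def normalize_total_counts(
    m: CountMatrix | pd.DataFrame, scale: float = 1e6, pseudocount: float = 1.0
) -> NormalizedMatrix:
    """Normalize each sample to its total count; derive log2 expression."""
    counts = m.counts if isinstance(m, CountMatrix) else m
    batch = m.batch if isinstance(m, CountMatrix) else None
    totals = counts.sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"zero total count for sample(s): {list(zero.index)}")
    fractions = counts / totals
    log2_expr = np.log2(fractions * scale + pseudocount)
    return NormalizedMatrix(fractions, log2_expr, scale, pseudocount, batch)


def abundance_percent(m: NormalizedMatrix, mirna: str, samples=None) -> float:
    """Mean percent of total reads attributed to one miRNA over a sample set."""
    if mirna not in m.fractions.index:
        raise KeyError(f"unknown miRNA {mirna!r}")
    row = m.fractions.loc[mirna]
    if samples is not None:
        row = row.loc[list(samples)]
    return 100.0 * float(row.mean())


def bin_age(age: int) -> int:
    """Age-group bin: 1 if <= 55, 2 if 56-70, 3 if > 70."""
    if age <= 0:
        raise ValueError("age must be positive")
    if age <= 55:
        return 1
    if age <= 70:
        return 2
    return 3


# ---------------------------------------------------------------------------
# correlation screen


def _residualize(values: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Project rows of ``values`` off the column space of ``design``."""
    coef, *_ = np.linalg.lstsq(design, values.T, rcond=None)
    return values - (design @ coef).T


def _batch_design(batch: pd.Series) -> np.ndarray:
    dummies = pd.get_dummies(batch, dtype=float)
    return np.column_stack([np.ones(len(batch)), dummies.values[:, 1:]])


@dataclass
class ScreenResults:
    """Per-miRNA screen output.

    ``table`` columns: estimate, p_value, adj_p_value, direction, testable,
    mean_abundance_pct. Untestable rows (constant expression) carry NaN
    statistics and are excluded from the BH family.
    """

    table: pd.DataFrame
    method: str
    covariate_name: str
    n_samples: int
    batch_adjusted: bool = False

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        sig = self.table[self.table["testable"] & (self.table["adj_p_value"] < alpha)]
        return sig.sort_values("adj_p_value")

    def summary(self, alpha: float = 0.05) -> str:
        sig = self.significant(alpha)
        lines = [
            f"Correlation screen ({self.method}) vs {self.covariate_name}",
            f"  samples: {self.n_samples}   miRNAs: {len(self.table)} "
            f"(testable: {int(self.table['testable'].sum())})"
            + ("   [batch-adjusted]" if self.batch_adjusted else ""),
            f"  significant at BH-adjusted p < {alpha:g}: {len(sig)}",
        ]
        if len(sig):
            lines.append(sig.round(4).to_string())
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.rename_axis("mirna_id").to_csv(path, sep="\t")


class CorrelationScreen:
    """Vectorized per-miRNA correlation screen.

    Parameters
    ----------
    norm : NormalizedMatrix
        Total-count normalized expression.
    covariate : pd.Series
        Numeric per-sample covariate (Oncotype DX DCIS score, or age)
        indexed by sample id; samples missing the covariate are dropped.
    method : {"pearson", "spearman"}
    adjust_batch : bool
        Partial out library-batch indicators from both expression and the
        covariate before correlating (requires batch labels).
    """

    def __init__(
        self,
        norm: NormalizedMatrix,
        covariate: pd.Series,
        method: str = "pearson",
        adjust_batch: bool = False,
        covariate_name: str | None = None,
    ):
        if method not in ("pearson", "spearman"):
            raise ValueError("method must be 'pearson' or 'spearman'")
        samples = [s for s in norm.sample_ids if s in covariate.index]
        if len(samples) < 3:
            raise ValueError("need at least 3 samples with the covariate")
        if adjust_batch and norm.batch is None:
            raise ValueError("batch adjustment requested but no batch labels")
        self.norm = norm
        self.samples = samples
        self.covariate = covariate.loc[samples].astype(float)
        self.method = method
        self.adjust_batch = adjust_batch
        self.covariate_name = covariate_name or (covariate.name or "covariate")

    def fit(self) -> ScreenResults:
        X = self.norm.log2_expr[self.samples].values.astype(float)
        y = self.covariate.values.copy()
        n = len(self.samples)

        # rank-transform first for Spearman: correlation of mid-ranks
        if self.method == "spearman":
            X = np.apply_along_axis(midrank, 1, X)
            y = midrank(y)

        df_loss = 2
        if self.adjust_batch:
            design = _batch_design(self.norm.batch.loc[self.samples])
            X = _residualize(X, design)
            y = _residualize(y[None, :], design)[0]
            df_loss += design.shape[1] - 1

        xc = X - X.mean(axis=1, keepdims=True)
        yc = y - y.mean()
        sx = np.sqrt((xc**2).sum(axis=1))
        sy = math.sqrt(float(yc @ yc))
        testable = (sx > 0) & (sy > 0) & (n > df_loss)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (xc @ yc) / (sx * sy)
        r = np.clip(r, -1.0, 1.0)
        r[~testable] = np.nan

        df = n - df_loss
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = r * np.sqrt(df / (1.0 - r**2))
        p = np.where(np.abs(r) >= 1.0, 0.0, 2.0 * _t_dist.sf(np.abs(tstat), df))
        p = np.minimum(p, 1.0)
        p[~testable] = np.nan

        adj = np.full(len(r), np.nan)
        if testable.any():
            adj[testable] = bh_adjust(p[testable])

        direction = np.where(r >= 0, "up", "down")
        table = pd.DataFrame(
            {
                "estimate": r,
                "p_value": p,
                "adj_p_value": adj,
                "direction": np.where(testable, direction, ""),
                "testable": testable,
                "mean_abundance_pct": 100.0
                * self.norm.fractions[self.samples].mean(axis=1).values,
            },
            index=self.norm.fractions.index,
        )
        return ScreenResults(
            table=table,
            method=self.method,
            covariate_name=self.covariate_name,
            n_samples=n,
            batch_adjusted=self.adjust_batch,
        )


def screen_vs_dx_score(
    m: NormalizedMatrix, scores: pd.Series, adjust_batch: bool = False
) -> ScreenResults:
    """Pearson screen of log2 expression against the Oncotype DX DCIS score."""
    return CorrelationScreen(
        m, scores, method="pearson", adjust_batch=adjust_batch, covariate_name="dx_score"
    ).fit()


def screen_vs_age(
    m: NormalizedMatrix, ages: pd.Series, adjust_batch: bool = False
) -> ScreenResults:
    """Spearman screen of log2 expression against patient age."""
    return CorrelationScreen(
        m, ages, method="spearman", adjust_batch=adjust_batch, covariate_name="age"
    ).fit()


def _top_hits(screen: ScreenResults, alpha: float, k: int) -> pd.DataFrame:
    sig = screen.significant(alpha)
    sig = sig.assign(abs_estimate=sig["estimate"].abs()).sort_values(
        ["adj_p_value", "abs_estimate"], ascending=[True, False]
    )
    return sig.head(k)


def select_panel(
    score_screen: ScreenResults,
    age_screen: ScreenResults,
    alpha: float = 0.05,
    k_score: int = 10,
    k_age: int = 9,
) -> MiRNAPanel:
    """Union of the top score- and age-associated miRNAs passing BH alpha.

    Provenance marks which screen nominated each member; on a double hit the
    direction label comes from the score screen.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if list(score_screen.table.index) != list(age_screen.table.index):
        raise ValueError("screens cover different miRNA universes")
    score_top = _top_hits(score_screen, alpha, k_score)
    age_top = _top_hits(age_screen, alpha, k_age)
    members = []
    for mirna in score_top.index:
        prov = "both" if mirna in age_top.index else "score"
        members.append(PanelMember(mirna, score_top.loc[mirna, "direction"], prov))
    for mirna in age_top.index:
        if mirna not in score_top.index:
            members.append(PanelMember(mirna, age_top.loc[mirna, "direction"], "age"))
    return MiRNAPanel(members)
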
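"""RT-qPCR relative quantification by the comparative ddCt method.

Triplicate Ct values are averaged per (sample, miRNA) with a simple QC rule
(replicate SD threshold; missing replicates flagged), normalized to an
endogenous control gene (dCt = mean Ct - control mean Ct), then referenced
to the low-risk group mean (ddCt = dCt - mean dCt over the reference
group). Relative expression is 2^-ddCt, assuming perfect amplification
efficiency (a doubling per cycle), so a 2-fold expression difference is
exactly one ddCt cycle.

Undetected replicates are treated as missing, never imputed to a maximum
cycle number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import CorrelationResult, bh_adjust, mann_whitney_u, pearson_r, welch_t_test

__all__ = [
    "CtTable",
    "DdCtResults",
    "DeltaDeltaCtModel",
    "MissingControlError",
    "aggregate_triplicates",
    "delta_ct",
    "delta_delta_ct",
    "compare_groups_ddct",
    "ngs_qpcr_concordance",
    "DEFAULT_CONTROL_GENE",
]

logger = logging.getLogger(__name__)

DEFAULT_CONTROL_GENE = "RNU6B"
QC_PASS = "pass"
QC_PARTIAL = "partial"
QC_DISCORDANT = "discordant"
QC_UNDETECTED = "undetected"


class MissingControlError(ValueError):
    """A sample lacks a usable control-gene Ct."""


@dataclass
class CtTable:
    """Long-format Ct measurements.

    ``data`` columns: sample_id, mirna_id, replicate (1-based), ct (NaN for
    an undetected replicate). At most 3 replicates per (sample, miRNA);
    detected Ct values must be positive.
    """

    data: pd.DataFrame
    control_gene: str = DEFAULT_CONTROL_GENE

    def __post_init__(self) -> None:
        required = {"sample_id", "mirna_id", "replicate", "ct"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"Ct table needs columns {sorted(required)}")
        detected = self.data["ct"].dropna()
        if (detected <= 0).any():
            raise ValueError("detected Ct values must be positive")
        reps = self.data.groupby(["sample_id", "mirna_id"])["replicate"].count()
        if (reps > 3).any():
            raise ValueError("more than 3 replicates for some (sample, miRNA)")

    @classmethod
    def from_csv(cls, path, control_gene: str = DEFAULT_CONTROL_GENE) -> "CtTable":
        df = pd.read_csv(path)
        df["ct"] = pd.to_numeric(df["ct"], errors="coerce")
        return cls(data=df, control_gene=control_gene)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @property
    def mirna_ids(self) -> list[str]:
        return sorted(set(self.data["mirna_id"]) - {self.control_gene})

    @property
    def sample_ids(self) -> list[str]:
        return sorted(set(self.data["sample_id"]))


def aggregate_triplicates(t: CtTable, sd_threshold: float = 0.5) -> pd.DataFrame:
    """Mean Ct per (sample, miRNA) with a QC flag.

    qc_flag: "pass" (3 concordant replicates), "partial" (< 3 detected),
    "discordant" (replicate SD > sd_threshold cycles), "undetected" (no
    detected replicate; mean is NaN and the row is excluded downstream).
    """
    grouped = t.data.groupby(["sample_id", "mirna_id"])["ct"]
    agg = grouped.agg(
        mean_ct="mean", ct_sd=lambda v: v.std(ddof=1), n_detected="count"
    )
    agg["ct_sd"] = agg["ct_sd"].fillna(0.0)
    flags = np.where(
        agg["n_detected"] == 0,
        QC_UNDETECTED,
        np.where(
            agg["ct_sd"] > sd_threshold,
            QC_DISCORDANT,
            np.where(agg["n_detected"] < 3, QC_PARTIAL, QC_PASS),
        ),
    )
    agg["qc_flag"] = flags
    undetected = agg[agg["qc_flag"] == QC_UNDETECTED]
    if len(undetected):
        logger.warning(
            "%d (sample, miRNA) pairs had no detected replicate and are excluded",
            len(undetected),
        )
    return agg


def delta_ct(agg: pd.DataFrame, control_gene: str = DEFAULT_CONTROL_GENE) -> pd.DataFrame:
    """dCt = target mean Ct - control-gene mean Ct, per sample.

    Returns a sample x miRNA matrix (control column removed). Raises
    :class:`MissingControlError` naming any sample whose control gene is
    absent or undetected.
    """
    mean_ct = agg["mean_ct"].unstack("mirna_id")
    if control_gene not in mean_ct.columns:
        raise MissingControlError(f"control gene {control_gene!r} absent from table")
    control = mean_ct[control_gene]
    bad = control[control.isna()].index.tolist()
    if bad:
        raise MissingControlError(f"no detected control Ct for sample(s): {bad}")
    return mean_ct.drop(columns=[control_gene]).sub(control, axis=0)


@dataclass
class DdCtResults:
    """ddCt quantification relative to a reference sample group.

    ``delta_delta_ct`` and ``fold_change`` are sample x miRNA matrices;
    fold_change = 2^-ddCt. By construction the reference group's mean ddCt
    is zero (geometric-mean fold change 1) for every miRNA.
    """

    delta_ct: pd.DataFrame
    delta_delta_ct: pd.DataFrame
    fold_change: pd.DataFrame
    reference_samples: list[str]
    qc: pd.DataFrame | None = None

    def compare_groups(
        self, groups: pd.Series, primary: str = "mann_whitney_u"
    ) -> pd.DataFrame:
        return compare_groups_ddct(self, groups, primary=primary)

    def summary(self) -> str:
        n, m = self.delta_delta_ct.shape
        return (
            f"ddCt quantification: {n} samples x {m} miRNAs, "
            f"{len(self.reference_samples)} reference (low-risk) samples\n"
            f"  median fold change per miRNA:\n"
            f"{self.fold_change.median().round(3).to_string()}"
        )

    def to_tsv(self, path) -> None:
        long = (
            self.delta_delta_ct.stack()
            .rename("delta_delta_ct")
            .to_frame()
            .join(self.delta_ct.stack().rename("delta_ct"))
            .join(self.fold_change.stack().rename("fold_change"))
            .reset_index()
        )
        long.to_csv(path, sep="\t", index=False)


def delta_delta_ct(dct: pd.DataFrame, reference_samples) -> DdCtResults:
    """ddCt_i = dCt_i - mean(dCt over the reference samples); fold = 2^-ddCt."""
    reference_samples = [s for s in reference_samples]
    if not reference_samples:
        raise ValueError("reference sample set is empty")
    missing = [s for s in reference_samples if s not in dct.index]
    if missing:
        raise ValueError(f"reference sample(s) absent from dCt table: {missing}")
    ref_mean = dct.loc[reference_samples].mean(axis=0)
    ddct = dct.sub(ref_mean, axis=1)
    return DdCtResults(
        delta_ct=dct,
        delta_delta_ct=ddct,
        fold_change=2.0 ** (-ddct),
        reference_samples=reference_samples,
    )


class DeltaDeltaCtModel:
    """End-to-end ddCt quantification bound to a clinical grouping.

    Aggregates triplicates, subtracts the endogenous control, and
    references ddCt to the given risk group (default: the low-risk group,
    the comparator used for all reported fold changes).
    """

    def __init__(
        self,
        ct_table: CtTable,
        groups: pd.Series,
        reference_group: str = "low",
        sd_threshold: float = 0.5,
    ):
        self.ct_table = ct_table
        self.groups = groups
        self.reference_group = reference_group
        self.sd_threshold = sd_threshold

    def fit(self) -> DdCtResults:
        agg = aggregate_triplicates(self.ct_table, self.sd_threshold)
        dct = delta_ct(agg, self.ct_table.control_gene)
        reference = [
            s
            for s in dct.index
            if self.groups.get(s) == self.reference_group
        ]
        if not reference:
            raise ValueError(
                f"no samples in reference group {self.reference_group!r}"
            )
        res = delta_delta_ct(dct, reference)
        res.qc = agg
        return res


def compare_groups_ddct(
    res: DdCtResults | pd.DataFrame,
    groups: pd.Series,
    primary: str = "mann_whitney_u",
) -> pd.DataFrame:
    """Per-miRNA low vs intermediate+high comparison of ddCt values.

    Reports Welch t and Mann-Whitney p-values; ``p_primary`` (default the
    Mann-Whitney p) is BH-adjusted across the panel. ``direction`` is the
    expression change in the pooled intermediate/high group relative to
    low: "down" when mean ddCt is higher there (less expression).
    """
    if primary not in ("mann_whitney_u", "welch_t"):
        raise ValueError("primary must be 'mann_whitney_u' or 'welch_t'")
    ddct = res.delta_delta_ct if isinstance(res, DdCtResults) else res
    common = ddct.index.intersection(groups.index)
    ddct = ddct.loc[common]
    g = groups.loc[common]
    low = g[g == "low"].index
    rest = g[g.isin(["intermediate", "high"])].index
    if len(low) < 2 or len(rest) < 2:
        raise ValueError("need at least 2 samples per group")
    rows = []
    for mirna in ddct.columns:
        a = ddct.loc[low, mirna].dropna().values
        b = ddct.loc[rest, mirna].dropna().values
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"miRNA {mirna!r}: fewer than 2 usable values per group")
        wt = welch_t_test(a, b)
        mw = mann_whitney_u(a, b)
        diff = float(b.mean() - a.mean())  # ddCt up = expression down
        rows.append(
            {
                "mirna_id": mirna,
                "mean_ddct_low": float(a.mean()),
                "mean_ddct_int_high": float(b.mean()),
                "direction": "down" if diff > 0 else ("up" if diff < 0 else "none"),
                "welch_t_stat": wt.statistic,
                "welch_t_p": wt.p_value,
                "mann_whitney_u_stat": mw.statistic,
                "mann_whitney_u_p": mw.p_value,
            }
        )
    table = pd.DataFrame(rows).set_index("mirna_id")
    table["p_primary"] = table[
        "mann_whitney_u_p" if primary == "mann_whitney_u" else "welch_t_p"
    ]
    table["adj_p_primary"] = bh_adjust(table["p_primary"].values)
    return table


def ngs_qpcr_concordance(
    log2_expr: pd.DataFrame,
    dct: pd.DataFrame,
    orientation: str = "neg_delta_ct",
) -> CorrelationResult:
    """Pearson concordance of sequencing expression with qPCR quantification.

    Pairs log2 NGS expression with -dCt (default) over all shared
    (sample, miRNA) cells, so that agreement between the platforms appears
    as a positive r (abundance and Ct are inversely related). Pass
    ``orientation="delta_ct"`` for the raw-Ct orientation (sign flips).
    """
    if orientation not in ("neg_delta_ct", "delta_ct"):
        raise ValueError("orientation must be 'neg_delta_ct' or 'delta_ct'")
    # dct is sample x miRNA; expression matrix is miRNA x sample
    shared_m = [m for m in log2_expr.index if m in dct.columns]
    shared_s = [s for s in log2_expr.columns if s in dct.index]
    x = log2_expr.loc[shared_m, shared_s].T.stack()
    y = dct.loc[shared_s, shared_m].stack()
    paired = pd.concat([x.rename("ngs"), y.rename("dct")], axis=1).dropna()
    if len(paired) < 3:
        raise ValueError("need at least 3 paired (sample, miRNA) observations")
    sign = -1.0 if orientation == "neg_delta_ct" else 1.0
    return pearson_r(paired["ngs"].values, sign * paired["dct"].values)
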
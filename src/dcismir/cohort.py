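"""Clinical cohort table: parsing, risk-group stratification, summaries.

The packaged example cohort is a 41-patient DCIS series in which every
lesion was scored with the Oncotype DX DCIS assay (integer score 0-100).
Scores stratify patients into low (< 39), intermediate (39-54) and high
(>= 55) recurrence-risk groups. Two ages are boundary-coded in the source
table ("<=30", ">=80") and are carried with an explicit censor flag;
cohort summaries use the boundary value.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterator

import numpy as np
import pandas as pd

from .stats import ContingencyResult, chi_square_independence

__all__ = [
    "CensoredAge",
    "ClinicalRecord",
    "CohortTable",
    "GroupCounts",
    "AgeSummary",
    "ClinicalSchemaError",
    "ClinicalRowError",
    "RISK_GROUPS",
    "code_age",
    "assign_risk_group",
    "parse_clinical_table",
    "load_example_cohort",
    "risk_group_counts",
    "cohort_age_summary",
    "grade_group_contingency",
]

RISK_GROUPS = ("low", "intermediate", "high")

REQUIRED_COLUMNS = (
    "patient_id",
    "dx_score",
    "age",
    "nuclear_grade",
    "follow_up_years",
    "treatment",
    "recurrence",
)

_MISSING_TOKENS = {"", "na", "n/a", "-", "–", "mx"}


class ClinicalSchemaError(ValueError):
    """The clinical CSV is missing required structure (columns, any rows)."""


class ClinicalRowError(ValueError):
    """A specific row of the clinical CSV could not be decoded."""


@dataclass(frozen=True)
class CensoredAge:
    """Age in whole years, possibly boundary-coded.

    ``censor`` is "at_most" for entries like "<=30", "at_least" for ">=80",
    "none" otherwise. ``value`` is always the boundary code itself, which is
    the value used in all cohort summaries.
    """

    value: int
    censor: str = "none"

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("age must be positive")
        if self.censor not in ("none", "at_most", "at_least"):
            raise ValueError(f"unknown censor flag {self.censor!r}")


_AGE_RE = re.compile(r"^\s*(<=|>=)?\s*(\d+)\s*$")


def code_age(raw: str) -> CensoredAge:
    """Decode an age cell: plain integer, "<=k" or ">=k"."""
    m = _AGE_RE.match(str(raw))
    if m is None:
        raise ValueError(f"unparseable age {raw!r}")
    flag = {None: "none", "<=": "at_most", ">=": "at_least"}[m.group(1)]
    return CensoredAge(int(m.group(2)), flag)


def assign_risk_group(dx_score: int) -> str:
    """Oncotype DX DCIS risk group: < 39 low, 39-54 intermediate, >= 55 high."""
    if dx_score < 0:
        raise ValueError("dx_score must be non-negative")
    if dx_score < 39:
        return "low"
    if dx_score <= 54:
        return "intermediate"
    return "high"


@dataclass(frozen=True)
class ClinicalRecord:
    patient_id: str
    dx_score: int
    age: CensoredAge
    nuclear_grade: int | None  # 1/2/3, None = not reported
    risk_group: str = field(init=False)
    follow_up_years: float | None = None
    treatment: str = ""
    recurrence: str = "NA"  # NED / ipsi_DCIS / ipsi_IBC / contra_DCIS / NA
    er_positive: bool = True  # whole example cohort is ER+

    def __post_init__(self) -> None:
        object.__setattr__(self, "risk_group", assign_risk_group(self.dx_score))


@dataclass(frozen=True)
class GroupCounts:
    low: int
    intermediate: int
    high: int

    @property
    def total(self) -> int:
        return self.low + self.intermediate + self.high


@dataclass(frozen=True)
class AgeSummary:
    n: int
    mean: float
    median: float


class CohortTable:
    """Ordered collection of :class:`ClinicalRecord` with unique patient ids."""

    def __init__(self, records: list[ClinicalRecord]):
        ids = [r.patient_id for r in records]
        if len(set(ids)) != len(ids):
            raise ValueError("patient_ids must be unique")
        self.records = list(records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ClinicalRecord]:
        return iter(self.records)

    def __getitem__(self, patient_id: str) -> ClinicalRecord:
        for r in self.records:
            if r.patient_id == patient_id:
                return r
        raise KeyError(patient_id)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": [r.patient_id for r in self.records],
                "dx_score": [r.dx_score for r in self.records],
                "age": [r.age.value for r in self.records],
                "age_censor": [r.age.censor for r in self.records],
                "nuclear_grade": [r.nuclear_grade for r in self.records],
                "risk_group": [r.risk_group for r in self.records],
                "follow_up_years": [r.follow_up_years for r in self.records],
                "treatment": [r.treatment for r in self.records],
                "recurrence": [r.recurrence for r in self.records],
            }
        )

    def to_csv(self, path) -> None:
        df = self.to_dataframe()
        age = df["age"].astype(str)
        age = np.where(df["age_censor"] == "at_most", "<=" + age, age)
        age = np.where(df["age_censor"] == "at_least", ">=" + df["age"].astype(str), age)
        out = df.drop(columns=["age_censor", "risk_group"]).copy()
        out["age"] = age
        out["nuclear_grade"] = [
            "NA" if r.nuclear_grade is None else f"N{r.nuclear_grade}"
            for r in self.records
        ]
        out["follow_up_years"] = out["follow_up_years"].fillna("NA")
        out.to_csv(path, index=False)

    # -- cohort-level statistics ------------------------------------------

    def risk_group_counts(self) -> GroupCounts:
        return risk_group_counts(self)

    def age_summary(self, by_group: bool = False) -> dict[str, AgeSummary]:
        return cohort_age_summary(self, by_group=by_group)

    def grade_group_contingency(self, collapse_int_high: bool = False) -> ContingencyResult:
        return grade_group_contingency(self, collapse_int_high=collapse_int_high)

    def ages(self) -> pd.Series:
        return pd.Series(
            [r.age.value for r in self.records],
            index=[r.patient_id for r in self.records],
            name="age",
            dtype=float,
        )

    def dx_scores(self) -> pd.Series:
        return pd.Series(
            [r.dx_score for r in self.records],
            index=[r.patient_id for r in self.records],
            name="dx_score",
            dtype=float,
        )

    def risk_groups(self) -> pd.Series:
        return pd.Series(
            [r.risk_group for r in self.records],
            index=[r.patient_id for r in self.records],
            name="risk_group",
        )

    def report(self) -> dict:
        """JSON-serializable cohort report (counts, age summaries, score range)."""
        counts = self.risk_group_counts()
        scores = [r.dx_score for r in self.records]
        return {
            "n": len(self),
            "risk_group_counts": {
                "low": counts.low,
                "intermediate": counts.intermediate,
                "high": counts.high,
            },
            "dx_score_range": [min(scores), max(scores)] if scores else None,
            "age_summary": {
                name: {"n": s.n, "mean": round(s.mean, 1), "median": s.median}
                for name, s in self.age_summary(by_group=True).items()
            },
        }


def _decode_grade(raw: str, patient_id: str) -> int | None:
    token = str(raw).strip()
    if token.lower() in _MISSING_TOKENS:
        return None
    m = re.match(r"^[Nn]?([123])$", token)
    if m is None:
        raise ClinicalRowError(
            f"row {patient_id!r}: unrecognized nuclear grade {raw!r}"
        )
    return int(m.group(1))


def parse_clinical_table(path, dialect: dict | None = None) -> CohortTable:
    """Parse a clinical CSV into a :class:`CohortTable`.

    Required columns: patient_id, dx_score, age, nuclear_grade,
    follow_up_years, treatment, recurrence. Age cells may be boundary-coded
    ("<=30", ">=80"); nuclear grade "N1"/"N2"/"N3" or a missing token
    ("NA", "-", empty). Risk group is derived from dx_score.
    """
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False, **(dialect or {}))
    except pd.errors.EmptyDataError as exc:
        raise ClinicalSchemaError(f"{path}: empty clinical table") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ClinicalSchemaError(f"{path}: missing required columns {missing}")

    records: list[ClinicalRecord] = []
    for idx, row in df.iterrows():
        pid = str(row["patient_id"]).strip()
        if not pid:
            raise ClinicalRowError(f"row {idx}: empty patient_id")
        try:
            score = int(str(row["dx_score"]).strip())
        except ValueError as exc:
            raise ClinicalRowError(
                f"row {pid!r}: non-numeric dx_score {row['dx_score']!r}"
            ) from exc
        try:
            age = code_age(row["age"])
        except ValueError as exc:
            raise ClinicalRowError(f"row {pid!r}: {exc}") from exc
        fu_raw = str(row["follow_up_years"]).strip()
        fu = None if fu_raw.lower() in _MISSING_TOKENS else float(fu_raw)
        rec_raw = str(row["recurrence"]).strip()
        recurrence = "NA" if rec_raw.lower() in _MISSING_TOKENS else rec_raw
        records.append(
            ClinicalRecord(
                patient_id=pid,
                dx_score=score,
                age=age,
                nuclear_grade=_decode_grade(row["nuclear_grade"], pid),
                follow_up_years=fu,
                treatment=str(row["treatment"]).strip(),
                recurrence=recurrence,
            )
        )
    return CohortTable(records)


def load_example_cohort() -> CohortTable:
    """The packaged 41-patient DCIS cohort table."""
    with resources.as_file(
        resources.files("dcismir.data").joinpath("dcis_cohort.csv")
    ) as p:
        return parse_clinical_table(p)


def risk_group_counts(cohort: CohortTable) -> GroupCounts:
    counts = {g: 0 for g in RISK_GROUPS}
    for r in cohort:
        counts[r.risk_group] += 1
    return GroupCounts(counts["low"], counts["intermediate"], counts["high"])


def _summary(ages: list[int]) -> AgeSummary:
    arr = np.asarray(ages, dtype=float)
    return AgeSummary(n=len(arr), mean=float(arr.mean()), median=float(np.median(arr)))


def cohort_age_summary(cohort: CohortTable, by_group: bool = False) -> dict[str, AgeSummary]:
    """Mean and exact median age, overall and (optionally) per risk group.

    Boundary-coded ages enter at their boundary value. Empty groups are
    simply absent from the result.
    """
    out: dict[str, AgeSummary] = {}
    ages = [r.age.value for r in cohort]
    if ages:
        out["overall"] = _summary(ages)
    if by_group:
        for g in RISK_GROUPS:
            grp = [r.age.value for r in cohort if r.risk_group == g]
            if grp:
                out[g] = _summary(grp)
    return out


def grade_group_contingency(
    cohort: CohortTable, collapse_int_high: bool = False
) -> ContingencyResult:
    """Chi-square independence of nuclear grade vs risk group.

    Records with missing grade are excluded listwise. With
    ``collapse_int_high``, the intermediate and high columns are pooled, the
    comparison reported in the study's supplement as the significant one.
    """
    graded = [r for r in cohort if r.nuclear_grade is not None]
    grades = sorted({r.nuclear_grade for r in graded})
    if collapse_int_high:
        columns = [("low",), ("intermediate", "high")]
    else:
        columns = [(g,) for g in RISK_GROUPS]
    table = np.array(
        [
            [sum(1 for r in graded if r.nuclear_grade == g and r.risk_group in col)
             for col in columns]
            for g in grades
        ],
        dtype=float,
    )
    return chi_square_independence(table)
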
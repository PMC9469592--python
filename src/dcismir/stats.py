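"""Self-contained statistical primitives used throughout the pipeline.

Every routine here is implemented from its textbook definition — only the
distribution tail functions (Student t, chi-square, standard normal) are
delegated to :mod:`scipy.stats`. This keeps each primitive transparent and
lets the test suite check it against an independent implementation
(scipy / statsmodels) and against brute-force oracles.

All tests are two-sided.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2 as _chi2_dist
from scipy.stats import norm as _norm_dist
from scipy.stats import t as _t_dist

__all__ = [
    "CorrelationResult",
    "TestResult",
    "AdjustedPValues",
    "ContingencyResult",
    "DegenerateTableError",
    "pearson_r",
    "spearman_rho",
    "chi_square_independence",
    "welch_t_test",
    "mann_whitney_u",
    "bh_adjust",
    "midrank",
]


class DegenerateTableError(ValueError):
    """Raised when a contingency table has a zero row or column total."""


@dataclass(frozen=True)
class CorrelationResult:
    """A correlation estimate with its two-sided p-value.

    ``testable`` is False when either input is constant, in which case
    ``estimate`` and ``p_value`` are NaN. Screens propagate such rows as
    flagged records instead of raising, so genome-wide loops never abort.
    """

    estimate: float
    p_value: float
    n: int
    method: str
    testable: bool = True


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    alternative: str = "two_sided"


@dataclass(frozen=True)
class AdjustedPValues:
    """Raw p-values and their BH-adjusted counterparts, in input order."""

    raw: np.ndarray
    adjusted: np.ndarray


@dataclass(frozen=True)
class ContingencyResult:
    observed: np.ndarray
    expected: np.ndarray
    statistic: float
    df: int
    p_value: float


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def _corr_p_from_r(r: float, n: int) -> float:
    # two-sided p from the exact null distribution of r via the t transform
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return min(1.0, 2.0 * float(_t_dist.sf(abs(t), n - 2)))


def pearson_r(x, y) -> CorrelationResult:
    """Sample Pearson correlation with a two-sided t-based p-value (df = n-2)."""
    x = _as_1d(x, "x")
    y = _as_1d(y, "y")
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = math.sqrt(float(xc @ xc))
    sy = math.sqrt(float(yc @ yc))
    if sx == 0.0 or sy == 0.0:
        return CorrelationResult(math.nan, math.nan, n, "pearson", testable=False)
    r = float(xc @ yc) / (sx * sy)
    r = max(-1.0, min(1.0, r))
    return CorrelationResult(r, _corr_p_from_r(r, n), n, "pearson")


def midrank(x) -> np.ndarray:
    """Mid-ranks (1-based; ties share the average of their rank range)."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=float)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def spearman_rho(x, y) -> CorrelationResult:
    """Spearman rank correlation: Pearson correlation of mid-ranks."""
    x = _as_1d(x, "x")
    y = _as_1d(y, "y")
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    res = pearson_r(midrank(x), midrank(y))
    return CorrelationResult(res.estimate, res.p_value, res.n, "spearman", res.testable)


def chi_square_independence(table) -> ContingencyResult:
    """Pearson chi-square test of independence, no continuity correction.

    statistic = sum (O - E)^2 / E with E from the product of the margins;
    p from the chi-square distribution with (r-1)(c-1) df.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if np.any(obs < 0):
        raise ValueError("table entries must be non-negative")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise DegenerateTableError("table has a zero row or column total")
    expected = np.outer(rows, cols) / obs.sum()
    statistic = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = 1.0 if statistic == 0.0 else min(1.0, float(_chi2_dist.sf(statistic, df)))
    return ContingencyResult(obs, expected, statistic, df, p)


def welch_t_test(a, b) -> TestResult:
    """Welch two-sample t test with Satterthwaite df, two-sided."""
    a = _as_1d(a, "a")
    b = _as_1d(b, "b")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    na, nb = len(a), len(b)
    va = float(a.var(ddof=1)) / na
    vb = float(b.var(ddof=1)) / nb
    diff = float(a.mean() - b.mean())
    if va + vb == 0.0:
        # zero variance in both groups: identical constants give p = 1
        p = 1.0 if diff == 0.0 else 0.0
        return TestResult(0.0 if diff == 0.0 else math.inf, p, "welch_t")
    t = diff / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    p = min(1.0, 2.0 * float(_t_dist.sf(abs(t), df)))
    return TestResult(t, p, "welch_t")


def _u_statistic(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum()) - n_a * (n_a + 1) / 2.0


def mann_whitney_u(a, b, exact_max_n: int = 8) -> TestResult:
    """Mann-Whitney U test; statistic is U for the first sample.

    Exact two-sided p by enumerating all C(n_a+n_b, n_a) group labelings when
    ``min(n_a, n_b) <= exact_max_n`` and there are no ties; otherwise the
    normal approximation with continuity and tie correction.
    """
    a = _as_1d(a, "a")
    b = _as_1d(b, "b")
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    na, nb = len(a), len(b)
    pooled = np.concatenate([a, b])
    ranks = midrank(pooled)
    u = _u_statistic(ranks[:na], na)
    nm = na * nb
    has_ties = len(np.unique(pooled)) < len(pooled)

    if min(na, nb) <= exact_max_n and not has_ties:
        # enumerate which sorted positions group a occupies; U depends only
        # on the occupied 1-based ranks
        u_lo, u_hi = min(u, nm - u), max(u, nm - u)
        total = math.comb(na + nb, na)
        if u_lo == u_hi:
            return TestResult(u, 1.0, "mann_whitney_u")
        count = 0
        offset = na * (na + 1) / 2.0
        for positions in itertools.combinations(range(1, na + nb + 1), na):
            u_perm = sum(positions) - offset
            if u_perm <= u_lo or u_perm >= u_hi:
                count += 1
        return TestResult(u, min(1.0, count / total), "mann_whitney_u")

    n = na + nb
    mu = nm / 2.0
    # tie correction to the null variance
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum()) / (n * (n - 1))
    sigma2 = nm / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0.0:
        return TestResult(u, 1.0, "mann_whitney_u")
    z = max(0.0, abs(u - mu) - 0.5) / math.sqrt(sigma2)
    p = min(1.0, 2.0 * float(_norm_dist.sf(z)))
    return TestResult(u, p, "mann_whitney_u")


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved).

    adjusted_(i) = min_{j >= i} (m / j) * p_(j), capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.empty(m, dtype=float)
    adjusted[order] = np.minimum(adjusted_sorted, 1.0)
    return adjusted
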
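"""Self-contained statistical kernel used throughout the package.

Implements the handful of classical procedures the painting analyses rest on:
pooled two-sample t (from raw samples or from published summary statistics),
Pearson chi-square on a 2x2 table, Benjamini-Hochberg FDR, point-biserial
correlation and RMSE.  The arithmetic is written out explicitly; SciPy is
used only for the reference distributions (t, chi-square) that turn test
statistics into p-values.

Defaults are chosen for fidelity to common psychiatric-epidemiology
reporting: Student's pooled-variance t (not Welch) and chi-square without
Yates continuity correction; both alternatives are available behind flags.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

__all__ = [
    "SummaryStats",
    "ContingencyTable2x2",
    "TTestResult",
    "summarize",
    "pooled_t",
    "two_sample_t_raw",
    "chi_square_2x2",
    "bh_fdr",
    "point_biserial",
    "rmse",
]


@dataclass(frozen=True)
class SummaryStats:
    """Sample size, mean and sample standard deviation (n-1 denominator)."""

    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError(f"need n >= 2, got n={self.n}")
        if self.sd < 0:
            raise ValueError("standard deviation must be non-negative")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for a group x category cross-tabulation.

    Layout: rows are groups, columns are categories::

        a  b
        c  d
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(v < 0 for v in cells):
            raise ValueError("cell counts must be non-negative")
        if min(self.row_margins) == 0 or min(self.col_margins) == 0:
            raise ValueError("chi-square undefined with a zero margin")

    @property
    def row_margins(self) -> tuple[int, int]:
        return (self.a + self.b, self.c + self.d)

    @property
    def col_margins(self) -> tuple[int, int]:
        return (self.a + self.c, self.b + self.d)

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class TTestResult:
    statistic: float
    df: float
    pvalue: float
    infinite: bool = False

    def __iter__(self):
        return iter((self.statistic, self.df, self.pvalue))


def summarize(values) -> SummaryStats:
    """Reduce a sample to the (n, mean, sd) triple used by :func:`pooled_t`."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D sample with at least two values")
    return SummaryStats(n=int(x.size), mean=float(x.mean()), sd=float(x.std(ddof=1)))


def pooled_t(summary_a: SummaryStats, summary_b: SummaryStats) -> TTestResult:
    """Student's pooled-variance two-sample t-test from summary statistics.

    df = n_a + n_b - 2; the p-value is two-sided.  Reproduces published group
    comparisons exactly from the printed (n, mean, SD) triples.
    """
    na, nb = summary_a.n, summary_b.n
    df = na + nb - 2
    sp2 = ((na - 1) * summary_a.sd**2 + (nb - 1) * summary_b.sd**2) / df
    se = math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    diff = summary_a.mean - summary_b.mean
    if se == 0.0:
        if diff == 0.0:
            return TTestResult(0.0, df, 1.0)
        return TTestResult(math.copysign(math.inf, diff), df, 0.0, infinite=True)
    t = diff / se
    p = 2.0 * _sps.t.sf(abs(t), df)
    return TTestResult(float(t), float(df), float(p))


def two_sample_t_raw(values_a, values_b) -> TTestResult:
    """Pooled two-sample t from raw samples.

    Algebraically identical to ``pooled_t(summarize(a), summarize(b))``;
    zero pooled variance with equal means gives t = 0, with unequal means an
    infinite-t flag.
    """
    return pooled_t(summarize(values_a), summarize(values_b))


def chi_square_2x2(table: ContingencyTable2x2, *, continuity: bool = False):
    """Pearson chi-square for a 2x2 table, df = 1.

    No continuity correction by default (matching how gender-by-group
    comparisons are customarily printed); Yates correction behind the
    ``continuity`` flag.

    Returns ``(chi2, df, p)``.
    """
    if not isinstance(table, ContingencyTable2x2):
        table = ContingencyTable2x2(*np.asarray(table, dtype=int).ravel())
    obs = np.array([[table.a, table.b], [table.c, table.d]], dtype=float)
    rows = obs.sum(axis=1, keepdims=True)
    cols = obs.sum(axis=0, keepdims=True)
    expected = rows @ cols / obs.sum()
    dev = np.abs(obs - expected)
    if continuity:
        dev = np.maximum(dev - 0.5, 0.0)
    chi2 = float((dev**2 / expected).sum())
    p = float(_sps.chi2.sf(chi2, 1))
    return chi2, 1, p


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} ( m * p_(j) / j ), capped at 1, where p_(1..m) are
    the sorted raw p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def point_biserial(values, binary_labels):
    """Pearson correlation between a variable and 0/1-coded group labels.

    Returns ``(r, p)`` with the p-value from the exact t transform,
    t = r * sqrt((n-2) / (1-r^2)), df = n - 2.  Returns ``(nan, nan)`` when
    the correlation is undefined (constant values or a single class).
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(binary_labels, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("values and labels must be 1-D and equal length")
    n = x.size
    classes = np.unique(y)
    if n < 3 or classes.size < 2:
        return float("nan"), float("nan")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0.0:
        return float("nan"), float("nan")
    r = float(xc @ yc) / denom
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(_sps.t.sf(abs(t), n - 2))
    return r, p


def rmse(predicted, actual) -> float:
    """Root mean square error between two equal-length vectors."""
    p = np.asarray(predicted, dtype=float).ravel()
    a = np.asarray(actual, dtype=float).ravel()
    if p.size != a.size:
        raise ValueError(f"length mismatch: {p.size} vs {a.size}")
    if p.size == 0:
        raise ValueError("need at least one value")
    return float(np.sqrt(np.mean((p - a) ** 2)))
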
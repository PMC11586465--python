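"""Elementary statistics used throughout the pipeline.

These are deliberately self-contained: Pearson chi-square on contingency
tables, Spearman rank correlation with average ranks, Benjamini–Hochberg
step-up q-values, and z-normalization. Only the chi-square and Student-t
tail probabilities are delegated to :mod:`scipy.stats` distributions.

The chi-square test uses the plain Pearson statistic with *no* continuity
correction: for cohort demographics tables (2x2 and 3x2 group contrasts)
the uncorrected asymptotic p-value is the convention adopted here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _sps

__all__ = [
    "ContingencyTable",
    "TestResult",
    "chi_square_test",
    "spearman_correlation",
    "bh_fdr",
    "z_normalize",
    "rankdata",
]


@dataclass(frozen=True)
class ContingencyTable:
    """An r x c table of non-negative counts with optional axis labels."""

    counts: np.ndarray
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValueError("contingency table must be at least 2x2")
        if np.any(counts < 0) or not np.all(np.isfinite(counts)):
            raise ValueError("counts must be finite and non-negative")
        if counts.sum() <= 0:
            raise ValueError("contingency table must have a positive total")
        object.__setattr__(self, "counts", counts.astype(float))


@dataclass(frozen=True)
class TestResult:
    """A test statistic with its p-value (and degrees of freedom if defined)."""

    statistic: float
    p_value: float
    df: int | None = None
    name: str = ""
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {"statistic": self.statistic, "p_value": self.p_value}
        if self.df is not None:
            out["df"] = self.df
        if self.name:
            out["name"] = self.name
        out.update(self.extra)
        return out


def chi_square_test(table: ContingencyTable | np.ndarray) -> TestResult:
    """Pearson chi-square test of independence on an r x c table.

    Expected counts come from the row/column marginals; the statistic is
    ``sum((O - E)^2 / E)`` with ``df = (r - 1)(c - 1)`` and an upper-tail
    asymptotic p-value. No Yates continuity correction is applied.
    """
    if not isinstance(table, ContingencyTable):
        table = ContingencyTable(np.asarray(table))
    counts = table.counts
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    if np.any(row == 0) or np.any(col == 0):
        raise ValueError("zero marginal row or column: expected counts undefined")
    expected = np.outer(row, col) / counts.sum()
    statistic = float(((counts - expected) ** 2 / expected).sum())
    df = (counts.shape[0] - 1) * (counts.shape[1] - 1)
    p = float(_sps.chi2.sf(statistic, df))
    return TestResult(statistic=statistic, p_value=p, df=df, name="pearson-chi2")


def rankdata(x: np.ndarray) -> np.ndarray:
    """Ranks 1..n with ties assigned the average of their rank range."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(x.size, dtype=float)
    ranks[order] = np.arange(1, x.size + 1, dtype=float)
    # average ranks within tied blocks
    sorted_x = x[order]
    i = 0
    while i < x.size:
        j = i
        while j + 1 < x.size and sorted_x[j + 1] == sorted_x[i]:
            j += 1
        if j > i:
            ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def spearman_correlation(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Spearman rank correlation with an asymptotic t-approximation p-value.

    Where a spatial null applies (parcellated brain maps), the analytic p
    reported here should be superseded by a spin-test p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    rx, ry = rankdata(x), rankdata(y)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        raise ValueError("undefined correlation: constant input")
    r = float(np.clip(((rx - rx.mean()) * (ry - ry.mean())).mean() / (sx * sy), -1.0, 1.0))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p = float(2.0 * _sps.t.sf(abs(t), n - 2))
    return TestResult(statistic=r, p_value=p, df=n - 2, name="spearman")


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values.

    q_(i) = min_{j >= i} ( m * p_(j) / j ), clipped at 1; elementwise
    q >= p and the ordering of the inputs is preserved.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-D")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def z_normalize(values: np.ndarray) -> np.ndarray:
    """Standardize to mean 0 and sample (ddof=1) standard deviation 1."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("zero spread: z-normalization undefined")
    return (x - x.mean()) / sd
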
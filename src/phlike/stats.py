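"""Association tests for contingency tables and group medians.

Implements the three tests used throughout the clinical comparisons —
Fisher's exact test, Pearson's chi-square without continuity correction,
and Mood's median test — plus the conventional rule for choosing between
the exact and asymptotic test (Fisher when any expected count is below 5).

Fisher's two-sided p-value follows the point-probability rule: the sum of
hypergeometric probabilities of every table with the observed margins whose
point probability does not exceed that of the observed table.  A
doubled-one-tail variant is available for cross-checking against software
that uses it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "ContingencyTable",
    "TestResult",
    "fisher_exact",
    "pearson_chi2",
    "mood_median_test",
    "choose_test",
]


@dataclass(frozen=True)
class ContingencyTable:
    """A 2 × k non-negative integer table with row/column labels."""

    counts: np.ndarray
    row_labels: tuple[str, ...] = ()
    col_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=np.int64)
        if arr.ndim != 2 or arr.shape[0] != 2 or arr.shape[1] < 2:
            raise ValueError("contingency table must be 2 x k with k >= 2")
        if (arr < 0).any():
            raise ValueError("negative cell count")
        object.__setattr__(self, "counts", arr)
        if not self.row_labels:
            object.__setattr__(self, "row_labels", tuple(f"row{i}" for i in range(2)))
        if not self.col_labels:
            object.__setattr__(
                self, "col_labels", tuple(f"col{j}" for j in range(arr.shape[1]))
            )

    @classmethod
    def from_cells(cls, a: int, b: int, c: int, d: int, **kw) -> "ContingencyTable":
        return cls(np.array([[a, b], [c, d]]), **kw)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def expected(self) -> np.ndarray:
        """Expected counts under row/column independence."""
        r = self.counts.sum(axis=1, keepdims=True)
        c = self.counts.sum(axis=0, keepdims=True)
        return r * c / self.total


@dataclass(frozen=True)
class TestResult:
    statistic: float | None
    p_value: float
    method: str
    table: ContingencyTable | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def _as_2x2(t: ContingencyTable) -> np.ndarray:
    if t.counts.shape != (2, 2):
        raise ValueError("a 2 x 2 table is required")
    return t.counts


def fisher_exact(t: ContingencyTable, rule: str = "point_probability") -> TestResult:
    """Two-sided Fisher's exact test on a 2 × 2 table.

    ``rule="point_probability"`` (default) sums hypergeometric probabilities
    of all tables with the observed margins whose point probability is at
    most that observed; ``rule="doubled"`` doubles the smaller one-sided
    tail (capped at 1).  Degenerate tables with a zero margin yield p = 1
    with a warning.
    """
    tab = _as_2x2(t)
    a, b = tab[0]
    c, d = tab[1]
    n = int(tab.sum())
    r1, c1 = int(a + b), int(a + c)
    if n == 0 or r1 in (0, n) or c1 in (0, n):
        warnings.warn("degenerate table (zero margin); p = 1 by convention")
        return TestResult(None, 1.0, "fisher_exact", t)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = _sps.hypergeom.pmf(support, n, r1, c1)
    p_obs = _sps.hypergeom.pmf(int(a), n, r1, c1)
    if rule == "point_probability":
        # tolerance guards against ties lost to floating point
        p = float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())
    elif rule == "doubled":
        lower = float(pmf[support <= a].sum())
        upper = float(pmf[support >= a].sum())
        p = 2.0 * min(lower, upper)
    else:
        raise ValueError(f"unknown two-sided rule {rule!r}")
    return TestResult(None, min(p, 1.0), "fisher_exact", t)


def pearson_chi2(t: ContingencyTable) -> TestResult:
    """Pearson chi-square on a 2 × k table, no continuity correction."""
    exp = t.expected()
    if (exp == 0).any():
        raise ValueError("zero expected count; chi-square undefined")
    stat, p, _, _ = _sps.chi2_contingency(t.counts, correction=False)
    return TestResult(float(stat), float(p), "pearson_chi2", t)


def choose_test(t: ContingencyTable) -> TestResult:
    """Fisher's exact if any expected count < 5, else Pearson chi-square."""
    tab = _as_2x2(t)
    if tab.sum() == 0:
        warnings.warn("all-zero table; p = 1 by convention")
        return TestResult(None, 1.0, "degenerate", t)
    if (t.expected() < 5).any():
        return fisher_exact(t)
    return pearson_chi2(t)


def mood_median_test(groups: list[np.ndarray] | list[list[float]]) -> TestResult:
    """Mood's median test across two or more groups.

    Counts values strictly above versus not-above the pooled grand median
    per group; the resulting 2 × k table goes to :func:`choose_test`
    (2 × 2) or :func:`pearson_chi2` (k > 2).  Values equal to the grand
    median count as "not above".
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size == 0 for a in arrays):
        raise ValueError("need >= 2 nonempty groups")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        warnings.warn("all values identical; median test degenerate, p = 1")
        return TestResult(None, 1.0, "mood_median", None)
    med = float(np.median(pooled))
    above = [int((a > med).sum()) for a in arrays]
    not_above = [int((a <= med).sum()) for a in arrays]
    table = ContingencyTable(
        np.array([above, not_above]),
        row_labels=("above_median", "not_above"),
        col_labels=tuple(f"group{i}" for i in range(len(arrays))),
    )
    if table.counts.shape[1] == 2:
        inner = choose_test(table)
    else:
        inner = pearson_chi2(table)
    return TestResult(inner.statistic, inner.p_value, f"mood_median[{inner.method}]", table)
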
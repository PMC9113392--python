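"""Diagnostic-accuracy statistics for the triage-vs-reference comparison.

The triage scale (5 ordinal levels) is cross-tabulated against the binary
reference standard (warning-score high/low), dichotomized at levels {1,2}
vs {3,4,5}, and summarised with the classical screening statistics:

* sensitivity, specificity, PPV, NPV — Wilson score 95% intervals;
* LR+ = sens/(1-spec), LR- = (1-sens)/spec — log-method 95% intervals
  (Simel et al.);
* agreement, over-triage (test high / reference low) and under-triage
  (test low / reference high) proportions, which partition the cohort.

All internal computation is full precision; one-decimal rounding happens
only in the report layer.  Statistics with zero denominators are NA
(``nan``), never 0 or infinity in reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .errors import (
    DegenerateMarginError,
    EmptyTableError,
    IncompleteVisitError,
)

LEVELS = (1, 2, 3, 4, 5)
ACUITY_ROWS = ("high", "low")
HIGH_LEVELS = (1, 2)


@dataclass(frozen=True)
class CrossTab:
    """2 (reference acuity: high/low) x 5 (triage level 1-5) count table."""

    counts: np.ndarray  # shape (2, 5), int

    def __post_init__(self):
        arr = np.asarray(self.counts, dtype=np.int64)
        if arr.shape != (2, 5):
            raise ValueError(f"crosstab must be 2x5, got {arr.shape}")
        if (arr < 0).any():
            raise ValueError("crosstab counts must be non-negative")
        object.__setattr__(self, "counts", arr)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        """Table with row/column totals, reference rows x triage columns."""
        df = pd.DataFrame(
            self.counts,
            index=pd.Index(["pews_high", "pews_low"], name="reference"),
            columns=[f"level_{lv}" for lv in LEVELS],
        )
        df["total"] = df.sum(axis=1)
        df.loc["total"] = df.sum(axis=0)
        return df


@dataclass(frozen=True)
class Confusion2x2:
    """TP/FP/FN/TN after dichotomizing the triage scale at {1,2} vs {3,4,5}."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class IntervalEstimate:
    """Point estimate with a two-sided interval; NaN encodes NA."""

    point: float
    lower: float
    upper: float
    method: str

    @property
    def is_na(self) -> bool:
        return math.isnan(self.point)


def _na(method: str = "NA") -> IntervalEstimate:
    return IntervalEstimate(math.nan, math.nan, math.nan, method)


@dataclass(frozen=True)
class DiagnosticSummary:
    """The full screening-accuracy summary; percent scale except the LRs."""

    sensitivity: IntervalEstimate
    specificity: IntervalEstimate
    ppv: IntervalEstimate
    npv: IntervalEstimate
    lr_pos: IntervalEstimate
    lr_neg: IntervalEstimate
    agreement: IntervalEstimate
    over_triage: IntervalEstimate
    under_triage: IntervalEstimate
    n: int


def build_crosstab(
    visits: pd.DataFrame,
    level_col: str = "final_level",
    acuity_col: str = "acuity",
) -> CrossTab:
    """Count visits into the 2x5 reference-acuity x triage-level table."""
    if len(visits) == 0:
        return CrossTab(np.zeros((2, 5), dtype=np.int64))
    levels = pd.to_numeric(visits[level_col], errors="coerce")
    acuity = visits[acuity_col]
    bad = levels.isna() | ~levels.isin(LEVELS) | ~acuity.isin(ACUITY_ROWS)
    if bad.any():
        raise IncompleteVisitError(visits.index[bad].tolist())
    counts = np.zeros((2, 5), dtype=np.int64)
    for i, row in enumerate(ACUITY_ROWS):
        mask = acuity == row
        for j, lv in enumerate(LEVELS):
            counts[i, j] = int((mask & (levels == lv)).sum())
    return CrossTab(counts)


def dichotomize(crosstab: CrossTab) -> Confusion2x2:
    """Pool triage levels {1,2} (test high) vs {3,4,5} (test low)."""
    high, low = crosstab.counts
    return Confusion2x2(
        tp=int(high[:2].sum()),
        fn=int(high[2:].sum()),
        fp=int(low[:2].sum()),
        tn=int(low[2:].sum()),
    )


#: statsmodels method names for the supported binomial interval methods
_PROPORTION_METHODS = {"exact": "beta", "wilson": "wilson", "wald": "normal"}


def proportion_ci(
    x: int, n: int, level: float = 0.95, method: str = "exact"
) -> IntervalEstimate:
    """Binomial proportion interval on the percent scale.

    The default is the exact (Clopper-Pearson) interval, which reproduces
    every printed interval of the reference validation study at one-decimal
    rounding; the Wilson score and Wald intervals are available by name.
    """
    if n <= 0:
        raise EmptyTableError("proportion over zero trials")
    if not 0 <= x <= n:
        raise ValueError(f"successes {x} outside 0..{n}")
    if method not in _PROPORTION_METHODS:
        raise ValueError(f"method must be one of {sorted(_PROPORTION_METHODS)}")
    lo, hi = proportion_confint(
        x, n, alpha=1 - level, method=_PROPORTION_METHODS[method]
    )
    p = x / n
    # guard floating noise in the backend so the interval contains the point
    lo, hi = min(float(lo), p), max(float(hi), p)
    return IntervalEstimate(100.0 * p, 100.0 * lo, 100.0 * hi, method)


def likelihood_ratio_ci(
    c: Confusion2x2, which: str = "positive", level: float = 0.95
) -> IntervalEstimate:
    """Log-method (Simel) confidence interval for LR+ or LR-.

    LR+ = (tp/(tp+fn)) / (fp/(fp+tn)) with
    SE(ln LR+) = sqrt(1/tp - 1/(tp+fn) + 1/fp - 1/(fp+tn));
    LR- mirrors with fn and tn in place of tp and fp.  Any zero cell that
    makes the log variance undefined yields an NA interval.
    """
    if which not in ("positive", "negative"):
        raise ValueError("which must be 'positive' or 'negative'")
    pos_total, neg_total = c.tp + c.fn, c.fp + c.tn
    if pos_total == 0 or neg_total == 0:
        return _na("log-method: empty reference class")
    a, b = (c.tp, c.fp) if which == "positive" else (c.fn, c.tn)
    if a == 0 or b == 0:
        return _na("log-method: zero cell")
    lr = (a / pos_total) / (b / neg_total)
    se = math.sqrt(1 / a - 1 / pos_total + 1 / b - 1 / neg_total)
    z = stats.norm.ppf(0.5 + level / 2)
    return IntervalEstimate(
        lr, lr * math.exp(-z * se), lr * math.exp(z * se), "log-method"
    )


def diagnostic_summary(c: Confusion2x2, level: float = 0.95) -> DiagnosticSummary:
    """All screening statistics with 95% intervals from one 2x2 table."""
    n = c.n
    if n == 0:
        raise EmptyTableError("cannot summarise an empty 2x2 table")

    def prop(x: int, denom: int) -> IntervalEstimate:
        if denom == 0:
            return _na()
        return proportion_ci(x, denom, level)

    return DiagnosticSummary(
        sensitivity=prop(c.tp, c.tp + c.fn),
        specificity=prop(c.tn, c.tn + c.fp),
        ppv=prop(c.tp, c.tp + c.fp),
        npv=prop(c.tn, c.tn + c.fn),
        lr_pos=likelihood_ratio_ci(c, "positive", level),
        lr_neg=likelihood_ratio_ci(c, "negative", level),
        agreement=prop(c.tp + c.tn, n),
        over_triage=prop(c.fp, n),
        under_triage=prop(c.fn, n),
        n=n,
    )


def chi_squared(table) -> Tuple[float, float, int]:
    """Pearson chi-squared test of independence on an r x c count table.

    Returns ``(statistic, p_value, dof)``.  Continuity correction is not
    applied; a zero row or column margin is rejected as degenerate.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise DegenerateMarginError("table must be at least 2x2")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DegenerateMarginError("zero row or column margin")
    res = stats.chi2_contingency(arr, correction=False)
    return float(res.statistic), float(res.pvalue), int(res.dof)


def bonferroni_threshold(alpha: float = 0.001, comparisons: int = 1) -> float:
    """Per-test significance threshold after Bonferroni division.

    The study-wide level defaults to 0.001 (chosen conservatively for a very
    large sample) and is divided across the declared comparison family.
    """
    if comparisons < 1:
        raise ValueError("comparisons must be >= 1")
    return alpha / comparisons
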
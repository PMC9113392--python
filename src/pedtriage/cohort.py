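"""Stratified validity and severity-outcome analyses.

Secondary analyses of the validation pipeline: screening accuracy within
subgroups (sex, age band, complaint type/category, diagnosis), disposition
rates by triage level, and length-of-stay comparison across levels by
one-way ANOVA with Scheffe post hoc contrasts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .config import age_band_of
from .errors import (
    InsufficientGroupsError,
    OutcomeVocabularyError,
)
from .metrics import (
    DiagnosticSummary,
    IntervalEstimate,
    build_crosstab,
    diagnostic_summary,
    dichotomize,
    proportion_ci,
)

OUTCOME_VOCABULARY = ("icu", "hospitalization", "transfer", "discharged")
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class Stratifier:
    """Maps each visit row to a stratum label; ``None`` -> unclassified."""

    factor: str
    levels: Tuple[str, ...]
    assign: Callable[[pd.Series], Optional[str]]


def _age_band_label(row: pd.Series) -> Optional[str]:
    age = row.get("age_days")
    if pd.isna(age):
        return None
    return age_band_of(float(age)).label


def by_sex() -> Stratifier:
    return Stratifier("sex", ("male", "female"), lambda r: r.get("sex") or None)


def by_age_band() -> Stratifier:
    from .config import AGE_BAND_LABELS

    return Stratifier("age_band", AGE_BAND_LABELS, _age_band_label)


def by_complaint_type() -> Stratifier:
    return Stratifier(
        "complaint_type",
        ("medical", "surgical"),
        lambda r: r.get("complaint_type") or None,
    )


def by_column(column: str, levels: Sequence[str]) -> Stratifier:
    """Generic stratifier over a categorical column (e.g. diagnosis)."""
    return Stratifier(column, tuple(levels), lambda r: r.get(column) or None)


@dataclass(frozen=True)
class StratumReport:
    stratum: str
    n: int
    prevalence_test_high: float  # percent triaged to levels 1-2; nan if n=0
    prevalence_ref_high: float  # percent reference-high; nan if n=0
    summary: Optional[DiagnosticSummary]  # None when the stratum is empty


def stratified_validity(
    visits: pd.DataFrame, stratifier: Stratifier
) -> List[StratumReport]:
    """Per-stratum crosstab -> dichotomize -> diagnostic summary.

    Strata are reported in the stratifier's declared order; visits the
    stratifier cannot place are pooled into an explicit ``unclassified``
    stratum.  Zero-denominator statistics inside a stratum are NA.
    """
    labels = visits.apply(stratifier.assign, axis=1) if len(visits) else pd.Series(
        [], dtype=object
    )
    reports: List[StratumReport] = []
    order = list(stratifier.levels)
    if labels.isna().any():
        order.append(UNCLASSIFIED)
    for stratum in order:
        mask = labels.isna() if stratum == UNCLASSIFIED else (labels == stratum)
        sub = visits.loc[mask]
        if len(sub) == 0:
            reports.append(StratumReport(stratum, 0, float("nan"), float("nan"), None))
            continue
        conf = dichotomize(build_crosstab(sub))
        reports.append(
            StratumReport(
                stratum=stratum,
                n=conf.n,
                prevalence_test_high=100.0 * (conf.tp + conf.fp) / conf.n,
                prevalence_ref_high=100.0 * (conf.tp + conf.fn) / conf.n,
                summary=diagnostic_summary(conf),
            )
        )
    return reports


def outcome_rates_by_level(
    visits: pd.DataFrame,
    level_col: str = "final_level",
    outcome_col: str = "outcome",
) -> Dict[int, Dict[str, IntervalEstimate]]:
    """Disposition proportions (with Wilson CIs) within each triage level.

    Any monotone trend across levels (e.g. hospitalization falling from
    level 1 to level 5) is a finding to report, not a constraint enforced
    here.
    """
    outcomes = visits[outcome_col]
    unknown = outcomes[~outcomes.isin(OUTCOME_VOCABULARY) & outcomes.notna()]
    if len(unknown):
        raise OutcomeVocabularyError(unknown.tolist(), OUTCOME_VOCABULARY)
    rates: Dict[int, Dict[str, IntervalEstimate]] = {}
    for lv, sub in visits.groupby(level_col):
        n = len(sub)
        rates[int(lv)] = {
            out: proportion_ci(int((sub[outcome_col] == out).sum()), n)
            for out in OUTCOME_VOCABULARY
        }
    return rates


@dataclass(frozen=True)
class LosSummary:
    """Per-level LOS moments, the one-way ANOVA, and Scheffe contrasts."""

    groups: pd.DataFrame  # index level; columns n, mean, sd
    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    scheffe: pd.DataFrame  # one row per level pair


def los_anova(
    visits: pd.DataFrame,
    level_col: str = "final_level",
    los_col: str = "los_minutes",
    alpha: float = 0.001,
) -> LosSummary:
    """One-way ANOVA of length of stay across triage levels, from the
    between/within sum-of-squares decomposition, with Scheffe post hoc
    pairwise contrasts at the study-wide ``alpha``.

    Levels with fewer than two LOS observations are dropped with a warning.
    """
    data = visits[[level_col, los_col]].dropna()
    groups: Dict[int, np.ndarray] = {}
    for lv, sub in data.groupby(level_col):
        values = np.asarray(sub[los_col], dtype=float)
        if len(values) < 2:
            warnings.warn(
                f"level {lv} has {len(values)} LOS observation(s); dropped from ANOVA",
                stacklevel=2,
            )
            continue
        groups[int(lv)] = values
    k = len(groups)
    if k < 2:
        raise InsufficientGroupsError("ANOVA needs >= 2 levels with >= 2 observations")

    all_values = np.concatenate(list(groups.values()))
    n_total = len(all_values)
    grand_mean = all_values.mean()
    ss_between = sum(len(v) * (v.mean() - grand_mean) ** 2 for v in groups.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df_b, df_w = k - 1, n_total - k
    ms_between = ss_between / df_b
    ms_within = ss_within / df_w
    if ms_within == 0:
        f_stat = 0.0 if ms_between == 0 else float("inf")
        p = 1.0 if ms_between == 0 else 0.0
    else:
        f_stat = ms_between / ms_within
        p = float(stats.f.sf(f_stat, df_b, df_w))

    group_frame = pd.DataFrame(
        {
            "n": {lv: len(v) for lv, v in groups.items()},
            "mean": {lv: v.mean() for lv, v in groups.items()},
            "sd": {lv: v.std(ddof=1) for lv, v in groups.items()},
        }
    ).sort_index()

    # Scheffe: F_pair = diff^2 / ((k-1) * MSW * (1/ni + 1/nj)), referred to
    # F(k-1, N-k); simultaneous CI half-width sqrt((k-1) F_crit) * SE(diff).
    f_crit = float(stats.f.ppf(1 - alpha, df_b, df_w))
    rows = []
    for (la, va), (lb, vb) in combinations(sorted(groups.items()), 2):
        diff = va.mean() - vb.mean()
        se2 = ms_within * (1 / len(va) + 1 / len(vb))
        if se2 > 0:
            f_pair = diff**2 / (df_b * se2)
            p_pair = float(stats.f.sf(f_pair, df_b, df_w))
            half = float(np.sqrt(df_b * f_crit * se2))
        else:
            f_pair, p_pair, half = float("nan"), float("nan"), 0.0
        rows.append(
            {
                "level_a": la,
                "level_b": lb,
                "mean_diff": diff,
                "ci_lower": diff - half,
                "ci_upper": diff + half,
                "f": f_pair,
                "p": p_pair,
                "significant": bool(p_pair < alpha) if not np.isnan(p_pair) else False,
            }
        )
    return LosSummary(
        groups=group_frame,
        f_statistic=float(f_stat),
        df_between=df_b,
        df_within=df_w,
        p_value=p,
        scheffe=pd.DataFrame(rows),
    )
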
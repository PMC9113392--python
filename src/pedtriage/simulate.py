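"""Synthetic pediatric-ED cohort generator.

Emulates the validation-study population: visits are sampled triage-level
first from the observed 5-level marginal, then reference acuity given
level from the observed high/low split, then demographics, complaint,
diagnosis, disposition and length of stay from the published per-level
conditionals.  Attributes not jointly tabulated in the source (e.g. age x
complaint) are drawn conditionally independent given the level — a stated
simplification, not a claim about the real cohort.

Each generated presentation is constructed so that the triage engine
reproduces its intended level exactly (round-trip property): the selected
complaint item carries the intended base level, recorded vitals are drawn
inside their reference range, and newborn ages are only assigned where the
automatic newborn override cannot alter the level.

Determinism: every attribute is driven by its own uniform stream derived
from one seed, and each visit consumes exactly one draw per stream, so
``generate(n + m, ...)`` extends ``generate(n, ...)`` row-for-row.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import stats

from .config import AGE_BANDS, TriageConfig, default_config
from .metrics import CrossTab
from .pews import DEFAULT_CUTOFF

LEVELS = (1, 2, 3, 4, 5)

DIAGNOSES = (
    "ent_infection",
    "acute_gastroenteritis",
    "asthma",
    "bronchiolitis",
    "flu",
    "fever_unknown_origin",
    "mild_traumatic_brain_injury",
    "upper_limb_trauma",
    "lower_limb_trauma",
    "burn",
    "visceral_pathology",
    "other",
)

OUTCOMES = ("icu", "hospitalization", "transfer", "discharged")

_SUM_TOL = 1e-9


def _normalized(v: Sequence[float]) -> List[float]:
    arr = np.asarray(v, dtype=float)
    return list(arr / arr.sum())


class CohortParams(BaseModel):
    """Generator parameters: observed counts plus per-level conditionals.

    The level marginal and the per-level probability of a reference-high
    score derive from the raw cross-tabulation counts, so the implied
    accuracy statistics are exactly those of the encoded table.
    """

    #: visits per triage level 1..5 in the reference cross-tabulation
    level_counts: Tuple[int, int, int, int, int]
    #: of those, visits scored reference-high (warning score >= cutoff)
    pews_high_counts: Tuple[int, int, int, int, int]
    sex_male_given_level: Tuple[float, ...]
    age_band_given_level: Tuple[Tuple[float, ...], ...]  # 5 x 7
    complaint_medical_given_level: Tuple[float, ...]
    outcome_given_level: Tuple[Tuple[float, ...], ...]  # 5 x 4 (OUTCOMES order)
    diagnosis_given_level: Tuple[Tuple[float, ...], ...]  # 5 x 12 (DIAGNOSES order)
    los_mean: Tuple[float, ...]  # minutes, per level
    los_sd: Tuple[float, ...]  # minutes, per level
    cutoff: int = Field(ge=1, le=9, default=DEFAULT_CUTOFF)
    #: fraction of level-1 visits entering through the critical shortcut
    critical_fraction_level1: float = Field(ge=0.0, le=1.0, default=0.5)
    #: fraction of visits with vital signs recorded (in-range when present)
    vitals_recorded_fraction: float = Field(ge=0.0, le=1.0, default=0.5)

    @model_validator(mode="after")
    def _check(self) -> "CohortParams":
        if any(c < 0 for c in self.level_counts) or sum(self.level_counts) == 0:
            raise ValueError("level_counts must be non-negative with positive total")
        for hi, tot in zip(self.pews_high_counts, self.level_counts):
            if not 0 <= hi <= tot:
                raise ValueError("pews_high_counts must be within level_counts")
        for name, rows, width in (
            ("age_band_given_level", self.age_band_given_level, len(AGE_BANDS)),
            ("outcome_given_level", self.outcome_given_level, len(OUTCOMES)),
            ("diagnosis_given_level", self.diagnosis_given_level, len(DIAGNOSES)),
        ):
            if len(rows) != 5:
                raise ValueError(f"{name} must have 5 rows")
            for row in rows:
                if len(row) != width:
                    raise ValueError(f"{name} rows must have {width} entries")
                if any(p < 0 or p > 1 for p in row):
                    raise ValueError(f"{name} probabilities must lie in [0,1]")
                if abs(sum(row) - 1.0) > _SUM_TOL:
                    raise ValueError(f"{name} rows must sum to 1 within {_SUM_TOL}")
        for name, vec in (
            ("sex_male_given_level", self.sex_male_given_level),
            ("complaint_medical_given_level", self.complaint_medical_given_level),
        ):
            if len(vec) != 5 or any(p < 0 or p > 1 for p in vec):
                raise ValueError(f"{name} must be 5 probabilities in [0,1]")
        if len(self.los_mean) != 5 or len(self.los_sd) != 5:
            raise ValueError("los_mean and los_sd must have 5 entries")
        if any(sd <= 0 for sd in self.los_sd):
            raise ValueError("los_sd must be positive")
        return self

    @property
    def level_marginal(self) -> np.ndarray:
        counts = np.asarray(self.level_counts, dtype=float)
        return counts / counts.sum()

    @property
    def pews_high_given_level(self) -> np.ndarray:
        hi = np.asarray(self.pews_high_counts, dtype=float)
        tot = np.asarray(self.level_counts, dtype=float)
        return np.divide(hi, tot, out=np.zeros(5), where=tot > 0)


def default_params() -> CohortParams:
    """Parameters encoding the validation cohort (n = 100,506).

    The level totals, the per-level reference-high counts, and every
    conditional below are taken cell-for-cell from the published
    characteristics and agreement tables of the validation study cohort;
    conditional rows are renormalized to sum exactly to 1.
    """
    return CohortParams(
        # cross-tabulation: column totals and reference-high row, levels 1..5
        level_counts=(217, 16575, 34832, 41302, 7580),
        pews_high_counts=(82, 1628, 489, 38, 1),
        # % male by level
        sex_male_given_level=(0.599, 0.594, 0.551, 0.529, 0.547),
        # % per age band (0-28d, 28d-3m, 3m-1y, 1-3y, 3-7y, 7-12y, 12-18y)
        age_band_given_level=tuple(
            tuple(_normalized(row))
            for row in (
                (1.8, 2.8, 14.3, 29.0, 24.9, 14.3, 12.9),
                (6.5, 7.9, 12.9, 21.4, 22.2, 15.6, 13.6),
                (0.2, 1.6, 11.5, 25.9, 29.7, 18.3, 12.9),
                (0.2, 1.2, 7.1, 20.1, 27.2, 26.1, 18.1),
                (0.4, 1.6, 11.8, 22.6, 26.9, 21.6, 15.1),
            )
        ),
        # % medical (vs surgical) complaint by level
        complaint_medical_given_level=(0.825, 0.864, 0.758, 0.611, 0.552),
        # % (icu, hospitalization, transfer, discharged) by level
        outcome_given_level=tuple(
            tuple(_normalized(row))
            for row in (
                (13.8, 53.5, 0.0, 32.7),
                (0.5, 21.8, 0.3, 77.4),
                (0.0, 4.8, 0.1, 95.1),
                (0.0, 1.0, 0.0, 99.0),
                (0.0, 0.6, 0.0, 99.4),
            )
        ),
        # % per named diagnosis by level; remainder -> "other"
        diagnosis_given_level=tuple(
            tuple(_normalized(row + (100.0 - sum(row),)))
            for row in (
                (0.5, 3.7, 22.1, 8.3, 0.5, 1.4, 6.5, 0.9, 0.9, 4.6, 0.0),
                (6.8, 12.0, 10.0, 6.6, 1.6, 4.5, 3.4, 4.9, 1.5, 0.7, 2.8),
                (18.4, 14.5, 3.1, 1.4, 2.5, 5.8, 6.5, 6.6, 2.5, 0.6, 1.4),
                (17.2, 4.5, 0.1, 0.1, 1.2, 3.7, 3.3, 14.7, 15.6, 0.3, 0.4),
                (17.6, 1.6, 0.1, 0.2, 0.8, 4.1, 15.6, 11.4, 11.0, 0.2, 0.0),
            )
        ),
        # length of stay, mean +/- sd minutes by level
        los_mean=(176.0, 136.9, 125.0, 107.0, 96.5),
        los_sd=(124.4, 88.9, 82.6, 69.7, 63.1),
        cutoff=4,
    )


def reference_crosstab(params: CohortParams) -> CrossTab:
    """The 2x5 reference table encoded by the parameters (exact counts)."""
    hi = np.asarray(params.pews_high_counts, dtype=np.int64)
    tot = np.asarray(params.level_counts, dtype=np.int64)
    return CrossTab(np.vstack([hi, tot - hi]))


def implied_metrics(params: CohortParams) -> Dict[str, float]:
    """Closed-form expected accuracy statistics under the parameters.

    Computed analytically from the level marginal and the per-level
    reference-high probabilities — no sampling.  Percent scale for the
    proportions, ratio scale for the likelihood ratios.
    """
    m = params.level_marginal
    q = params.pews_high_given_level
    p_tp = float((m[:2] * q[:2]).sum())
    p_fn = float((m[2:] * q[2:]).sum())
    p_fp = float((m[:2] * (1 - q[:2])).sum())
    p_tn = float((m[2:] * (1 - q[2:])).sum())
    sens = p_tp / (p_tp + p_fn)
    spec = p_tn / (p_tn + p_fp)
    return {
        "sensitivity": 100 * sens,
        "specificity": 100 * spec,
        "ppv": 100 * p_tp / (p_tp + p_fp),
        "npv": 100 * p_tn / (p_tn + p_fn),
        "lr_pos": sens / (1 - spec) if spec < 1 else float("inf"),
        "lr_neg": (1 - sens) / spec if spec > 0 else float("inf"),
        "agreement": 100 * (p_tp + p_tn),
        "over_triage": 100 * p_fp,
        "under_triage": 100 * p_fn,
    }


_STREAMS = (
    "level",
    "acuity_phase",
    "pews_total",
    "pews_split",
    "sex",
    "age_band",
    "age_within",
    "complaint",
    "item",
    "critical",
    "diagnosis",
    "outcome",
    "los",
    "vitals_recorded",
    "heart_rate",
    "resp_rate",
    "spo2",
)


def _uniforms(seed: int, n: int) -> Dict[str, np.ndarray]:
    """One independent uniform stream per attribute, one draw per visit
    (the acuity stream instead draws one random phase per level)."""
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    out = {}
    for name, child in zip(_STREAMS, children):
        rng = np.random.default_rng(child)
        out[name] = rng.random(5) if name == "acuity_phase" else rng.random(n)
    return out


def _categorical(u: np.ndarray, cum_rows: np.ndarray, row_idx: np.ndarray) -> np.ndarray:
    """Inverse-CDF categorical draw with a per-visit distribution row."""
    idx = (u[:, None] > cum_rows[row_idx]).sum(axis=1)
    return np.minimum(idx, cum_rows.shape[1] - 1)


def _pews_compositions() -> Dict[int, np.ndarray]:
    """All (behavior, cardiovascular, respiratory) splits of each total."""
    comps: Dict[int, List[Tuple[int, int, int]]] = {t: [] for t in range(10)}
    for b in range(4):
        for c in range(4):
            for r in range(4):
                comps[b + c + r].append((b, c, r))
    return {t: np.asarray(v) for t, v in comps.items()}


def generate(
    n: int,
    params: Optional[CohortParams] = None,
    seed: int = 0,
    config: Optional[TriageConfig] = None,
) -> pd.DataFrame:
    """Sample ``n`` synthetic visits as a visit-table DataFrame.

    Latent truth columns ``intended_level`` and ``intended_acuity`` are
    included alongside the raw presentation fields, so the full pipeline
    can be validated against the generator's ground truth.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    params = params or default_params()
    config = config or default_config()
    u = _uniforms(seed, n)

    level_idx = np.minimum(
        np.searchsorted(np.cumsum(params.level_marginal), u["level"]), 4
    )
    levels = level_idx + 1

    # reference acuity | level by systematic (quota) sampling with a random
    # phase per level: among any k consecutive same-level visits the number
    # of high-acuity ones is within 1 of k*q, so the cohort's joint
    # triage x acuity composition tracks the target probabilities for every
    # seed while remaining random and prefix-stable.
    q_by_level = params.pews_high_given_level
    acuity_high = np.zeros(n, dtype=bool)
    for li in range(5):
        mask = level_idx == li
        m = int(mask.sum())
        if m == 0:
            continue
        q = q_by_level[li]
        phase = u["acuity_phase"][li] + np.arange(1, m + 1) * q
        acuity_high[mask] = np.floor(phase) > np.floor(phase - q)

    # warning-score total: uniform over {cutoff..9} (high) / {0..cutoff-1} (low)
    cut = params.cutoff
    totals = np.where(
        acuity_high,
        cut + np.minimum((u["pews_total"] * (10 - cut)).astype(int), 9 - cut),
        np.minimum((u["pews_total"] * cut).astype(int), cut - 1),
    )
    comps = _pews_compositions()
    split = np.empty((n, 3), dtype=int)
    for t in np.unique(totals):
        mask = totals == t
        options = comps[int(t)]
        pick = np.minimum((u["pews_split"][mask] * len(options)).astype(int),
                          len(options) - 1)
        split[mask] = options[pick]

    sex = np.where(
        u["sex"] < np.asarray(params.sex_male_given_level)[level_idx],
        "male",
        "female",
    )

    # age band | level; for levels 3-5 the newborn band is excluded (and the
    # row renormalized) so the automatic newborn override cannot contradict
    # the intended level.
    age_rows = np.asarray(params.age_band_given_level, dtype=float).copy()
    age_rows[2:, 0] = 0.0
    age_rows /= age_rows.sum(axis=1, keepdims=True)
    band_idx = _categorical(u["age_band"], np.cumsum(age_rows, axis=1), level_idx)
    # integer ages uniform over the band's valid integers [ceil(lo), ceil(hi)-1]
    a_lo = np.ceil(np.asarray([b.lo_days for b in AGE_BANDS]))[band_idx].astype(int)
    a_hi = (np.ceil(np.asarray([b.hi_days for b in AGE_BANDS])) - 1)[band_idx].astype(
        int
    )
    age_days = np.minimum(
        a_lo + (u["age_within"] * (a_hi - a_lo + 1)).astype(int), a_hi
    )

    medical = u["complaint"] < np.asarray(params.complaint_medical_given_level)[
        level_idx
    ]
    complaint_type = np.where(medical, "medical", "surgical")

    # one complaint item whose base level equals the intended level
    by_level_type = config.items_by_level_and_type()
    items = np.empty(n, dtype=object)
    categories = np.empty(n, dtype=object)
    for lv in LEVELS:
        for ctype in ("medical", "surgical"):
            pool = by_level_type.get((lv, ctype))
            mask = (levels == lv) & (complaint_type == ctype)
            if not mask.any():
                continue
            if not pool:
                raise ValueError(
                    f"item table has no {ctype} item at level {lv}; cannot emulate"
                )
            pick = np.minimum((u["item"][mask] * len(pool)).astype(int), len(pool) - 1)
            items[mask] = [pool[j].label for j in pick]
            categories[mask] = [pool[j].category for j in pick]

    critical = (levels == 1) & (u["critical"] < params.critical_fraction_level1)

    diag_cum = np.cumsum(np.asarray(params.diagnosis_given_level), axis=1)
    diagnosis = np.asarray(DIAGNOSES)[_categorical(u["diagnosis"], diag_cum, level_idx)]

    out_cum = np.cumsum(np.asarray(params.outcome_given_level), axis=1)
    outcome = np.asarray(OUTCOMES)[_categorical(u["outcome"], out_cum, level_idx)]

    mu = np.asarray(params.los_mean)[level_idx]
    sd = np.asarray(params.los_sd)[level_idx]
    los = stats.truncnorm.ppf(u["los"], -mu / sd, np.inf, loc=mu, scale=sd)
    los = np.round(los, 1)

    # vitals: recorded for a fraction of visits, always inside the age-band
    # reference range (the generator emulates the missing-as-normal study
    # convention; abnormal vitals are not simulated)
    recorded = u["vitals_recorded"] < params.vitals_recorded_fraction
    hr = np.full(n, np.nan)
    rr = np.full(n, np.nan)
    spo2 = np.full(n, np.nan)
    glasgow = np.full(n, np.nan)
    band_labels = [b.label for b in AGE_BANDS]
    range_idx = {lbl: br for lbl, br in ((b.age_band, b) for b in config.vital_ranges)}
    for bi, lbl in enumerate(band_labels):
        br = range_idx.get(lbl)
        if br is None:
            continue
        mask = recorded & (band_idx == bi)
        if not mask.any():
            continue
        hr_r, rr_r, sp_r = br.vitals["heart_rate"], br.vitals["resp_rate"], br.vitals["spo2"]
        hr[mask] = np.floor(hr_r.low + u["heart_rate"][mask] * (hr_r.high - hr_r.low))
        rr[mask] = np.floor(rr_r.low + u["resp_rate"][mask] * (rr_r.high - rr_r.low))
        spo2[mask] = np.floor(sp_r.low + u["spo2"][mask] * (sp_r.high + 1 - sp_r.low))
        glasgow[mask] = 15
    spo2 = np.minimum(spo2, 100)

    return pd.DataFrame(
        {
            "visit_id": [f"V{i + 1:07d}" for i in range(n)],
            "age_days": age_days,
            "sex": sex,
            "critical_flag": critical,
            "items": items,
            "risk_conditions": np.where(age_days < 28, "newborn", ""),
            "glasgow": glasgow,
            "heart_rate": hr,
            "resp_rate": rr,
            "spo2": spo2,
            "oxygen_support": np.full(n, np.nan),
            "pews_behavior": split[:, 0],
            "pews_cardiovascular": split[:, 1],
            "pews_respiratory": split[:, 2],
            "outcome": outcome,
            "los_minutes": los,
            "complaint_type": complaint_type,
            "complaint_category": categories,
            "diagnosis": diagnosis,
            "intended_level": levels,
            "intended_acuity": np.where(acuity_high, "high", "low"),
        }
    )
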
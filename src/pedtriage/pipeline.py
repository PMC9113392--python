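"""Table-level glue: run the rule engine and the warning score over a
visit DataFrame, appending the derived columns the validation needs."""

from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .config import TriageConfig, default_config
from .pews import DEFAULT_CUTOFF, PewsComponents, classify_acuity, total_pews
from .triage import Presentation, VitalSigns, evaluate

_ITEM_SEP = ";"


def _split_labels(cell) -> frozenset:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return frozenset()
    return frozenset(s.strip() for s in str(cell).split(_ITEM_SEP) if s.strip())


def _opt(value, cast=float):
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return None
    return cast(value)


def presentation_from_row(row: pd.Series) -> Presentation:
    """Build an engine :class:`Presentation` from one visit-table row."""
    return Presentation(
        age_days=int(row["age_days"]),
        sex=row["sex"],
        critical_flag=bool(row["critical_flag"]),
        selected_items=_split_labels(row.get("items")),
        risk_conditions=_split_labels(row.get("risk_conditions")),
        vitals=VitalSigns(
            glasgow=_opt(row.get("glasgow"), int),
            heart_rate=_opt(row.get("heart_rate")),
            resp_rate=_opt(row.get("resp_rate")),
            spo2=_opt(row.get("spo2")),
            oxygen_support=_opt(row.get("oxygen_support")),
        ),
    )


def apply_triage(
    visits: pd.DataFrame, config: Optional[TriageConfig] = None
) -> pd.DataFrame:
    """Append ``suggested_level``, ``final_level`` and ``fractile_minutes``."""
    config = config or default_config()
    suggested, final, fractile = [], [], []
    for _, row in visits.iterrows():
        res = evaluate(presentation_from_row(row), config)
        suggested.append(res.suggested_level)
        final.append(res.final_level)
        fractile.append(res.fractile_minutes)
    out = visits.copy()
    out["suggested_level"] = suggested
    out["final_level"] = final
    out["fractile_minutes"] = fractile
    return out


def apply_pews(visits: pd.DataFrame, cutoff: int = DEFAULT_CUTOFF) -> pd.DataFrame:
    """Append ``pews_total`` and ``acuity`` from the three component columns.

    Missing components score 0 (missing-as-normal convention).
    """
    out = visits.copy()
    comps = (
        out[["pews_behavior", "pews_cardiovascular", "pews_respiratory"]]
        .fillna(0)
        .astype(int)
    )
    totals, acuity = [], []
    for b, c, r in comps.itertuples(index=False):
        score = total_pews(PewsComponents(int(b), int(c), int(r)))
        totals.append(score.total)
        acuity.append(classify_acuity(score, cutoff))
    out["pews_total"] = totals
    out["acuity"] = acuity
    return out
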
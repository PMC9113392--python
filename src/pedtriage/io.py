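"""Visit-table readers/writers and deterministic report rendering.

Visit tables are CSV (UTF-8, comma-separated, mandatory header) or
JSON-lines with identical field names.  CSV files carry a schema-version
comment line (``# pedtriage-visit-table v1``) ahead of the header; an empty
string encodes an absent value — never 0.  Reader-level exclusion filters
mirror a diagnostic study's participant flow (psychiatric visits, left
without being seen, unreliable vitals, missing outcome) and report a
STARD-style disposition count per reason.
"""

from __future__ import annotations

import io as _io
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Optional, Tuple

import numpy as np
import pandas as pd

from .cohort import StratumReport
from .errors import SchemaError
from .metrics import CrossTab, DiagnosticSummary, IntervalEstimate

SCHEMA_HEADER = "# pedtriage-visit-table v1"

REQUIRED_COLUMNS = (
    "visit_id",
    "age_days",
    "sex",
    "critical_flag",
    "items",
    "risk_conditions",
    "glasgow",
    "heart_rate",
    "resp_rate",
    "spo2",
    "oxygen_support",
    "pews_behavior",
    "pews_cardiovascular",
    "pews_respiratory",
    "outcome",
    "los_minutes",
)

EXCLUSION_FLAGS = ("psychiatric", "left_without_being_seen", "unreliable_vitals")

SEX_VOCABULARY = ("male", "female")


@dataclass
class Disposition:
    """Participant-flow accounting for one read: rows in, rows excluded."""

    total_rows: int = 0
    included: int = 0
    excluded: Dict[str, int] = field(default_factory=dict)

    def as_dict(self) -> Dict[str, int]:
        return {
            "total_rows": self.total_rows,
            "included": self.included,
            **{f"excluded_{k}": v for k, v in self.excluded.items()},
        }


def _is_truthy(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in ("1", "true", "yes")
    return bool(value) and not (isinstance(value, float) and math.isnan(value))


def _validate(df: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    dup = df["visit_id"][df["visit_id"].duplicated()]
    if len(dup):
        raise SchemaError(f"duplicate visit_id value(s): {sorted(set(dup))[:10]}")
    bad_sex = df["sex"].notna() & ~df["sex"].isin(SEX_VOCABULARY)
    if bad_sex.any():
        row = int(np.flatnonzero(bad_sex)[0])
        raise SchemaError(
            f"row {row}, column 'sex': {df['sex'].iloc[row]!r} not in "
            f"{list(SEX_VOCABULARY)}"
        )
    age = pd.to_numeric(df["age_days"], errors="coerce")
    bad_age = df["age_days"].notna() & (age.isna() | (age < 0))
    if bad_age.any():
        row = int(np.flatnonzero(bad_age)[0])
        raise SchemaError(
            f"row {row}, column 'age_days': {df['age_days'].iloc[row]!r} is not a "
            "non-negative number"
        )


def read_visits(
    path,
    dialect: str = "csv",
    apply_filters: bool = True,
) -> Tuple[pd.DataFrame, Disposition]:
    """Read a visit table, optionally applying the exclusion filters.

    Returns the included visits and the disposition counts.  With filters
    off, every schema-valid row is returned.
    """
    path = Path(path)
    if dialect == "csv":
        text = path.read_text(encoding="utf-8")
        if text.startswith("#"):
            header, _, rest = text.partition("\n")
            if not header.startswith("# pedtriage-visit-table"):
                raise SchemaError(f"unrecognized schema header {header!r}")
            text = rest
        df = pd.read_csv(_io.StringIO(text), dtype={"visit_id": str})
    elif dialect == "jsonl":
        df = pd.read_json(path, lines=True, dtype={"visit_id": str})
    else:
        raise ValueError(f"unknown dialect {dialect!r} (use 'csv' or 'jsonl')")
    # empty strings are absent values, never zeros
    df = df.replace({"": np.nan})
    _validate(df)

    disp = Disposition(total_rows=len(df))
    mask = pd.Series(True, index=df.index)
    if apply_filters:
        for flag in EXCLUSION_FLAGS:
            if flag in df.columns:
                hit = df[flag].map(_is_truthy)
            else:
                hit = pd.Series(False, index=df.index)
            disp.excluded[flag] = int((hit & mask).sum())
            mask &= ~hit
        no_outcome = df["outcome"].isna()
        disp.excluded["missing_outcome"] = int((no_outcome & mask).sum())
        mask &= ~no_outcome
    disp.included = int(mask.sum())
    return df.loc[mask].reset_index(drop=True), disp


def write_visits(df: pd.DataFrame, path, dialect: str = "csv") -> None:
    """Write a visit table; absent values serialize as empty strings."""
    path = Path(path)
    if dialect == "csv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(SCHEMA_HEADER + "\n")
            df.to_csv(fh, index=False)
    elif dialect == "jsonl":
        df.to_json(path, orient="records", lines=True)
    else:
        raise ValueError(f"unknown dialect {dialect!r} (use 'csv' or 'jsonl')")


# -- report rendering -------------------------------------------------------


def fmt1(x: Optional[float]) -> str:
    """One-decimal rendering with the literal ``NA`` for undefined values."""
    if x is None or (isinstance(x, float) and (math.isnan(x) or math.isinf(x))):
        return "NA"
    return f"{x:.1f}"


def interval_to_dict(est: IntervalEstimate) -> Dict[str, Optional[float]]:
    def r(v: float) -> Optional[float]:
        return None if math.isnan(v) or math.isinf(v) else round(v, 1)

    return {"point": r(est.point), "lower": r(est.lower), "upper": r(est.upper)}


def summary_to_dict(summary: DiagnosticSummary) -> Dict[str, object]:
    """JSON-ready rendering of a diagnostic summary, one-decimal precision."""
    out: Dict[str, object] = {"n": summary.n}
    for name in (
        "sensitivity",
        "specificity",
        "ppv",
        "npv",
        "lr_pos",
        "lr_neg",
        "agreement",
        "over_triage",
        "under_triage",
    ):
        out[name] = interval_to_dict(getattr(summary, name))
    return out


def summary_to_tsv(summary: DiagnosticSummary) -> str:
    lines = ["statistic\tpoint\tlower\tupper"]
    d = summary_to_dict(summary)
    for name, val in d.items():
        if name == "n":
            continue
        lines.append(
            "\t".join(
                [name] + [fmt1(val[k] if val[k] is not None else math.nan)
                          for k in ("point", "lower", "upper")]
            )
        )
    lines.append(f"n\t{summary.n}\t\t")
    return "\n".join(lines) + "\n"


def crosstab_to_tsv(crosstab: CrossTab) -> str:
    return crosstab.to_frame().to_csv(sep="\t")


def strata_to_frame(reports: Iterable[StratumReport]) -> pd.DataFrame:
    """Stratified-validity reports as one row per stratum (NA-tolerant)."""
    rows = []
    for rep in reports:
        row = {
            "stratum": rep.stratum,
            "n": rep.n,
            "test_high_pct": fmt1(rep.prevalence_test_high),
            "ref_high_pct": fmt1(rep.prevalence_ref_high),
        }
        if rep.summary is None:
            row.update(
                {k: "NA" for k in ("sensitivity", "specificity", "ppv", "npv",
                                   "lr_pos", "lr_neg")}
            )
        else:
            for k in ("sensitivity", "specificity", "ppv", "npv", "lr_pos", "lr_neg"):
                row[k] = fmt1(getattr(rep.summary, k).point)
        rows.append(row)
    return pd.DataFrame(rows)


def write_report(obj, format: str, path) -> None:
    """Serialize a summary / crosstab / strata table deterministically."""
    path = Path(path)
    if format == "json":
        if isinstance(obj, DiagnosticSummary):
            payload = summary_to_dict(obj)
        elif isinstance(obj, CrossTab):
            payload = obj.to_frame().to_dict()
        elif isinstance(obj, pd.DataFrame):
            payload = obj.to_dict(orient="records")
        else:
            payload = obj
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    elif format == "tsv":
        if isinstance(obj, DiagnosticSummary):
            path.write_text(summary_to_tsv(obj))
        elif isinstance(obj, CrossTab):
            path.write_text(crosstab_to_tsv(obj))
        elif isinstance(obj, pd.DataFrame):
            path.write_text(obj.to_csv(sep="\t", index=False))
        else:
            raise TypeError(f"cannot render {type(obj).__name__} as TSV")
    else:
        raise ValueError(f"unknown report format {format!r} (use 'tsv' or 'json')")
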
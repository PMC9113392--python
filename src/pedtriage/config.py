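"""Configuration models for the triage engine and early-warning-score rubric.

The triage rule is fully configuration-driven: the complaint-item table, the
risk-condition overrides, the age-banded vital-sign reference ranges and the
warning-score rubric all live in a single schema-validated YAML document.
The document shipped with the package (``data/default_config.yaml``) is a
synthetic fixture: its item labels and reference ranges are clinically
plausible placeholders that exercise every pathway of the rule engine, and
they make no claim to fidelity with any deployed triage tool.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Dict, List, Literal, Optional, Tuple

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import ConfigError, RangeCoverageError

#: Calendar conversions used to place the age-band boundaries on a day scale.
DAYS_PER_MONTH = 30.44
DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class AgeBand:
    """Half-open age interval [lo_days, hi_days) with a display label."""

    label: str
    lo_days: float
    hi_days: float

    def contains(self, age_days: float) -> bool:
        return self.lo_days <= age_days < self.hi_days


#: The seven pediatric age bands used for stratified reporting and for the
#: vital-sign reference ranges.  Boundaries are half-open on the day scale.
AGE_BANDS: Tuple[AgeBand, ...] = (
    AgeBand("0-28d", 0.0, 28.0),
    AgeBand("28d-3m", 28.0, 3 * DAYS_PER_MONTH),
    AgeBand("3m-1y", 3 * DAYS_PER_MONTH, DAYS_PER_YEAR),
    AgeBand("1-3y", DAYS_PER_YEAR, 3 * DAYS_PER_YEAR),
    AgeBand("3-7y", 3 * DAYS_PER_YEAR, 7 * DAYS_PER_YEAR),
    AgeBand("7-12y", 7 * DAYS_PER_YEAR, 12 * DAYS_PER_YEAR),
    AgeBand("12-18y", 12 * DAYS_PER_YEAR, 18 * DAYS_PER_YEAR),
)

AGE_BAND_LABELS: Tuple[str, ...] = tuple(b.label for b in AGE_BANDS)

#: Age in days below which the automatic "newborn" risk condition matches.
NEWBORN_AGE_DAYS = 28


def age_band_of(age_days: float) -> AgeBand:
    """Return the age band containing ``age_days``.

    Raises :class:`RangeCoverageError` for ages at or above 18 years or
    negative ages, which are outside the pediatric scope.
    """
    for band in AGE_BANDS:
        if band.contains(age_days):
            return band
    raise RangeCoverageError(f"age {age_days} days is outside the covered 0-18y bands")


MEDICAL_CATEGORIES = (
    "ent",
    "pulmonary",
    "cardiovascular",
    "neurology",
    "digestive",
    "urology_nephrology",
    "gynecology",
    "dermatology",
    "endocrinology_metabolism",
    "infectious",
    "rheumatology_pain",
    "hematology",
    "poisoning",
    "other_medical",
)
SURGICAL_CATEGORIES = (
    "head_neck_trauma",
    "upper_limb_trauma",
    "lower_limb_trauma",
    "trunk_pelvis_urogenital_trauma",
    "burns",
    "other_surgical",
)
ALL_CATEGORIES = MEDICAL_CATEGORIES + SURGICAL_CATEGORIES


class TriageItem(BaseModel):
    """One complaint item of the triage table, carrying a base severity level."""

    label: str = Field(min_length=1)
    category: Literal[ALL_CATEGORIES]  # type: ignore[valid-type]
    base_level: int = Field(ge=1, le=5)

    @property
    def complaint_type(self) -> str:
        return "medical" if self.category in MEDICAL_CATEGORIES else "surgical"


class RiskConditionDef(BaseModel):
    """A risky situation/profile that forces at least a given severity level."""

    label: str = Field(min_length=1)
    assigned_level: int = Field(ge=1, le=5, default=2)


class VitalRange(BaseModel):
    """Acceptable range for one vital sign; out-of-range escalates triage."""

    low: Optional[float] = None
    high: Optional[float] = None
    escalation_level: int = Field(ge=1, le=5, default=2)

    def out_of_range(self, value: float) -> bool:
        if self.low is not None and value < self.low:
            return True
        if self.high is not None and value > self.high:
            return True
        return False


class AgeBandRanges(BaseModel):
    """Vital-sign reference ranges for one age band."""

    age_band: Literal[AGE_BAND_LABELS]  # type: ignore[valid-type]
    vitals: Dict[Literal["glasgow", "heart_rate", "resp_rate", "spo2"], VitalRange]


class PewsRubric(BaseModel):
    """Maps raw observation labels to 0-3 component scores.

    The rubric shipped by default uses Monaghan-style band labels; it is a
    documented stand-in, since the validation pipeline itself only consumes
    the three component integers.
    """

    behavior: Dict[str, int]
    cardiovascular: Dict[str, int]
    respiratory: Dict[str, int]

    @model_validator(mode="after")
    def _scores_in_range(self) -> "PewsRubric":
        for comp in ("behavior", "cardiovascular", "respiratory"):
            bands = getattr(self, comp)
            if not bands:
                raise ValueError(f"rubric component {comp!r} declares no bands")
            bad = {k: v for k, v in bands.items() if not 0 <= v <= 3}
            if bad:
                raise ValueError(f"rubric scores outside 0..3 in {comp}: {bad}")
        return self


class TriageConfig(BaseModel):
    """Complete engine configuration: items, risk overrides, ranges, rubric."""

    version: str
    items: List[TriageItem]
    risk_conditions: List[RiskConditionDef]
    vital_ranges: List[AgeBandRanges]
    pews_rubric: PewsRubric
    pews_cutoff: int = Field(ge=1, le=9, default=4)
    #: Triage level forced when the patient is on supplemental oxygen
    #: (any positive flow); ``None`` disables the rule.
    oxygen_escalation_level: Optional[int] = Field(ge=1, le=5, default=2)

    @field_validator("items")
    @classmethod
    def _unique_item_labels(cls, items: List[TriageItem]) -> List[TriageItem]:
        seen = set()
        for it in items:
            if it.label in seen:
                raise ValueError(f"duplicate item label {it.label!r}")
            seen.add(it.label)
        return items

    @model_validator(mode="after")
    def _build_indexes(self) -> "TriageConfig":
        object.__setattr__(self, "_item_index", {it.label: it for it in self.items})
        object.__setattr__(
            self, "_risk_index", {rc.label: rc for rc in self.risk_conditions}
        )
        object.__setattr__(
            self, "_range_index", {br.age_band: br for br in self.vital_ranges}
        )
        return self

    # -- lookup helpers -----------------------------------------------------

    @property
    def item_index(self) -> Dict[str, TriageItem]:
        return self._item_index  # type: ignore[attr-defined]

    @property
    def risk_index(self) -> Dict[str, RiskConditionDef]:
        return self._risk_index  # type: ignore[attr-defined]

    def ranges_for_age(self, age_days: float) -> AgeBandRanges:
        band = age_band_of(age_days)
        try:
            return self._range_index[band.label]  # type: ignore[attr-defined]
        except KeyError:
            raise RangeCoverageError(
                f"no vital-sign ranges configured for age band {band.label!r}"
            ) from None

    def items_by_level_and_type(self) -> Dict[Tuple[int, str], List[TriageItem]]:
        """Index items by (base_level, medical|surgical), labels sorted."""
        out: Dict[Tuple[int, str], List[TriageItem]] = {}
        for it in sorted(self.items, key=lambda i: i.label):
            out.setdefault((it.base_level, it.complaint_type), []).append(it)
        return out


def load_config(path) -> TriageConfig:
    """Load and validate a YAML/JSON engine configuration file."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    try:
        return TriageConfig.model_validate(raw)
    except Exception as exc:  # pydantic ValidationError and friends
        raise ConfigError(f"invalid triage configuration {path}: {exc}") from exc


@lru_cache(maxsize=1)
def default_config() -> TriageConfig:
    """The synthetic default configuration shipped with the package."""
    ref = resources.files("pedtriage.data").joinpath("default_config.yaml")
    raw = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return TriageConfig.model_validate(raw)
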
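"""Five-level pediatric triage rule engine.

The rule models the nurse-facing decision sequence of a computerized
pediatric triage tool:

1. *Critical shortcut* — a patient in overt cardio-respiratory failure at
   the door is assigned Level 1 and the structured triage stops.
2. *Item aggregation* — the nurse selects every complaint item that
   applies; each item carries a base severity level and the most severe
   (numerically smallest) one determines the suggested level.
3. *Moderation* — risky profiles (newborns, immunosuppressed patients, ...)
   and out-of-range vital signs can only upgrade the level, never downgrade
   it.  Vital signs that were not recorded are treated as normal.
4. *Nurse override* — the nurse may upgrade the final level but any
   requested downgrade is refused and logged.

Levels map to fractile response times: the target maximum delay, in
minutes, before the patient must be seen by a physician.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import FrozenSet, Iterable, Optional, Set, Tuple

from .config import NEWBORN_AGE_DAYS, TriageConfig
from .errors import (
    InvalidLevelError,
    NoItemsError,
    UnknownItemError,
)

LEVELS = (1, 2, 3, 4, 5)

#: Target maximum minutes-to-physician for each triage level.
FRACTILE_MINUTES = {1: 0, 2: 15, 3: 60, 4: 120, 5: 240}


def fractile_target(level: int) -> int:
    """Fractile response time (minutes) attached to a triage level."""
    try:
        return FRACTILE_MINUTES[level]
    except (KeyError, TypeError):
        raise InvalidLevelError(level) from None


@dataclass(frozen=True)
class VitalSigns:
    """Vital signs recorded at triage; ``None`` means not recorded.

    Absence is a first-class state (never encoded as 0): a missing value is
    treated as normal by the moderation step.
    """

    glasgow: Optional[int] = None
    heart_rate: Optional[float] = None
    resp_rate: Optional[float] = None
    spo2: Optional[float] = None
    oxygen_support: Optional[float] = None  # L/min; 0 = ambient air

    def __post_init__(self):
        if self.glasgow is not None and not 3 <= self.glasgow <= 15:
            raise ValueError(f"glasgow {self.glasgow} outside 3..15")
        if self.spo2 is not None and not 0 <= self.spo2 <= 100:
            raise ValueError(f"spo2 {self.spo2} outside 0..100")
        for name in ("heart_rate", "resp_rate", "oxygen_support"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")


@dataclass(frozen=True)
class Presentation:
    """One ED presentation as seen by the triage nurse."""

    age_days: int
    sex: str  # "male" | "female"
    critical_flag: bool = False
    selected_items: FrozenSet[str] = frozenset()
    risk_conditions: FrozenSet[str] = frozenset()
    vitals: VitalSigns = field(default_factory=VitalSigns)

    def __post_init__(self):
        if self.age_days < 0:
            raise ValueError("age_days must be non-negative")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        object.__setattr__(self, "selected_items", frozenset(self.selected_items))
        object.__setattr__(self, "risk_conditions", frozenset(self.risk_conditions))
        if (
            not self.critical_flag
            and not self.risk_conditions
            and not self.selected_items
        ):
            raise ValueError(
                "a non-critical presentation without risk conditions must select "
                "at least one complaint item"
            )


@dataclass(frozen=True)
class TriageResult:
    """Outcome of the rule engine, with a moderation/override audit trail."""

    suggested_level: int
    final_level: int
    moderation_applied: Tuple[str, ...] = ()  # subset of {"critical","risk","vitals"}
    override_applied: bool = False
    override_refused: bool = False
    fractile_minutes: int = 0

    def __post_init__(self):
        for lv in (self.suggested_level, self.final_level):
            if lv not in FRACTILE_MINUTES:
                raise InvalidLevelError(lv)
        if self.final_level > self.suggested_level:
            raise ValueError(
                "final_level may only be more severe (numerically lower) than "
                "suggested_level"
            )


def aggregate_items(selected: Iterable[str], config: TriageConfig) -> int:
    """Most severe base level over the selected complaint items.

    Severity increases as the numeric level decreases, so the aggregate is
    the *minimum* of the item base levels.
    """
    labels = list(selected)
    if not labels:
        raise NoItemsError("no complaint items selected")
    levels = []
    for label in labels:
        item = config.item_index.get(label)
        if item is None:
            raise UnknownItemError(label)
        levels.append(item.base_level)
    return min(levels)


def apply_risk_overrides(
    level: int,
    conditions: Set[str],
    age_days: int,
    config: TriageConfig,
) -> int:
    """Force the level up to the assigned level of any matching risk condition.

    The ``newborn`` condition is matched automatically from age (< 28 days)
    whether or not it was recorded.  Unknown condition labels are ignored:
    only configured conditions carry an assigned level.
    """
    if level not in FRACTILE_MINUTES:
        raise InvalidLevelError(level)
    matched = set(conditions)
    if age_days < NEWBORN_AGE_DAYS and "newborn" in config.risk_index:
        matched.add("newborn")
    assigned = [
        config.risk_index[c].assigned_level for c in matched if c in config.risk_index
    ]
    return min([level] + assigned)


def moderate_by_vitals(
    level: int,
    vitals: VitalSigns,
    age_days: int,
    config: TriageConfig,
) -> int:
    """Upgrade the level for any recorded vital outside its age-band range.

    Missing vitals are treated as normal.  Supplemental oxygen (flow > 0)
    escalates via the configured oxygen rule, if any.
    """
    if level not in FRACTILE_MINUTES:
        raise InvalidLevelError(level)
    band_ranges = config.ranges_for_age(age_days)  # raises RangeCoverageError
    candidates = [level]
    for name in ("glasgow", "heart_rate", "resp_rate", "spo2"):
        value = getattr(vitals, name)
        if value is None:
            continue
        vr = band_ranges.vitals.get(name)
        if vr is not None and vr.out_of_range(value):
            candidates.append(vr.escalation_level)
    if (
        vitals.oxygen_support is not None
        and vitals.oxygen_support > 0
        and config.oxygen_escalation_level is not None
    ):
        candidates.append(config.oxygen_escalation_level)
    return min(candidates)


def evaluate(presentation: Presentation, config: TriageConfig) -> TriageResult:
    """Run the full rule: shortcut, aggregation, risk and vitals moderation."""
    if presentation.critical_flag:
        return TriageResult(
            suggested_level=1,
            final_level=1,
            moderation_applied=("critical",),
            fractile_minutes=fractile_target(1),
        )
    suggested = aggregate_items(presentation.selected_items, config)
    flags = []
    level = apply_risk_overrides(
        suggested, presentation.risk_conditions, presentation.age_days, config
    )
    if level < suggested:
        flags.append("risk")
    moderated = moderate_by_vitals(
        level, presentation.vitals, presentation.age_days, config
    )
    if moderated < level:
        flags.append("vitals")
    return TriageResult(
        suggested_level=suggested,
        final_level=moderated,
        moderation_applied=tuple(flags),
        fractile_minutes=fractile_target(moderated),
    )


def nurse_override(result: TriageResult, requested_level: int) -> TriageResult:
    """Apply an upgrade-only nurse override.

    A request for a more severe (numerically lower) level is applied; a
    downgrade request is refused, signalled on the returned result, and the
    level is left unchanged.
    """
    if requested_level not in FRACTILE_MINUTES:
        raise InvalidLevelError(requested_level)
    if requested_level < result.final_level:
        return replace(
            result,
            final_level=requested_level,
            override_applied=True,
            fractile_minutes=fractile_target(requested_level),
        )
    if requested_level > result.final_level:
        return replace(result, override_refused=True)
    return result
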
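"""Pediatric Early Warning Score (PEWS) computation and acuity classing.

The score sums three components — behavior / early signs of shock,
cardiovascular status (skin tone, capillary refill) and respiratory status
(rate, oxygen dependence) — each rated 0-3, for a 0-9 total.  A total at or
above a cutoff (4 by default) flags a high-level emergency, the reference
standard the triage rule is validated against.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

from .config import PewsRubric
from .errors import ComponentRangeError, RubricCoverageError

COMPONENTS = ("behavior", "cardiovascular", "respiratory")
DEFAULT_CUTOFF = 4


@dataclass(frozen=True)
class PewsComponents:
    behavior: int
    cardiovascular: int
    respiratory: int

    def __post_init__(self):
        for name in COMPONENTS:
            v = getattr(self, name)
            if not isinstance(v, int) or not 0 <= v <= 3:
                raise ComponentRangeError(f"{name} component {v!r} outside 0..3")


@dataclass(frozen=True)
class PewsScore:
    components: PewsComponents
    total: int


def total_pews(components: PewsComponents) -> PewsScore:
    """Sum the three 0-3 components into the 0-9 total."""
    total = components.behavior + components.cardiovascular + components.respiratory
    return PewsScore(components=components, total=total)


def classify_acuity(score: PewsScore, cutoff: int = DEFAULT_CUTOFF) -> str:
    """``"high"`` iff the total reaches the cutoff, else ``"low"``.

    The classification depends only on the total, never on how it is split
    across components.
    """
    if not 1 <= cutoff <= 9:
        raise ValueError(f"cutoff {cutoff} outside 1..9")
    return "high" if score.total >= cutoff else "low"


def components_from_observations(
    observations: Mapping[str, Optional[str]],
    rubric: PewsRubric,
) -> PewsComponents:
    """Map raw observation labels to component scores through a rubric.

    ``observations`` maps component name -> band label (or ``None``).  An
    absent observation scores 0, mirroring the missing-as-normal convention
    used for vital signs.
    """
    scores = {}
    for name in COMPONENTS:
        label = observations.get(name)
        if label is None:
            scores[name] = 0
            continue
        bands = getattr(rubric, name)
        if label not in bands:
            raise RubricCoverageError(
                f"observation {label!r} matches no band of rubric component {name!r}"
            )
        scores[name] = bands[label]
    return PewsComponents(**scores)
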
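"""Exception hierarchy shared across the package."""


class PedtriageError(Exception):
    """Base class for all package errors."""


class ConfigError(PedtriageError):
    """A configuration document failed validation."""


class NoItemsError(PedtriageError):
    """A presentation carried no complaint items where at least one is required."""


class UnknownItemError(PedtriageError):
    """A selected complaint item is not in the configured item table."""

    def __init__(self, label: str):
        self.label = label
        super().__init__(f"unknown triage item: {label!r}")


class InvalidLevelError(PedtriageError):
    """A triage level outside 1..5 was supplied."""

    def __init__(self, level):
        self.level = level
        super().__init__(f"invalid triage level: {level!r} (must be 1..5)")


class RangeCoverageError(PedtriageError):
    """No configured vital-sign reference range covers the patient's age band."""


class ComponentRangeError(PedtriageError):
    """An early-warning-score component lies outside 0..3."""


class RubricCoverageError(PedtriageError):
    """An observation label is not covered by any band of the scoring rubric."""


class IncompleteVisitError(PedtriageError):
    """Visits lacked the triage level or acuity class needed for cross-tabulation."""

    def __init__(self, offenders):
        self.offenders = list(offenders)
        super().__init__(
            f"{len(self.offenders)} visit(s) lack a triage level or acuity class: "
            f"{self.offenders[:10]}"
        )


class EmptyTableError(PedtriageError):
    """A contingency table with zero total count cannot be summarised."""


class DegenerateMarginError(PedtriageError):
    """A contingency table has a zero row or column margin."""


class InsufficientGroupsError(PedtriageError):
    """Fewer than two usable groups were available for a between-group analysis."""


class OutcomeVocabularyError(PedtriageError):
    """An outcome label is outside the declared vocabulary."""

    def __init__(self, labels, vocabulary):
        self.labels = sorted(set(labels))
        super().__init__(
            f"unknown outcome label(s) {self.labels}; expected one of {sorted(vocabulary)}"
        )


class SchemaError(PedtriageError):
    """A visit table violated its schema (named row/column where possible)."""
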
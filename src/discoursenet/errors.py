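"""Exception hierarchy shared across the pipeline."""


class DiscourseNetError(Exception):
    """Base class for all package errors."""


class SchemaError(DiscourseNetError):
    """Input table is missing a required column or key."""


class RowError(DiscourseNetError):
    """A single input row is invalid (bad date, stance, or empty field)."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


class EmptyCorpusError(DiscourseNetError):
    """An operation requiring statements received none."""


class IntervalError(DiscourseNetError):
    """A date interval with start >= end."""


class SelfPairError(DiscourseNetError):
    """A pairwise operation was asked about an actor and itself."""


class DegenerateActorError(DiscourseNetError):
    """Average-activity normalization met an actor with zero statements."""


class TooFewActorsError(DiscourseNetError):
    """Network construction needs at least two actors."""


class CoverageError(DiscourseNetError):
    """A partition/assignment does not cover the required actor set."""


class UndefinedRatioError(DiscourseNetError):
    """External ratio requested for an isolated actor (degree 0)."""


class ConfigError(DiscourseNetError):
    """Invalid simulation or run configuration."""
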
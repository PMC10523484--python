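"""Exception hierarchy for qtrap."""


class QtrapError(Exception):
    """Base class for all qtrap errors."""


class TableParseError(QtrapError):
    """A tabular input file violated its grammar or an invariant.

    Carries the offending line number where one can be identified.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class TableSchemaError(QtrapError):
    """A required column or record type is missing or malformed."""


class LambdaCoverageError(QtrapError):
    """The λ windows do not tile [0, 1] (gap or overlap)."""


class ProfileGapError(QtrapError):
    """An interior bin of a work profile received no trajectory data."""

    def __init__(self, message: str, bins=()):
        self.bins = tuple(bins)
        super().__init__(message)


class UnstableTimestepError(QtrapError):
    """The Langevin timestep exceeds the overdamped stability bound."""
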
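"""Exception types shared across the package."""


class BPScreenError(Exception):
    """Base class for all package errors."""


class ConfigError(BPScreenError):
    """A configuration object violates an invariant.

    The message names the offending field.
    """


class IncompleteRecordError(BPScreenError):
    """A participant record is missing one or more of the three
    serial blood-pressure readings.  Readings are never imputed."""


class SchemaError(BPScreenError):
    """An input table is missing mandatory columns or contains
    values outside the documented schema."""


class DegenerateDesignError(BPScreenError):
    """The grouping structure cannot support the requested multilevel
    model (e.g., a single country or a single region)."""


class NoEventsError(BPScreenError):
    """The model outcome has zero positive cases."""


class ConvergenceError(BPScreenError):
    """The optimizer failed to converge; carries diagnostics."""

    def __init__(self, message: str, gradient_norm: float | None = None):
        super().__init__(message)
        self.gradient_norm = gradient_norm
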
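"""Exception types shared across the package.

All errors carry enough context (field, host id, missing dates, column names)
to diagnose a failure without re-running with a debugger; nothing is silently
imputed or skipped.
"""


class TickBurdenError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TickBurdenError):
    """A configuration field is invalid; the message names the field."""


class MissingDataError(TickBurdenError):
    """Required records are absent (e.g. days missing from a meteorology window)."""


class CoverageError(TickBurdenError):
    """A date or year falls outside the coverage of a supplied series."""


class SchemaError(TickBurdenError):
    """A required column is missing from a table."""


class SingularityError(TickBurdenError):
    """The design matrix is rank deficient; the message names collinear columns."""


class ValidationError(TickBurdenError):
    """Input values violate a precondition (negative counts, non-integers, ...)."""


class NonConvergenceError(TickBurdenError):
    """An iterative fit failed to converge and the caller asked for an exception."""
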
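"""Exception and warning types shared across the package."""


class TdfspecError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(TdfspecError, ValueError):
    """A parameter violates a precondition (non-positive width, unknown solvent, ...)."""


class DegenerateInputError(TdfspecError, ValueError):
    """Input is structurally valid but carries no usable signal (all-zero counts,
    a spectral slice without an interior maximum, an empty phase, ...)."""


class UndefinedGPError(DegenerateInputError):
    """GP is undefined because the channel-intensity denominator is zero."""


class InconsistentEstimatesError(TdfspecError, ValueError):
    """Derived quantities contradict each other (e.g. negative total shift)."""


class FormatError(TdfspecError, ValueError):
    """A file violates the expected on-disk dialect.

    Carries the 1-based line number when the offence is attributable to a line.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class TimeZeroUnavailable(TdfspecError):
    """The Fee–Maroncelli time-zero estimate cannot be formed.

    Raised when a reference spectrum is missing, e.g. for dyes insoluble in
    non-polar solvents; carries the reason so downstream results can record
    why the total shift and relaxation time are not computable.
    """

    def __init__(self, reason: str):
        self.reason = reason
        super().__init__(reason)


class TdfspecWarning(UserWarning):
    """Base class for package warnings."""


class CoverageWarning(TdfspecWarning):
    """The time window does not comfortably cover the relaxation kinetics."""


class RelaxationIncompleteWarning(TdfspecWarning):
    """The band-position trajectory has not plateaued inside the window."""


class FitRangeWarning(TdfspecWarning):
    """The fit range excludes channels needed to constrain the model."""
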
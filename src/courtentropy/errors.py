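"""Exception types shared across the package."""


class CourtEntropyError(Exception):
    """Base class for all package errors."""


class InvalidInputError(CourtEntropyError, ValueError):
    """A scalar argument is outside its domain (non-finite, wrong sign, ...)."""


class FormatError(CourtEntropyError, ValueError):
    """A stroke-log file does not match the expected column contract."""


class ValidationError(CourtEntropyError, ValueError):
    """A record, rally or match violates a structural invariant."""


class EmptyInputError(CourtEntropyError, ValueError):
    """An operation that needs at least one event received none."""


class InsufficientPointsError(CourtEntropyError, ValueError):
    """A spatial computation needs more points than were supplied."""


class DegenerateTestError(CourtEntropyError, ValueError):
    """A statistical test cannot be computed (e.g. zero-variance differences)."""


class InvalidConfigError(CourtEntropyError, ValueError):
    """A generator or pipeline configuration is unusable."""
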
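"""Exception hierarchy for hopfbrain.

All errors raised intentionally by the library derive from HopfBrainError so
callers can catch the package's failures without catching programming errors.
"""


class HopfBrainError(Exception):
    """Base class for all hopfbrain errors."""


class InvalidArgumentError(HopfBrainError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateGraphError(HopfBrainError):
    """A graph operation received an empty / all-zero network it cannot handle."""


class ShortSeriesError(HopfBrainError):
    """Time series too short for the requested filter or window."""


class UndefinedPhaseError(HopfBrainError):
    """Instantaneous phase undefined (e.g. an all-zero signal row)."""


class InstabilityError(HopfBrainError):
    """Numerical integration diverged."""


class ParseError(HopfBrainError):
    """A delimited text matrix file could not be parsed."""
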
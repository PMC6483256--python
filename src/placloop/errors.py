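"""Exception types raised by placloop."""


class PlacloopError(Exception):
    """Base class for all placloop-specific errors."""


class InsufficientDataError(PlacloopError):
    """Too few observations to fit the requested model."""


class ConvergenceError(PlacloopError):
    """Model fitting failed to converge."""


class DegenerateDataError(PlacloopError):
    """Input data are degenerate for the requested operation."""


class UndefinedScoreError(PlacloopError):
    """A ratio statistic has no usable denominator."""


class InvalidRecordError(PlacloopError):
    """A record violates the output format's invariants."""
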
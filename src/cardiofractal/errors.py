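"""Exception taxonomy shared by all pipeline stages.

Every stage raises a subclass of :class:`CardioFractalError`, so batch
drivers can catch one type and record per-record failures as data rather
than crashing a whole run.
"""


class CardioFractalError(Exception):
    """Base class for all errors raised by this package."""


class ParameterError(CardioFractalError, ValueError):
    """A supplied parameter is outside its valid domain."""


class ConfigError(CardioFractalError, ValueError):
    """A configuration value is missing or inconsistent."""


class ParseError(CardioFractalError, ValueError):
    """An input file could not be parsed as numeric signal data."""


class LengthError(CardioFractalError, ValueError):
    """The signal is too short for the requested operation."""


class DegenerateSignalError(CardioFractalError, ValueError):
    """The signal carries no usable variation (constant, all-zero, ...)."""


class NoSaturationError(CardioFractalError, RuntimeError):
    """A correlation-dimension curve never saturated, so no embedding
    dimension can be chosen from it."""


class EstimationError(CardioFractalError, RuntimeError):
    """A scaling-exponent estimate failed (no valid scaling region)."""


class FitFailureError(CardioFractalError, RuntimeError):
    """The parametric f(alpha) fit did not converge or fit poorly."""


class DegenerateTrainingError(CardioFractalError, ValueError):
    """Training data does not contain enough examples of both classes."""


class InsufficientBeatsError(CardioFractalError, RuntimeError):
    """Too few heartbeats could be detected in the record."""


class UnreliableResultError(CardioFractalError, RuntimeError):
    """Too many member computations failed for the aggregate to be trusted."""


class InvalidTestError(CardioFractalError, RuntimeError):
    """A statistical test could not be completed (failed members)."""
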
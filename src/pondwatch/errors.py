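"""Exception hierarchy for pondwatch.

All package-specific failures derive from :class:`PondwatchError` so callers
can distinguish domain errors from programming errors.
"""


class PondwatchError(Exception):
    """Base class for all pondwatch errors."""


class ConfigError(PondwatchError):
    """Invalid configuration value or block."""


class OutOfRangeError(PondwatchError):
    """Input outside the supported physical range."""


class IntegrationDivergedError(PondwatchError):
    """Non-finite state encountered during ODE integration."""

    def __init__(self, step: int, time: float):
        self.step = step
        self.time = time
        super().__init__(f"integration diverged at step {step} (t={time:g} d)")


class FilterDivergedError(PondwatchError):
    """Non-finite estimate or covariance during Kalman filtering."""


class NumericalDegeneracyError(PondwatchError):
    """Singular or non-positive quantity where positivity is required."""


class TooFewPointsError(PondwatchError):
    """Not enough data points for the requested operation."""


class UnfittableError(PondwatchError):
    """Data incompatible with the requested curve family."""


class SingularDesignError(PondwatchError):
    """Degenerate design matrix (e.g. all abscissae equal)."""


class UndefinedCorrelationError(PondwatchError):
    """Correlation undefined because a variance is zero."""


class UndefinedIndexError(PondwatchError):
    """Stability index undefined (a component mean is ~0)."""


class UndefinedRatioError(PondwatchError):
    """Sensitivity ratio undefined (degenerate reference column)."""


class NonInvertibleError(PondwatchError):
    """Indirect-observation model cannot be inverted (alpha = 0)."""


class SensorCSVError(PondwatchError):
    """Malformed sensor CSV file."""
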
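"""Exception types shared across the package."""


class TacsimError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgument(TacsimError, ValueError):
    """An argument violates an operation's preconditions."""


class ConfigError(TacsimError):
    """A circuit or protocol configuration is inconsistent."""


class NumericalFailure(TacsimError):
    """The integrator produced non-finite state; the trial is aborted."""


class DataError(TacsimError):
    """Recorded data required by an analysis step is missing or malformed."""


class UndefinedStatistic(TacsimError):
    """A statistic is undefined for the given sample (e.g. zero variance)."""


class SchedulingError(TacsimError):
    """A synaptic event was scheduled in the past."""


class OutOfWindow(TacsimError, ValueError):
    """A time point falls outside the active stimulation window."""


class CalibrationFailure(TacsimError):
    """Drive calibration could not bracket or reach the target rate."""
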
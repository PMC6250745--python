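"""Exception hierarchy shared across the package."""


class CannTrackError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CannTrackError):
    """Invalid model or hardware configuration."""


class InputError(CannTrackError):
    """Malformed runtime input (shape mismatch, empty sequence, ...)."""


class LoadError(CannTrackError):
    """A sequence folder or annotation file could not be loaded."""


class ScalingError(CannTrackError):
    """Scaling chain rule violated (e.g. adding operands on different scales)."""


class CalibrationError(CannTrackError):
    """Fixed-point calibration infeasible for the requested bit widths."""


class PlanningError(CannTrackError):
    """The mapping planner cannot place the network under the core constraints."""


class RoutingError(CannTrackError):
    """A packet cannot be delivered on the simulated many-core fabric."""


class AccumulatorOverflowError(CannTrackError):
    """An integer accumulation exceeded the accumulator bit width."""
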
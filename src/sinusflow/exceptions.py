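"""Package exception hierarchy."""


class SinusflowError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(SinusflowError, ValueError):
    """A cross-section, segment or tree violates a geometric invariant."""


class ThinMaskError(SinusflowError, ValueError):
    """A lumen mask is too thin for finite differencing."""


class SolverError(SinusflowError, RuntimeError):
    """The network flow solver failed to converge."""


class CalibrationError(SinusflowError, RuntimeError):
    """Loss calibration is infeasible for the requested anchor."""


class ConfigError(SinusflowError, ValueError):
    """A run configuration is invalid; the message names the offending key."""
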
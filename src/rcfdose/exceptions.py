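"""Exception hierarchy shared by all rcfdose modules."""


class RcfDoseError(Exception):
    """Base class for every error raised by this package."""


class DomainError(RcfDoseError, ValueError):
    """An input value lies outside the physical domain of an operation."""


class CalibrationError(RcfDoseError):
    """A calibration fit failed (too few points, non-monotone fit, ...)."""


class OutOfRangeError(RcfDoseError):
    """A value to be inverted lies outside the calibrated range."""


class ConfigurationError(RcfDoseError):
    """A device/beam/phantom configuration parameter is invalid."""


class GeometryError(RcfDoseError):
    """Film, phantom and sensor geometries are inconsistent."""


class EstimationError(RcfDoseError):
    """A parameter estimation has no admissible solution."""
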
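"""Exception hierarchy used across the pipeline."""


class SmolkinError(Exception):
    """Base class for all package errors."""


class ParameterError(SmolkinError, ValueError):
    """A parameter violates its documented precondition."""


class ConfigurationError(SmolkinError, ValueError):
    """An analysis/scene configuration is inconsistent or invalid."""


class InsufficientDataError(SmolkinError):
    """Too few points/events to perform the requested fit."""


class DegenerateInputError(SmolkinError):
    """Input carries no usable signal (e.g. all-zero movie)."""


class CalibrationError(SmolkinError):
    """Intensity calibration refused (indistinguishable plateaus)."""


class FitError(SmolkinError):
    """A model fit failed or returned parameters outside their domain."""
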
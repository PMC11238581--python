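"""Exception hierarchy shared across the package."""


class VesifitError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(VesifitError, ValueError):
    """A physical precondition on an input was violated."""


class NumericalAccuracyError(VesifitError, RuntimeError):
    """A numerical routine could not reach its configured accuracy."""


class ConfigurationError(VesifitError, ValueError):
    """Inconsistent or incomplete configuration."""


class CalibrationError(VesifitError, RuntimeError):
    """A radius-to-fraction calibration could not be constructed."""
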
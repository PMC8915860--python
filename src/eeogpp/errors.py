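"""Exception types used across the package."""


class EEOError(Exception):
    """Base class for all package errors."""


class DomainError(EEOError, ValueError):
    """An input lies outside the physical domain of an operation."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class ParameterError(EEOError, ValueError):
    """A model parameter is invalid."""


class CalibrationError(EEOError, RuntimeError):
    """Site calibration or capacity coordination failed."""


class AttributionError(EEOError, ValueError):
    """Attribution inputs are insufficient (e.g. too few years)."""
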
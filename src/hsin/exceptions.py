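"""Exception hierarchy shared across the package."""


class HsinError(Exception):
    """Base class for all package-specific errors."""


class FormatError(HsinError):
    """Malformed or unsupported on-disk format (e.g. a broken ENVI header)."""


class CalibrationError(HsinError):
    """Radiometric calibration failed (e.g. white == dark at some band)."""


class InvalidParameterError(HsinError, ValueError):
    """A parameter violates an operation's precondition."""


class InvalidInputError(HsinError, ValueError):
    """Input data violates an operation's precondition."""


class DegenerateInputError(HsinError):
    """Input is degenerate for the requested operation (e.g. constant values)."""


class WavelengthLookupError(HsinError, KeyError):
    """Requested wavelength is farther from the grid than half the band spacing."""


class InsufficientCanopyError(HsinError):
    """Too few patch positions satisfy the plant-fraction criterion."""

    def __init__(self, n_valid: int, n_requested: int, message: str | None = None):
        self.n_valid = n_valid
        self.n_requested = n_requested
        super().__init__(
            message
            or f"only {n_valid} valid patch positions available, {n_requested} requested"
        )


class ShapeInferenceError(HsinError):
    """A layer's output shape could not be inferred (input too small)."""
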
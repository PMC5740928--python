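"""Exception hierarchy shared across the package."""


class FfirstError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(FfirstError, ValueError):
    """A parameter is outside its documented domain."""


class DegenerateInputError(FfirstError, ValueError):
    """Input is structurally valid but carries no usable information."""


class SegmentationFailureError(FfirstError, RuntimeError):
    """Foreground extraction produced an empty mask."""


class IncompatibilityError(FfirstError, RuntimeError):
    """Model and descriptor configurations do not match."""


class NoPredictionError(FfirstError, RuntimeError):
    """Every descriptor window was empty; no prediction can be made."""
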
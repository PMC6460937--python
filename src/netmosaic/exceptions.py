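"""Exception hierarchy shared across the pipeline stages."""


class NetmosaicError(Exception):
    """Base class for all package errors."""


class ValidationError(NetmosaicError, ValueError):
    """An input violates a documented precondition."""


class SizingError(ValidationError):
    """A grid or series is too small for the requested structure."""


class GridMismatchError(ValidationError):
    """Two volumes do not share a voxel grid / affine; resample upstream."""


class ConvergenceError(NetmosaicError, RuntimeError):
    """An iterative fit failed in a way that has no defined fallback."""
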
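"""Exception hierarchy shared across the package."""


class MamrudError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MamrudError, ValueError):
    """An input object violates a documented precondition.

    ``field`` names the offending parameter when known.
    """

    def __init__(self, message: str, field: str | None = None):
        self.field = field
        if field is not None:
            message = f"{field}: {message}"
        super().__init__(message)


class SegmentationError(MamrudError, RuntimeError):
    """A segmentation operation could not produce a valid region."""


class FitConvergenceError(MamrudError, RuntimeError):
    """Nonlinear least squares failed to converge.

    Carries the residual of the last evaluated parameter vector when
    available (``last_residual``, RMS in the units of the fitted data).
    """

    def __init__(self, message: str, last_residual: float | None = None):
        self.last_residual = last_residual
        super().__init__(message)
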
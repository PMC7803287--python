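"""Exception hierarchy shared across the package."""


class ConspicuityError(Exception):
    """Base class for all package-specific errors."""


class DimensionError(ConspicuityError):
    """Array shapes or pyramid depths are incompatible with an operation."""


class DataValidationError(ConspicuityError):
    """Input records or tables violate their contract."""


class UndefinedMetricError(ConspicuityError):
    """A similarity score is undefined for the given operands (e.g. zero maps)."""


class SingularFeatureMatrixError(ConspicuityError):
    """The feature matrix is rank deficient; least squares has no unique solution."""

    def __init__(self, message: str, collinear: tuple[str, str] | None = None):
        super().__init__(message)
        self.collinear = collinear


class PlacementError(ConspicuityError):
    """A stimulus specification cannot be packed onto the canvas."""
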
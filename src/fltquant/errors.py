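"""Exception types shared across the pipeline."""


class FltQuantError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(FltQuantError, ValueError):
    """An input violated a documented precondition or invariant."""


class SizingError(ValidationError):
    """A phantom grid is too small to hold the requested regions."""


class EmptyROIError(ValidationError):
    """A region-of-interest mask selects no voxels."""


class RangeError(ValidationError):
    """A value falls outside the supported range (e.g. outside histogram edges)."""


class ShapeMismatchError(ValidationError):
    """Volumes/masks that must be co-registered have different shapes."""


class AffineMismatchError(ValidationError):
    """Volumes/masks that must be co-registered have different affines."""


class UnitError(ValidationError):
    """Mixed or inconsistent physical units within one comparison."""


class DegenerateNormalizationError(ValidationError):
    """A normalization denominator is zero or undefined."""
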
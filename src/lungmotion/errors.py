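"""Exception types shared across the pipeline."""


class LungMotionError(Exception):
    """Base class for all package-specific errors."""


class GeometryOverflowError(LungMotionError):
    """Phantom motion or geometry pushes the lung outside the image grid."""


class FoldingFieldError(LungMotionError):
    """A deformation has a non-positive Jacobian determinant somewhere it matters."""


class LesionOverflowError(LungMotionError):
    """Requested low-attenuation burden cannot fit inside the lung volume."""


class EmptyMaskError(LungMotionError):
    """An operation that needs lung voxels received an empty mask/region."""


class DegenerateDenominatorError(LungMotionError):
    """A ratio index (e.g. EDI) has a zero denominator and is undefined."""
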
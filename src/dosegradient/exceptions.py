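"""Exception types shared across the package."""


class DoseGradientError(ValueError):
    """Base class for all package-specific errors."""


class EmptyIsodoseError(DoseGradientError):
    """Requested isodose level lies outside the dose range of the grid."""


class OpenSurfaceError(DoseGradientError):
    """Isodose surface intersects the evaluation-domain boundary.

    Surface area of a clipped level set is meaningless for the DGI, so the
    level is rejected instead of being capped.
    """


class OpenMeshError(DoseGradientError):
    """Mesh is not closed; enclosed volume is undefined."""


class NestingError(DoseGradientError):
    """Isodose nesting violated (lower-dose volume not larger)."""


class EmptyStructureError(DoseGradientError):
    """A binary structure is empty where a non-empty one is required."""


class DoseReadError(DoseGradientError):
    """A dose or mask volume could not be parsed."""
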
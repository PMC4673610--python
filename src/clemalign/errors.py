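"""Exception hierarchy shared across the package."""


class ClemAlignError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ClemAlignError):
    """Unsupported image format or bit depth."""


class DegenerateInputError(ClemAlignError):
    """Input image carries no usable signal (e.g. constant intensity)."""


class DegenerateGeometryError(ClemAlignError):
    """Point configuration admits no valid tessellation."""


class EmptyDistributionError(ClemAlignError):
    """Statistics requested on an empty table."""


class InsufficientCorrespondenceError(ClemAlignError):
    """Too few point matches to constrain a transform."""


class AlignmentFailedError(ClemAlignError):
    """No alignment with a score above the configured floor."""


class PlacementNotFoundError(ClemAlignError):
    """Template placement score fell below the configured floor."""


class CoverageError(ClemAlignError):
    """Requested foreground coverage could not be reached."""


class GeometryError(ClemAlignError):
    """Image shapes incompatible with the requested operation."""
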
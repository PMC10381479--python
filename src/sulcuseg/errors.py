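"""Typed failure modes shared across the segmentation pipeline."""


class SulcusegError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SulcusegError, ValueError):
    """Unsupported or malformed image file format."""


class SchemaError(SulcusegError, ValueError):
    """Annotation table violates the groove/vertex/x/y schema."""


class ParseError(SchemaError):
    """A table cell could not be parsed as the expected type."""


class GeometryError(SulcusegError, ValueError):
    """Degenerate ROI polygon or crop window."""


class ParameterError(SulcusegError, ValueError):
    """A method parameter is outside its valid domain."""


class ShapeError(SulcusegError, ValueError):
    """Array arguments have incompatible or empty shapes."""


class FrameError(SulcusegError, ValueError):
    """A mask is in the wrong coordinate frame for the operation."""


class BoundsError(SulcusegError, ValueError):
    """A coordinate falls outside the image after a frame transposition."""


class TopologyError(SulcusegError, ValueError):
    """Mask topology unsuitable for contour extraction (multi-component or holes)."""


class EmptySelectionError(SulcusegError, RuntimeError):
    """The structure-selection chain eliminated every candidate region.

    Signals per-groove segmentation failure: no connected component survived
    the area and centroid filters inside the clinician's ROI.
    """
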
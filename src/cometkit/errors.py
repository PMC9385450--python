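"""Exception hierarchy shared across the toolkit."""


class CometKitError(Exception):
    """Base class for all toolkit errors."""


class FormatError(CometKitError):
    """An on-disk artifact could not be read or written."""


class CapacityError(CometKitError):
    """A container cannot represent the requested number of objects."""


class DegenerateHistogramError(CometKitError):
    """A histogram has too little structure to support thresholding."""


class EmptySegmentationError(CometKitError):
    """Thresholding produced no foreground inside the ROI."""


class GeometryError(CometKitError):
    """An ROI or polygon is geometrically invalid."""


class PlacementError(CometKitError):
    """Synthetic comets could not be placed at the requested density."""


class SchemaError(CometKitError):
    """A feature table does not match the expected column schema."""


class ProjectVersionError(CometKitError):
    """A saved project declares an unsupported format version."""
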
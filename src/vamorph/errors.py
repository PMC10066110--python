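"""Exception hierarchy.

Every error raised on a contract violation derives from :class:`VamorphError`
so callers can catch the package's failures without catching programming
errors.
"""


class VamorphError(Exception):
    """Base class for all vamorph errors."""


class InvalidParameterError(VamorphError, ValueError):
    """A parameter violates its documented precondition."""


class FormatError(VamorphError, IOError):
    """Unknown file extension or malformed/mismatched file content."""


class UnsupportedGeometryError(VamorphError):
    """Volume geometry outside the supported axis-aligned convention."""


class GeometryError(VamorphError):
    """Mesh or mask geometry unusable for the requested operation."""


class DomainError(VamorphError):
    """A generated object escapes its allowed spatial domain."""


class SeedMissError(VamorphError):
    """Seed point fell on background; carries distance to nearest foreground."""

    def __init__(self, message: str, nearest_mm: float | None = None):
        super().__init__(message)
        self.nearest_mm = nearest_mm


class SegmentationFailureError(VamorphError):
    """Segmentation produced an empty result."""


class CenterlineError(VamorphError):
    """Skeleton is disconnected between the requested endpoints."""


class UndefinedDirectionError(VamorphError):
    """Measurement direction has no usable in-slice projection."""


class InvalidMeasurementError(VamorphError, ValueError):
    """A measurement value violates its precondition (e.g. negative)."""


class DegenerateDataError(VamorphError):
    """Statistical input with no usable variance."""


class InvalidLabelsError(VamorphError, ValueError):
    """Classification labels unusable (e.g. a single class)."""
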
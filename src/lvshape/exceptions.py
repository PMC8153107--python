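"""Exception hierarchy shared across the package."""


class LVShapeError(Exception):
    """Base class for all package-specific errors."""


class FormatError(LVShapeError):
    """A mesh file could not be parsed, or its format is unknown/ambiguous."""


class GeometryError(LVShapeError):
    """A mesh violates a geometric precondition (open surface, zero area, ...)."""


class DegenerateGeometryError(GeometryError):
    """A point configuration is rank-deficient (e.g. collinear) for registration."""


class ValidationError(LVShapeError, ValueError):
    """A clinical/functional input violates its physiological constraints."""
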
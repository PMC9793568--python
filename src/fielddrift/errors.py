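"""Exception hierarchy shared across the package.

All errors raised by fielddrift derive from :class:`FieldDriftError` so
callers can catch package failures with a single except clause while the
concrete subclasses keep failure modes distinguishable in tests and the CLI.
"""


class FieldDriftError(Exception):
    """Base class for all fielddrift errors."""


class SchemaError(FieldDriftError):
    """An input table violates the documented column schema."""


class OrderingError(FieldDriftError):
    """Session times are not strictly increasing within a participant."""


class InsufficientDataError(FieldDriftError):
    """Fewer observations than the operation requires."""


class GeometryError(FieldDriftError):
    """A polygon is degenerate, self-intersecting, or has zero area."""


class UndefinedStatisticError(FieldDriftError):
    """The statistic is undefined for this input (e.g. all steps zero-length)."""


class ThresholdNotFoundError(FieldDriftError):
    """The ascending charge sweep reached its ceiling without a detection."""
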
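"""Exception hierarchy used across the package.

Every error raised by sigpolytope derives from :class:`SigPolytopeError`,
so callers can catch one type at pipeline boundaries while tests can
assert on the specific failure mode.
"""


class SigPolytopeError(Exception):
    """Base class for all sigpolytope errors."""


class SchemaError(SigPolytopeError):
    """An input table is missing a mandatory column or has a bad header."""


class IntegrityError(SigPolytopeError):
    """Structural integrity violation, e.g. duplicate circuitry identifiers."""


class ParseError(SigPolytopeError):
    """A cell could not be parsed; message carries row/column coordinates."""


class EncodingError(SigPolytopeError):
    """An unknown categorical label was passed to an encoder."""


class ConsistencyError(SigPolytopeError):
    """Mutually inconsistent annotation fields (e.g. significant endpoint
    with a non-significant direction)."""


class DomainError(SigPolytopeError):
    """A numeric argument lies outside its mathematical domain."""


class ShapeError(SigPolytopeError):
    """Array dimensions do not match the expected shape."""


class DegenerateGeometryError(SigPolytopeError):
    """A point set is too degenerate (rank-deficient) for the requested
    geometric computation; carries the observed rank when known."""

    def __init__(self, message: str, rank: int | None = None):
        super().__init__(message)
        self.rank = rank


class ConfigError(SigPolytopeError):
    """Invalid pipeline or simulation configuration."""


class InsufficientDataError(SigPolytopeError):
    """Not enough rows/values for the requested statistic."""
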
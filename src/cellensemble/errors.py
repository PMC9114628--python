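"""Exception hierarchy shared across the package."""


class CellEnsembleError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(CellEnsembleError):
    """Input violates the table schema (gene axis mismatch, unknown metadata field)."""


class ColumnError(CellEnsembleError, KeyError):
    """A referenced column is neither a metadata field nor a gene on the axis."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it readable
        return Exception.__str__(self)


class FormatError(CellEnsembleError):
    """A persisted file is missing, malformed, or internally inconsistent."""


class OntologyError(CellEnsembleError):
    """Ontology structure violation: cycle, duplicate name, bad edge type."""


class NameLookupError(CellEnsembleError, KeyError):
    """A name (ontology node, organ, gene) does not exist."""

    def __str__(self) -> str:
        return Exception.__str__(self)


class ParseError(CellEnsembleError):
    """Query expression could not be parsed.

    Carries the character position at which parsing failed.
    """

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


class QueryError(CellEnsembleError):
    """Well-formed expression cannot be evaluated (e.g. ordering op on text)."""


class GroupingError(CellEnsembleError):
    """A grouping required by a statistic is empty or degenerate."""


class DimensionError(CellEnsembleError):
    """Matrix/embedding dimensions are incompatible."""
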
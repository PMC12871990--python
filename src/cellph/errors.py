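"""Exception hierarchy shared by all cellph modules."""


class CellPHError(Exception):
    """Base class for all cellph errors."""


class MalformedInputError(CellPHError):
    """Input file or table violates the expected layout."""


class ParseError(MalformedInputError):
    """A row of an input file could not be parsed as numbers."""


class UnitError(CellPHError):
    """Operation applied to data in the wrong physical unit."""


class GeometryError(CellPHError):
    """Geometric precondition violated (self-intersection, exterior centre, ...)."""


class DegeneracyError(CellPHError):
    """Input degenerate for the requested operation (collinear points, thin mask, ...)."""


class ParameterError(CellPHError):
    """Invalid parameter value."""


class ContractError(CellPHError):
    """Mismatched companion objects (e.g. function not aligned with graph)."""


class DomainError(CellPHError):
    """Quantity undefined for this input (e.g. purity of the full leaf set)."""
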
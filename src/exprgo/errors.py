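"""Exception hierarchy shared across the package.

The command-line interface maps these onto process exit codes:
validation/domain/integrity errors -> 2, parse errors -> 3,
degenerate-statistics errors -> 4.
"""


class ExprgoError(Exception):
    """Base class for all errors raised by exprgo."""


class ValidationError(ExprgoError):
    """Input data violates a documented invariant (e.g. negative RPKM)."""


class IntegrityError(ValidationError):
    """Ontology structure violates a graph invariant (cycle, missing root)."""


class DomainError(ExprgoError, ValueError):
    """An argument is outside the domain of the requested operation."""


class ParseError(ExprgoError):
    """A file could not be parsed; the message names the location."""


class OboParseError(ParseError):
    """Malformed OBO stanza or accession."""


class DegenerateDataError(ExprgoError):
    """Statistics are undefined on the data (e.g. zero variance)."""
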
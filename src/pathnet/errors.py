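"""Exception hierarchy shared across the package."""


class PathnetError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(PathnetError, ValueError):
    """An argument value violates a documented precondition."""


class ParseError(PathnetError, ValueError):
    """An input file does not conform to its declared format."""


class StructureError(PathnetError, ValueError):
    """An ontology or network violates a structural invariant (e.g. a cycle)."""


class ColumnNotFoundError(PathnetError, KeyError):
    """A mapped column name is absent from an input file."""
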
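"""Exception hierarchy shared across the package."""


class Embed2NetError(Exception):
    """Base class for all package errors."""


class DecodeError(Embed2NetError):
    """Raised when a document's raw text cannot be decoded."""


class SynonymAmbiguityError(Embed2NetError):
    """Raised when one synonym phrase maps to several preferred terms."""


class TableValidationError(Embed2NetError):
    """Raised when a synonym table row is malformed (e.g. unknown entity type)."""


class TermNotFoundError(Embed2NetError, KeyError):
    """Raised when a queried term is absent from an embedding vocabulary."""


class TrainingError(Embed2NetError):
    """Raised when embedding or classifier training cannot proceed."""


class SamplingError(Embed2NetError):
    """Raised when a requested random sample cannot be drawn."""


class FitError(Embed2NetError):
    """Raised when a curve fit fails to converge."""


class ParameterError(Embed2NetError, ValueError):
    """Raised on invalid user-supplied parameters."""


class ParseError(Embed2NetError):
    """Raised on malformed input files; carries a line number when known."""


class SearchError(Embed2NetError):
    """Raised when a threshold search cannot reach its target size."""


class AlignmentError(Embed2NetError):
    """Raised when expression features and network vertices do not overlap."""


class StructureError(Embed2NetError):
    """Raised when a graph lacks required structure (e.g. connectivity)."""


class SpecError(Embed2NetError, ValueError):
    """Raised on infeasible synthetic-data specifications."""


class ConfigError(Embed2NetError):
    """Raised on invalid pipeline configurations."""


class DependencyError(Embed2NetError):
    """Raised when a pipeline stage is missing an upstream artifact."""
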
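"""Exception hierarchy.

Every error raised on bad user input derives from :class:`MatteError`, so the
command-line layer can map any validation failure to exit code 2 while real
bugs still surface as ordinary tracebacks.
"""


class MatteError(ValueError):
    """Base class for all validation and domain errors."""


class IdentifierError(MatteError):
    """Duplicate or malformed gene/sample identifiers."""


class ParseError(MatteError):
    """Unparseable file content; message carries row/column coordinates."""


class DomainError(MatteError):
    """Value outside its mathematical domain (negative expression, log of 0)."""


class ConflictError(MatteError):
    """Contradictory inputs, e.g. one sample mapped to two phenotypes."""


class InsufficientPhenotypesError(MatteError):
    """Fewer than two distinct phenotype labels."""


class InsufficientSamplesError(MatteError):
    """A phenotype has too few samples for the requested statistic."""


class DegenerateSampleError(MatteError):
    """A sample column that cannot be normalized (e.g. sums to zero)."""


class EmptyResultError(MatteError):
    """An operation removed or filtered everything; advises a threshold change."""


class AlignmentError(MatteError):
    """Gene lists of paired matrices do not match."""


class DegenerateGraphError(MatteError):
    """Correlation graph with an isolated (zero-degree) node."""


class DimensionalityError(MatteError):
    """Embedding has too few coordinates for the requested operation."""


class IncompletenessError(MatteError):
    """A gene is missing one of its per-phenotype instances or module cells."""


class DegenerateModuleError(MatteError):
    """Module whose member expression carries no usable variance."""


class DegeneratePairError(MatteError):
    """Gene pair with zero variance in one member."""


class ConfigurationError(MatteError):
    """Inconsistent analysis configuration."""


class UndefinedMetricError(MatteError):
    """Metric undefined for the given inputs (e.g. one-class ROC)."""


class ValidationError(MatteError):
    """Generic input-shape/content validation failure."""
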
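"""Exception hierarchy.

Every error raised by the library derives from :class:`OncosiftError`, so
callers (and the CLI) can catch one type and report a single-line reason.
"""


class OncosiftError(Exception):
    """Base class for all library errors."""


class ValidationError(OncosiftError):
    """Input data violates a container invariant."""


class NormalizationError(ValidationError):
    """Expression matrix is not on the expected log2(1 + normalized count) scale."""


class LabelError(ValidationError):
    """A requested annotation column or class label is missing."""


class IndexingError(ValidationError):
    """Duplicate or inconsistent cell/gene identifiers."""


class ParseError(OncosiftError):
    """A file could not be parsed; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class CoordinateError(ParseError):
    """Genomic interval with start > end."""


class CoverageError(OncosiftError):
    """Dataset carries fewer than the required fraction of a signature's genes."""

    def __init__(self, signature_name: str, coverage: float, required: float):
        self.signature_name = signature_name
        self.coverage = coverage
        self.required = required
        super().__init__(
            f"signature {signature_name!r}: only {coverage:.1%} of genes present "
            f"in dataset, {required:.0%} required"
        )


class InsufficientCellsError(OncosiftError):
    """A class has too few cells for the requested statistic."""


class DegenerateTargetError(OncosiftError):
    """Training labels contain a single class."""


class ConfigurationError(OncosiftError):
    """Invalid parameter combination (k >= n_cells, <3 datasets, ...)."""
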
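"""Exception hierarchy shared across the pipeline stages."""


class CogloadError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CogloadError):
    """Invalid configuration value; message names the offending field."""


class DomainError(CogloadError, ValueError):
    """An input outside the mathematical domain of an operation."""


class SchemaError(CogloadError):
    """A table or history does not match the expected column/slot layout."""


class ParseError(SchemaError):
    """An unparseable cell, addressed by row and column."""


class InsufficientDataError(CogloadError):
    """Too few observations for the statistic to be defined."""


class DegenerateInputError(CogloadError):
    """Zero-variance or otherwise degenerate input (e.g. constant series)."""


class DegenerateMeasureError(DegenerateInputError):
    """A measure with zero spread; message names the measure."""


class MissingDataError(CogloadError):
    """A required measure is absent for a participant or column."""


class CollinearityError(CogloadError):
    """Perfectly collinear (aliased) model terms."""


class NoSolutionError(CogloadError):
    """A numerical solve has no solution in the admissible range."""
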
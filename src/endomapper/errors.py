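"""Exception hierarchy. Every stage fails loudly with the offending name attached."""


class EndomapperError(Exception):
    """Base class for all package errors."""


class SchemaError(EndomapperError):
    """Table and variable dictionary disagree (undeclared/missing column, bad role)."""


class ParseError(EndomapperError):
    """A cell could not be parsed as a number; message carries row and column."""


class ConfigurationError(EndomapperError):
    """Invalid or contradictory configuration (empty selection, duplicate pairs...)."""


class TransformError(EndomapperError):
    """A log transform was requested for a variable with no positive values."""


class ImputationError(EndomapperError):
    """Imputation cannot proceed (e.g. an all-missing variable)."""


class GenerationError(EndomapperError):
    """Synthetic cohort generation failed (e.g. correlation matrix not repairable)."""


class TestError(EndomapperError):
    """A statistical test was called on degenerate input (empty/constant sample)."""
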
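"""Exception hierarchy for pollentrace.

All package-specific failures derive from :class:`PollentraceError` so callers
can catch one base class at CLI boundaries.
"""


class PollentraceError(Exception):
    """Base class for all pollentrace errors."""


class SchemaError(PollentraceError):
    """A tabular input is missing required columns or has malformed values."""


class ConsistencyError(PollentraceError):
    """Manifest-level invariant violated (e.g. producer in two municipalities)."""


class FormatError(PollentraceError):
    """An image or file is not in a supported format."""


class ParameterError(PollentraceError):
    """A parameter is outside its documented range."""


class ConfigError(PollentraceError):
    """A configuration object violates its invariants."""


class DegenerateInputError(PollentraceError):
    """Input carries no usable signal (e.g. a constant image for Otsu)."""


class InsufficientDataError(PollentraceError):
    """Not enough observations to fit the requested model."""


class ContractError(PollentraceError):
    """An in-memory API contract was violated (shape/tag/label mismatch)."""


class StratificationError(PollentraceError):
    """A class is too small to stratify into the requested number of folds."""


class UndefinedCorrelationError(PollentraceError):
    """Pearson correlation is undefined because one vector is constant."""


class IncompatibilityError(PollentraceError):
    """A persisted artifact cannot be loaded (version mismatch or corruption)."""
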
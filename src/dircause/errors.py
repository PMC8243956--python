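"""Exception hierarchy shared across the package."""


class DircauseError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(DircauseError):
    """A file or table does not match the documented schema (columns, labels)."""


class ValidationError(DircauseError):
    """A value violates its contract (range, sign, duplication, emptiness)."""


class CoverageError(DircauseError):
    """A required (verb, feature) or (verb, form) cell has no observations."""


class UndefinedCorrelationError(DircauseError):
    """Pearson r is undefined (a constant vector); reported as missing, never 0."""
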
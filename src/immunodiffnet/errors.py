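"""Exception hierarchy shared across the pipeline stages."""


class ImmunoDiffNetError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ImmunoDiffNetError):
    """A file does not conform to the expected tabular dialect."""


class ParseError(FormatError):
    """A cell could not be parsed as a number; names the offending row/column."""


class ValidationError(ImmunoDiffNetError):
    """An input violates a structural invariant (duplicate ids, mismatched patients...)."""


class DomainError(ImmunoDiffNetError):
    """A value is outside the mathematical domain of a transform."""


class DegenerateMarkerError(ImmunoDiffNetError):
    """A marker row carries no usable variation (e.g. constant across patients)."""

    def __init__(self, markers, message=None):
        self.markers = list(markers)
        super().__init__(message or f"degenerate (constant) marker rows: {self.markers}")


class ConfigError(ImmunoDiffNetError):
    """A configuration object is internally inconsistent."""


class InsufficientDataError(ImmunoDiffNetError):
    """Too few complete observations to compute the requested statistic."""


class UndefinedCorrelationError(ImmunoDiffNetError):
    """Correlation undefined because one variable has zero variance."""


class SaturationError(ImmunoDiffNetError):
    """|r| = 1 makes the Fisher transform infinite; advise the shrinkage epsilon."""


class SizeError(ImmunoDiffNetError):
    """Exact enumeration refused because the table exceeds the enumeration budget."""
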
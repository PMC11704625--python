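"""Exception hierarchy shared across the package."""


class CogdiagError(Exception):
    """Base class for all package errors."""


class ConfigError(CogdiagError):
    """Invalid configuration; message names the violated invariant."""


class MissingDataError(CogdiagError):
    """An operation was applied to data flagged as missing."""


class InsufficientDataError(CogdiagError):
    """Too few observations to compute the requested statistic."""


class DegenerateBoundsError(CogdiagError):
    """A marker is constant on the reference cohort; min-max scale undefined."""


class RuleParseError(CogdiagError):
    """Rule DSL parse failure; carries line number and offending token."""

    def __init__(self, message: str, line_no: int | None = None, token: str | None = None):
        self.line_no = line_no
        self.token = token
        prefix = f"line {line_no}: " if line_no is not None else ""
        suffix = f" (offending token: {token!r})" if token else ""
        super().__init__(f"{prefix}{message}{suffix}")


class MissingMarkerError(CogdiagError):
    """A rule references a marker absent from the participant record."""


class UnparseableResponseError(CogdiagError):
    """Backend response did not contain a recognizable diagnosis line."""

    def __init__(self, raw_text: str):
        self.raw_text = raw_text
        super().__init__(f"no diagnosis found in response: {raw_text!r}")


class QueryError(CogdiagError):
    """Unknown marker, label, or statistic in a cohort query."""


class SchemaError(CogdiagError):
    """Cohort file violates the serialization schema."""


class SplitError(CogdiagError):
    """Not enough eligible participants to honor the split design."""
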
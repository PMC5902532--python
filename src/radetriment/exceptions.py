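"""Exception hierarchy.

All computational errors derive from :class:`RadetrimentError` so callers can
distinguish domain failures (bad or missing data) from programming errors.
"""


class RadetrimentError(Exception):
    """Base class for all package errors."""


class SchemaError(RadetrimentError):
    """A delimited input file violates the expected schema.

    Carries the 1-based physical line number of the offending row when known.
    """

    def __init__(self, message: str, line: int | None = None, path: str | None = None):
        self.line = line
        self.path = path
        prefix = ""
        if path is not None:
            prefix += f"{path}:"
        if line is not None:
            prefix += f"line {line}: "
        super().__init__(prefix + message)


class MissingSeriesError(RadetrimentError):
    """A (year, site, kind) series required by a computation is absent."""


class DomainError(RadetrimentError):
    """Input values outside the mathematical domain of an operation."""


class UndefinedLethalityError(RadetrimentError):
    """Weighted cumulative incidence is zero; the lethality ratio is undefined."""


class UndefinedLifeLostError(RadetrimentError):
    """Survival-weighted mortality is identically zero; mean age at death undefined."""


class ConfigError(RadetrimentError):
    """Invalid run or scenario configuration."""
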
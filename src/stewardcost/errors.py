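"""Exception hierarchy.

Every error raised by the package derives from :class:`StewardCostError` so
callers (and the CLI) can distinguish usage problems from genuine bugs.
"""


class StewardCostError(Exception):
    """Base class for all package errors."""


class ParameterDomainError(StewardCostError, ValueError):
    """A model parameter violates its domain (names the offending field)."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class ValidationError(StewardCostError, ValueError):
    """Invalid input data; carries row/field coordinates where applicable."""

    def __init__(self, message: str, row: int | None = None, field: str | None = None):
        self.row = row
        self.field = field
        prefix = ""
        if row is not None:
            prefix += f"row {row}"
        if field is not None:
            prefix += f"{', ' if prefix else ''}field '{field}'"
        super().__init__(f"{prefix}: {message}" if prefix else message)


class MatchingError(StewardCostError):
    """Frequency matching cannot be satisfied by the supplied pool."""


class InsufficientDataError(StewardCostError):
    """Too few records to compute the requested summary or comparison."""


class ConfigurationError(StewardCostError):
    """Inconsistent or unknown configuration (test names, families, axes...)."""
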
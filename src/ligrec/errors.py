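"""Exception hierarchy shared across the package."""


class LigrecError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(LigrecError):
    """A file does not conform to the expected tabular layout."""


class RowError(FormatError):
    """A single data row failed validation.

    Carries the 1-based line number of the offending row when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(LigrecError):
    """Input values violate a documented precondition or invariant."""


class ConfigurationError(LigrecError):
    """Inconsistent run configuration (labels, series, parameters)."""
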
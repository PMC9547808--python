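"""Exception hierarchy for the gppdn package."""


class GppdnError(Exception):
    """Base class for all package errors."""


class ParseError(GppdnError):
    """A malformed line in an input file; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class ConfigError(GppdnError):
    """Invalid configuration (layer declarations, jump matrix, dimensions)."""


class InputError(GppdnError):
    """Invalid user input to an operation (unknown seed, bad entity type...)."""
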
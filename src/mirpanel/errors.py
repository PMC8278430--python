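"""Exception hierarchy shared across the package."""


class MirpanelError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(MirpanelError):
    """An input table does not match the expected column schema."""


class InputError(MirpanelError):
    """An input file is unusable (empty, unreadable, malformed values)."""


class ParseError(InputError):
    """A line of a delimited file could not be parsed; carries a line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class ConfigurationError(MirpanelError):
    """A configuration value is inconsistent with the supplied data."""


class InsufficientDataError(MirpanelError):
    """Too few observations (e.g. an empty group) for the requested statistic."""
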
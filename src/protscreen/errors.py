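"""Exception hierarchy shared across the pipeline."""


class ProtscreenError(Exception):
    """Base class for all package errors."""


class ConfigError(ProtscreenError, ValueError):
    """Invalid configuration value; message names the offending field."""


class ValidationError(ProtscreenError, ValueError):
    """Input data violates a contract (shapes, groups, value domains)."""


class SchemaError(ProtscreenError, ValueError):
    """A file does not conform to its TSV schema; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line
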
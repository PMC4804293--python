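"""Exception types shared across the pipeline."""


class CnvPopGenError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(CnvPopGenError, ValueError):
    """A configuration object failed validation; the message names the field."""


class InputError(CnvPopGenError, ValueError):
    """User-supplied data violates a precondition (labels, shapes, headers)."""


class ParseError(CnvPopGenError, ValueError):
    """A text input could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line


class DegenerateDesignError(CnvPopGenError, ValueError):
    """A regression/estimation design is degenerate (e.g. constant GC track)."""
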
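"""Exception hierarchy shared across the pipeline."""


class CacsomaticError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(CacsomaticError, ValueError):
    """A caller violated an operation precondition."""


class SchemaError(CacsomaticError, ValueError):
    """An on-disk file does not match its declared schema."""


class ParseError(CacsomaticError, ValueError):
    """A row or field could not be parsed; carries a line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class UndefinedTestError(CacsomaticError, ValueError):
    """A statistical test is not defined on the given data (e.g. empty group,
    zero variance)."""
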
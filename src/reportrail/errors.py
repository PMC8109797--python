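"""Exception hierarchy for reportrail.

All errors raised by the public API derive from :class:`ReportError`, so
callers embedding report construction inside a larger tool can catch one
type. Operations validate their arguments *before* touching the report
file; a raised error therefore implies the on-disk document is unchanged.
"""


class ReportError(Exception):
    """Base class for all reportrail errors."""


class ValidationError(ReportError, ValueError):
    """An argument violates a documented precondition."""


class StateError(ReportError, RuntimeError):
    """An operation was called in the wrong document state
    (e.g. adding prose while a code chunk is open)."""


class CollisionError(ReportError, FileExistsError):
    """Target report file already exists and overwrite was not requested."""


class SerializationError(ReportError, TypeError):
    """A value cannot be rendered as code text; use a Placeholder instead."""


class ParseError(ReportError, ValueError):
    """Report source could not be parsed.

    Attributes
    ----------
    line : int or None
        1-based line number of the offending construct, when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class CompileError(ReportError, RuntimeError):
    """Compilation failed.

    Attributes
    ----------
    chunk_label : str or None
        Label of the failing code chunk, when the failure is chunk-bound.
    """

    def __init__(self, message: str, chunk_label: str | None = None):
        self.chunk_label = chunk_label
        if chunk_label is not None:
            message = f"chunk '{chunk_label}': {message}"
        super().__init__(message)
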
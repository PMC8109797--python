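"""Turn function invocations and literal values into executable code text.

Large data values never belong inside a report chunk: the emitted code
must reference them *by name* so the chunk stays re-executable in any
environment where that name is bound. :class:`Placeholder` is the
explicit marker for such by-name references; everything else is rendered
through :func:`format_literal`, which guarantees an evaluation
round-trip (evaluating the emitted text reconstructs an equal value).

:class:`Raw` wraps code text that must pass through verbatim — the
analogue of quoting raw code when the host language cannot capture an
unevaluated expression itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import PurePath
from typing import Mapping, Sequence

from .errors import SerializationError, ValidationError
from .markdown_emitter import Dialect, get_dialect

__all__ = [
    "Placeholder",
    "Raw",
    "SerializedCode",
    "format_literal",
    "serialize_call",
    "serialize_raw",
    "serialize_statements",
]


@dataclass(frozen=True)
class Placeholder:
    """Reference to a variable by name inside emitted code.

    Serializes as the bare identifier; the runtime value it stands for is
    never written into the report.
    """

    variable_name: str

    def __post_init__(self) -> None:
        if not isinstance(self.variable_name, str) or not self.variable_name:
            raise ValidationError("placeholder variable name must be non-empty")


@dataclass(frozen=True)
class Raw:
    """Code text passed through verbatim (no quoting, no validation)."""

    code: str


@dataclass(frozen=True)
class SerializedCode:
    text: str
    statement_count: int

    def __post_init__(self) -> None:
        if self.statement_count < 1:
            raise ValidationError("statement_count must be positive")


def _check_identifier(name: str, dialect: Dialect, what: str) -> None:
    if not dialect.is_identifier(name):
        raise ValidationError(f"{name!r} is not a valid {dialect.name} {what}")


def format_literal(value: object, dialect: str | Dialect = "python") -> str:
    """Render a scalar, path or flat sequence as a dialect literal.

    Supported kinds: booleans, integers, floats (repr-fidelity, so the
    shortest text that round-trips), text, :class:`~pathlib.PurePath`,
    the absent-value marker (``None``) and flat sequences of these.
    Anything else — nested sequences, mappings, arbitrary objects — raises
    :class:`SerializationError` directing the caller to a Placeholder.
    """
    d = get_dialect(dialect) if isinstance(dialect, str) else dialect
    return _format(value, d, depth=0)


def _format(value: object, d: Dialect, depth: int) -> str:
    if value is None:
        return d.none_literal
    if isinstance(value, bool):
        return d.code_true if value else d.code_false
    # numpy scalars quack like Python numbers via item()
    item = getattr(value, "item", None)
    if item is not None and not isinstance(value, (str, bytes)):
        try:
            return _format(value.item(), d, depth)  # type: ignore[union-attr]
        except (TypeError, ValueError):
            pass
    if isinstance(value, int):
        return str(value)
    if isinstance(value, float):
        if math.isnan(value) or math.isinf(value):
            raise SerializationError(f"non-finite float {value!r} has no portable literal")
        return repr(value)
    if isinstance(value, PurePath):
        return d.quote(str(value))
    if isinstance(value, str):
        return d.quote(value)
    if isinstance(value, (list, tuple)):
        if depth >= 1:
            raise SerializationError(
                "nested sequences are not serializable; bind the value to a "
                "variable and pass a Placeholder instead"
            )
        inner = ", ".join(_format(v, d, depth + 1) for v in value)
        return d.seq_open + inner + d.seq_close
    raise SerializationError(
        f"values of type {type(value).__name__!r} cannot be serialized as a "
        "code literal; bind the value to a variable and pass a Placeholder"
    )


def serialize_call(
    function_name: str,
    arguments: Mapping[str, object] | None = None,
    assign_to: str | None = None,
    dialect: str | Dialect = "python",
) -> SerializedCode:
    """Render a single keyword-style call, optionally with an assignment.

    Arguments are rendered in mapping order: Placeholders as bare names,
    :class:`Raw` verbatim, and everything else via :func:`format_literal`.
    Keyword style is used for every argument so the emitted call survives
    signature reordering.
    """
    d = get_dialect(dialect) if isinstance(dialect, str) else dialect
    _check_identifier(function_name, d, "function name")
    parts: list[str] = []
    for name, value in (arguments or {}).items():
        _check_identifier(name, d, "argument name")
        if isinstance(value, Placeholder):
            _check_identifier(value.variable_name, d, "identifier")
            rendered = value.variable_name
        elif isinstance(value, Raw):
            rendered = value.code
        else:
            try:
                rendered = _format(value, d, depth=0)
            except SerializationError as exc:
                raise SerializationError(f"argument {name!r}: {exc}") from exc
        parts.append(f"{name}={rendered}")
    call = f"{function_name}({', '.join(parts)})"
    if assign_to is not None:
        _check_identifier(assign_to, d, "identifier")
        call = d.assignment(assign_to, call)
    return SerializedCode(text=call, statement_count=1)


def serialize_raw(code: str | Raw) -> SerializedCode:
    """Wrap verbatim code text as one statement (quote-style capture)."""
    text = code.code if isinstance(code, Raw) else code
    if not isinstance(text, str) or not text.strip():
        raise ValidationError("raw code must be non-empty text")
    return SerializedCode(text=text, statement_count=1)


def serialize_statements(statements: Sequence[SerializedCode]) -> SerializedCode:
    """Join statements with single newlines, order preserved."""
    if not statements:
        raise ValidationError("statement list must be non-empty")
    text = "\n".join(s.text for s in statements)
    return SerializedCode(text=text, statement_count=sum(s.statement_count for s in statements))
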
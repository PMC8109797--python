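"""Append titles, prose and fenced code chunks to a report.

The emitter owns the *grammar* of the report body: ATX headings, verbatim
paragraphs, and fenced code chunks whose header line carries a dialect
tag, a unique label and the chunk options that differ from the document
defaults::

    ```{python chunk-1, eval=false, fig.width=5}
    counts = load_counts("counts.tsv")
    ```

Two construction styles are supported, mirroring how analysts actually
work: a step-by-step state machine (:func:`open_chunk`, :func:`add_code`,
:func:`close_chunk`) for long multi-statement chunks, and the one-shot
:func:`add_complete_chunk` for tracing a single call together with an
optional heading and natural-language comment. Both produce byte-identical
chunk text for the same inputs.

While a chunk is open it lives only in memory; it is appended to the
document (and written to disk) when the chunk is closed. This keeps the
on-disk file a faithful serialization of the document after every
completed operation and makes failed operations side-effect free.
"""

from __future__ import annotations

import keyword
import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from .errors import ParseError, StateError, ValidationError

__all__ = [
    "ChunkOptions",
    "CodeChunk",
    "Dialect",
    "Text",
    "Title",
    "add_code",
    "add_complete_chunk",
    "add_text",
    "add_title",
    "add_titled_text",
    "add_variable_assignment",
    "close_chunk",
    "get_dialect",
    "include_source_files",
    "make_options_list",
    "open_chunk",
]

FENCE = "```"

# ---------------------------------------------------------------------------
# Dialects
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Dialect:
    """Spelling rules for one target language of emitted code.

    ``header_true``/``header_false`` are used inside chunk headers,
    ``code_true``/``code_false`` inside code text (Python distinguishes
    the two spellings, R does not).
    """

    name: str
    header_true: str
    header_false: str
    code_true: str
    code_false: str
    none_literal: str
    assign_template: str        # {name}, {expr}
    loader_template: str        # {path} already quoted
    seq_open: str
    seq_close: str
    identifier_re: re.Pattern

    def quote(self, text: str) -> str:
        if self.name == "python":
            return repr(text)
        escaped = (
            text.replace("\\", "\\\\")
            .replace('"', '\\"')
            .replace("\n", "\\n")
            .replace("\t", "\\t")
        )
        return f'"{escaped}"'

    def is_identifier(self, name: str) -> bool:
        if self.name == "python":
            return name.isidentifier() and not keyword.iskeyword(name)
        return bool(self.identifier_re.match(name))

    def assignment(self, name: str, expression: str) -> str:
        return self.assign_template.format(name=name, expr=expression)

    def loader(self, path: str) -> str:
        return self.loader_template.format(path=self.quote(str(path)))

    def header_bool(self, value: bool) -> str:
        return self.header_true if value else self.header_false


DIALECTS: dict[str, Dialect] = {
    "python": Dialect(
        name="python",
        header_true="true",
        header_false="false",
        code_true="True",
        code_false="False",
        none_literal="None",
        assign_template="{name} = {expr}",
        loader_template='exec(compile(open({path}).read(), {path}, "exec"))',
        seq_open="[",
        seq_close="]",
        identifier_re=re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$"),
    ),
    "r": Dialect(
        name="r",
        header_true="TRUE",
        header_false="FALSE",
        code_true="TRUE",
        code_false="FALSE",
        none_literal="NULL",
        assign_template="{name} <- {expr}",
        loader_template="source({path})",
        seq_open="c(",
        seq_close=")",
        identifier_re=re.compile(r"^[a-zA-Z.][a-zA-Z0-9._]*$"),
    ),
}


def get_dialect(name: str) -> Dialect:
    try:
        return DIALECTS[name]
    except KeyError:
        raise ValidationError(
            f"unknown chunk dialect {name!r}; supported: {sorted(DIALECTS)}"
        ) from None


# ---------------------------------------------------------------------------
# Chunk options
# ---------------------------------------------------------------------------

# canonical field order for header emission
_OPTION_FIELDS: tuple[str, ...] = (
    "eval",
    "echo",
    "include",
    "warning",
    "message",
    "cache",
    "fig_width",
    "fig_height",
)

_HEADER_NAMES: dict[str, str] = {
    "eval": "eval",
    "echo": "echo",
    "include": "include",
    "warning": "warning",
    "message": "message",
    "cache": "cache",
    "fig_width": "fig.width",
    "fig_height": "fig.height",
}
_FIELD_BY_HEADER = {v: k for k, v in _HEADER_NAMES.items()}

#: documented defaults: every chunk runs, echoes its code and shows output
OPTION_DEFAULTS: dict[str, object] = {
    "eval": True,
    "echo": True,
    "include": True,
    "warning": True,
    "message": True,
    "cache": False,
    "fig_width": None,
    "fig_height": None,
}

_BOOL_OPTIONS = {"eval", "echo", "include", "warning", "message", "cache"}


@dataclass
class ChunkOptions:
    """Per-chunk execution/rendering flags.

    Every field is tri-state: ``None`` means *inherit* from the document's
    global options (which in turn fall back to :data:`OPTION_DEFAULTS`).
    ``label``, when given, must be unique within the document.
    """

    label: str | None = None
    eval: bool | None = None
    echo: bool | None = None
    include: bool | None = None
    warning: bool | None = None
    message: bool | None = None
    cache: bool | None = None
    fig_width: float | None = None
    fig_height: float | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in _BOOL_OPTIONS:
            value = getattr(self, name)
            if value is not None and not isinstance(value, bool):
                raise ValidationError(f"option {name!r} must be a boolean, got {value!r}")
        for name in ("fig_width", "fig_height"):
            value = getattr(self, name)
            if value is not None:
                if isinstance(value, bool) or not isinstance(value, (int, float)):
                    raise ValidationError(f"option {name!r} must be a number, got {value!r}")
                if value <= 0:
                    raise ValidationError(f"option {name!r} must be > 0, got {value!r}")
        if self.label is not None and not _LABEL_RE.match(self.label):
            raise ValidationError(
                f"invalid chunk label {self.label!r}: must match {_LABEL_RE.pattern}"
            )

    def explicit_items(self) -> list[tuple[str, object]]:
        """Fields explicitly set (non-None), in canonical order."""
        return [
            (name, getattr(self, name))
            for name in _OPTION_FIELDS
            if getattr(self, name) is not None
        ]

    def resolved(self, base: "ChunkOptions | None" = None) -> dict[str, object]:
        """Effective option values: defaults <- ``base`` <- self."""
        effective = dict(OPTION_DEFAULTS)
        for source in (base, self):
            if source is not None:
                effective.update(source.explicit_items())
        return effective

    def copy(self) -> "ChunkOptions":
        return replace(self)


def make_options_list(**kwargs: object) -> ChunkOptions:
    """Build a :class:`ChunkOptions`, rejecting unknown option names.

    Accepts the nine documented option fields (``label``, ``eval``,
    ``echo``, ``include``, ``warning``, ``message``, ``cache``,
    ``fig_width``, ``fig_height``).
    """
    supported = ("label",) + _OPTION_FIELDS
    unknown = sorted(set(kwargs) - set(supported))
    if unknown:
        raise ValidationError(
            f"unknown chunk option(s) {unknown}; supported keys: {list(supported)}"
        )
    return ChunkOptions(**kwargs)  # type: ignore[arg-type]


_LABEL_RE = re.compile(r"^[A-Za-z][A-Za-z0-9_.-]*$")


# ---------------------------------------------------------------------------
# Document elements
# ---------------------------------------------------------------------------


@dataclass
class Title:
    level: int
    text: str


@dataclass
class Text:
    text: str


@dataclass
class CodeChunk:
    """A fenced, labelled block of executable code.

    ``title``/``comment`` are construction-time conveniences: they are
    serialized as an ordinary heading/paragraph immediately before the
    fence, so a parsed document represents them as separate elements.
    """

    label: str
    options: ChunkOptions = field(default_factory=ChunkOptions)
    source_files: list[str] = field(default_factory=list)
    code_lines: list[str] = field(default_factory=list)
    title: tuple[int, str] | None = None
    comment: str | None = None


# ---------------------------------------------------------------------------
# Rendering (block = text without trailing newline; blocks are joined by
# one blank line at the document level)
# ---------------------------------------------------------------------------


def _render_header_value(value: object, dialect: Dialect) -> str:
    if isinstance(value, bool):
        return dialect.header_bool(value)
    if isinstance(value, int):
        return str(value)
    if isinstance(value, float):
        return repr(value)
    raise ValidationError(f"cannot render option value {value!r} in a chunk header")


def render_chunk_header(
    chunk: CodeChunk, dialect: Dialect, global_options: ChunkOptions | None
) -> str:
    """Header line listing only options that differ from document defaults."""
    base = (global_options or ChunkOptions()).resolved()
    parts = [f"{dialect.name} {chunk.label}"]
    for name, value in chunk.options.explicit_items():
        if value != base[name]:
            parts.append(f"{_HEADER_NAMES[name]}={_render_header_value(value, dialect)}")
    return FENCE + "{" + ", ".join(parts) + "}"


def render_chunk_blocks(
    chunk: CodeChunk, dialect: Dialect, global_options: ChunkOptions | None
) -> list[str]:
    blocks: list[str] = []
    if chunk.title is not None:
        level, text = chunk.title
        blocks.append(render_title(Title(level, text)))
    if chunk.comment is not None:
        blocks.append(chunk.comment)
    lines = [render_chunk_header(chunk, dialect, global_options)]
    lines.extend(chunk.code_lines)
    lines.append(FENCE)
    blocks.append("\n".join(lines))
    return blocks


def render_title(title: Title) -> str:
    return "#" * title.level + " " + title.text


def render_element(
    element: Title | Text | CodeChunk,
    dialect: Dialect,
    global_options: ChunkOptions | None,
) -> list[str]:
    if isinstance(element, Title):
        return [render_title(element)]
    if isinstance(element, Text):
        return [element.text]
    if isinstance(element, CodeChunk):
        return render_chunk_blocks(element, dialect, global_options)
    raise TypeError(f"unknown element type: {type(element)!r}")


# ---------------------------------------------------------------------------
# Header parsing (shared with the compiler)
# ---------------------------------------------------------------------------

_HEADER_RE = re.compile(
    r"^```\{(?P<dialect>[A-Za-z][A-Za-z0-9]*)\s+(?P<label>[A-Za-z][A-Za-z0-9_.-]*)"
    r"(?:,\s*(?P<opts>.*))?\}\s*$"
)


def parse_chunk_header(line: str, lineno: int | None = None) -> tuple[str, str, ChunkOptions]:
    """Parse a fence header line into (dialect name, label, options)."""
    match = _HEADER_RE.match(line)
    if not match:
        raise ParseError(f"malformed chunk header: {line!r}", lineno)
    dialect_name = match.group("dialect")
    if dialect_name not in DIALECTS:
        raise ParseError(f"unknown dialect {dialect_name!r} in chunk header", lineno)
    kwargs: dict[str, object] = {}
    raw_opts = match.group("opts")
    if raw_opts:
        for item in raw_opts.split(","):
            item = item.strip()
            if not item:
                continue
            if "=" not in item:
                raise ParseError(f"malformed chunk option {item!r}", lineno)
            key, _, raw = item.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in _FIELD_BY_HEADER:
                raise ParseError(f"unknown chunk option {key!r}", lineno)
            kwargs[_FIELD_BY_HEADER[key]] = _parse_header_value(raw, lineno)
    try:
        options = ChunkOptions(**kwargs)  # type: ignore[arg-type]
    except ValidationError as exc:
        raise ParseError(str(exc), lineno) from exc
    return dialect_name, match.group("label"), options


def _parse_header_value(raw: str, lineno: int | None) -> object:
    if raw in ("true", "TRUE"):
        return True
    if raw in ("false", "FALSE"):
        return False
    try:
        return int(raw)
    except ValueError:
        pass
    try:
        return float(raw)
    except ValueError:
        raise ParseError(f"cannot parse chunk option value {raw!r}", lineno) from None


# ---------------------------------------------------------------------------
# Emitter operations (delegate persistence to the document)
# ---------------------------------------------------------------------------


def _require_no_open_chunk(doc, operation: str) -> None:
    if doc.chunk_open:
        raise StateError(
            f"{operation}: a code chunk is open; close it first "
            "(use add_code to add code to the open chunk)"
        )


def _require_open_chunk(doc, operation: str) -> None:
    if not doc.chunk_open:
        raise StateError(f"{operation}: no code chunk is open; call open_chunk first")


def _validate_title(text: str, level: int) -> None:
    if not isinstance(text, str) or not text.strip():
        raise ValidationError("title text must be non-empty")
    if not isinstance(level, int) or isinstance(level, bool) or not 1 <= level <= 6:
        raise ValidationError(f"title level must be an integer in 1..6, got {level!r}")


def add_title(doc, text: str, level: int = 1):
    """Append a heading (levels 1..6, markdown ATX style)."""
    _validate_title(text, level)
    _require_no_open_chunk(doc, "add_title")
    doc._append_elements(Title(level, text))
    return doc


def add_text(doc, text: str):
    """Append a prose paragraph verbatim (no escaping or reflow)."""
    if not isinstance(text, str) or not text:
        raise ValidationError("text must be a non-empty string")
    _require_no_open_chunk(doc, "add_text")
    doc._append_elements(Text(text))
    return doc


def add_titled_text(doc, title: str, level: int, text: str):
    """Append a heading followed by a paragraph, atomically."""
    _validate_title(title, level)
    if not isinstance(text, str) or not text:
        raise ValidationError("text must be a non-empty string")
    _require_no_open_chunk(doc, "add_titled_text")
    doc._append_elements(Title(level, title), Text(text))
    return doc


def _resolve_label(doc, options: ChunkOptions, label: str | None) -> str:
    explicit = label if label is not None else options.label
    if explicit is not None:
        if not _LABEL_RE.match(explicit):
            raise ValidationError(f"invalid chunk label {explicit!r}")
        if explicit in doc.chunk_labels():
            raise ValidationError(f"duplicate chunk label {explicit!r}")
        return explicit
    return f"chunk-{doc.chunk_counter + 1}"


def open_chunk(
    doc,
    options: ChunkOptions | None = None,
    source_files: Sequence[str] | None = None,
    label: str | None = None,
):
    """Start a new code chunk (buffered until :func:`close_chunk`).

    ``source_files`` entries become loader statements — the first code
    lines of the chunk. Paths are not checked for existence here; a
    missing file surfaces as a chunk execution error at compile time.
    """
    _require_no_open_chunk(doc, "open_chunk")
    opts = options.copy() if options is not None else ChunkOptions()
    resolved = _resolve_label(doc, opts, label)
    opts.label = resolved
    chunk = CodeChunk(label=resolved, options=opts)
    if source_files:
        _add_source_files(doc, chunk, source_files)
    doc._open_chunk = chunk
    return doc


def add_code(doc, code: str):
    """Append code lines to the open chunk, order preserved."""
    _require_open_chunk(doc, "add_code")
    if not isinstance(code, str):
        raise ValidationError("code must be a string")
    doc._open_chunk.code_lines.extend(code.split("\n"))
    return doc


def add_variable_assignment(doc, name: str, expression: str, show: bool = False):
    """Emit ``name = expression`` (dialect operator) inside the open chunk.

    With ``show=True`` an additional bare-name display statement follows,
    so the compiled report prints the assigned value.
    """
    _require_open_chunk(doc, "add_variable_assignment")
    dialect = get_dialect(doc.dialect)
    if not dialect.is_identifier(name):
        raise ValidationError(f"{name!r} is not a valid {dialect.name} identifier")
    if not isinstance(expression, str) or not expression.strip():
        raise ValidationError("expression must be non-empty code text")
    doc._open_chunk.code_lines.extend(dialect.assignment(name, expression).split("\n"))
    if show:
        doc._open_chunk.code_lines.append(name)
    return doc


def include_source_files(doc, paths: Iterable[str]):
    """Emit one loader statement per path at the current chunk position."""
    _require_open_chunk(doc, "include_source_files")
    _add_source_files(doc, doc._open_chunk, paths)
    return doc


def _add_source_files(doc, chunk: CodeChunk, paths: Iterable[str]) -> None:
    dialect = get_dialect(doc.dialect)
    for path in paths:
        chunk.source_files.append(str(path))
        chunk.code_lines.append(dialect.loader(str(path)))


def close_chunk(doc):
    """Close the open chunk, appending it to the document and file."""
    _require_open_chunk(doc, "close_chunk")
    chunk = doc._open_chunk
    doc._open_chunk = None
    try:
        doc._append_elements(chunk, count_chunk=True)
    except Exception:
        doc._open_chunk = chunk
        raise
    return doc


def add_complete_chunk(
    doc,
    code: str | Sequence[str],
    options: ChunkOptions | None = None,
    source_files: Sequence[str] | None = None,
    comment: str | None = None,
    title: str | None = None,
    level: int = 2,
    label: str | None = None,
):
    """Append an optional heading, optional comment and a full chunk in one
    atomic step. A sequence of code texts is joined one statement per line.
    """
    _require_no_open_chunk(doc, "add_complete_chunk")
    if title is not None:
        _validate_title(title, level)
    if comment is not None and not isinstance(comment, str):
        raise ValidationError("comment must be a string")
    opts = options.copy() if options is not None else ChunkOptions()
    resolved = _resolve_label(doc, opts, label)
    opts.label = resolved
    chunk = CodeChunk(label=resolved, options=opts)
    if source_files:
        _add_source_files(doc, chunk, source_files)
    if isinstance(code, str):
        pieces = [code] if code else []
    else:
        pieces = [str(c) for c in code]
    for piece in pieces:
        chunk.code_lines.extend(piece.split("\n"))
    # heading and comment are stored as ordinary elements so that a parsed
    # document has the same element stream as an emitted one
    preamble: list[Title | Text] = []
    if title is not None:
        preamble.append(Title(level, title))
    if comment is not None:
        preamble.append(Text(comment))
    doc._append_elements(*preamble, chunk, count_chunk=True)
    return doc
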
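"""Report metadata and on-disk document lifecycle.

A :class:`ReportDocument` mirrors exactly one markdown file on disk:
YAML front matter (title, authors, date, registered resources), followed
by one fenced *global-options* chunk declaring the document-wide chunk
defaults, followed by the body elements. After every completed public
operation the file content equals the serialization of the in-memory
document; failed operations leave both untouched.

The report source is plain UTF-8 markdown, so it remains readable and
editable outside this package and can be committed alongside the analysis
it documents.
"""

from __future__ import annotations

import datetime as _dt
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

from . import markdown_emitter as emitter
from .errors import CollisionError, ValidationError
from .markdown_emitter import ChunkOptions, CodeChunk, Text, Title

__all__ = [
    "Author",
    "GLOBAL_OPTIONS_LABEL",
    "ReportDocument",
    "ReportMeta",
    "ReportSnapshot",
    "Resource",
    "add_resource",
    "create_report",
    "inspect_report",
    "serialize_document",
    "set_global_options",
]

GLOBAL_OPTIONS_LABEL = "global-options"

_MARKDOWN_SUFFIXES = {".md", ".markdown", ".rmd"}

_AUTHOR_FIELDS = ("name", "email", "affiliation", "affiliation_url", "orcid", "url")


@dataclass
class Author:
    """One report author, publication-style.

    Only ``name`` is mandatory; email, affiliation (with URL), ORCID and
    personal website are optional.
    """

    name: str
    email: str | None = None
    affiliation: str | None = None
    affiliation_url: str | None = None
    orcid: str | None = None
    url: str | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.name, str) or not self.name.strip():
            raise ValidationError("author name must be non-empty")

    def to_mapping(self) -> dict[str, str]:
        return {f: getattr(self, f) for f in _AUTHOR_FIELDS if getattr(self, f) is not None}


@dataclass
class Resource:
    """One row of the compiled report's "Resources Availability" table."""

    source: str
    description: str = ""
    locator: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.source, str) or not self.source.strip():
            raise ValidationError("resource source must be non-empty")


@dataclass
class ReportMeta:
    filename_path: Path
    title: str
    authors: list[Author] = field(default_factory=list)
    document_type: str = "html"
    global_options: ChunkOptions = field(default_factory=ChunkOptions)
    bibliography: str | None = None
    resources: list[Resource] = field(default_factory=list)
    date: str = field(default_factory=lambda: _dt.date.today().isoformat())


class ReportDocument:
    """Ordered report elements plus metadata and open-chunk state.

    Instances are normally obtained from :func:`create_report` or from
    the compiler's ``parse_report``; the constructor itself performs no
    file I/O.
    """

    def __init__(self, meta: ReportMeta, dialect: str = "python"):
        emitter.get_dialect(dialect)
        self.meta = meta
        self.dialect = dialect
        self.elements: list[Title | Text | CodeChunk] = []
        self.chunk_counter = 0
        self._open_chunk: CodeChunk | None = None

    # -- state ------------------------------------------------------------

    @property
    def path(self) -> Path:
        return self.meta.filename_path

    @property
    def chunk_open(self) -> bool:
        return self._open_chunk is not None

    def chunk_labels(self) -> set[str]:
        labels = {GLOBAL_OPTIONS_LABEL}
        labels.update(e.label for e in self.elements if isinstance(e, CodeChunk))
        if self._open_chunk is not None:
            labels.add(self._open_chunk.label)
        return labels

    def chunks(self) -> list[CodeChunk]:
        return [e for e in self.elements if isinstance(e, CodeChunk)]

    # -- persistence ------------------------------------------------------

    def serialize(self) -> str:
        return serialize_document(self)

    def _sync(self) -> None:
        """Atomically rewrite the report file from the in-memory document."""
        content = self.serialize().encode("utf-8")
        target = self.meta.filename_path
        tmp = target.with_name(target.name + ".tmp~")
        tmp.write_bytes(content)
        os.replace(tmp, target)

    def _append_elements(self, *new: Title | Text | CodeChunk, count_chunk: bool = False):
        n_before = len(self.elements)
        self.elements.extend(new)
        if count_chunk:
            self.chunk_counter += 1
        try:
            self._sync()
        except Exception:
            del self.elements[n_before:]
            if count_chunk:
                self.chunk_counter -= 1
            raise

    # -- convenience methods (thin wrappers over the module operations) ---

    def add_title(self, text: str, level: int = 1) -> "ReportDocument":
        return emitter.add_title(self, text, level)

    def add_text(self, text: str) -> "ReportDocument":
        return emitter.add_text(self, text)

    def add_titled_text(self, title: str, level: int, text: str) -> "ReportDocument":
        return emitter.add_titled_text(self, title, level, text)

    def open_chunk(self, options=None, source_files=None, label=None) -> "ReportDocument":
        return emitter.open_chunk(self, options, source_files, label)

    def add_code(self, code: str) -> "ReportDocument":
        return emitter.add_code(self, code)

    def add_variable_assignment(self, name, expression, show=False) -> "ReportDocument":
        return emitter.add_variable_assignment(self, name, expression, show)

    def include_source_files(self, paths) -> "ReportDocument":
        return emitter.include_source_files(self, paths)

    def close_chunk(self) -> "ReportDocument":
        return emitter.close_chunk(self)

    def add_complete_chunk(self, code, **kwargs) -> "ReportDocument":
        return emitter.add_complete_chunk(self, code, **kwargs)

    def set_global_options(self, options) -> "ReportDocument":
        return set_global_options(self, options)

    def add_resource(self, source, description="", locator="") -> "ReportDocument":
        return add_resource(self, source, description, locator)

    def inspect(self) -> "ReportSnapshot":
        return inspect_report(self)

    def compile(self, output_format: str | None = None, on_error: str = "halt") -> Path:
        from .compiler import compile_report

        return compile_report(self, output_format=output_format, on_error=on_error)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def _front_matter_mapping(doc: ReportDocument) -> dict:
    meta = doc.meta
    mapping: dict = {"title": meta.title}
    if meta.authors:
        mapping["authors"] = [a.to_mapping() for a in meta.authors]
    mapping["date"] = meta.date
    mapping["document_type"] = meta.document_type
    if meta.bibliography is not None:
        mapping["bibliography"] = meta.bibliography
    if meta.resources:
        mapping["resources"] = [
            {"source": r.source, "description": r.description, "locator": r.locator}
            for r in meta.resources
        ]
    return mapping


def serialize_document(doc: ReportDocument) -> str:
    """Canonical text form: front matter, global-options chunk, body.

    Blocks are separated by exactly one blank line and the file ends with
    a newline, so serialization is deterministic and byte-stable.
    """
    dialect = emitter.get_dialect(doc.dialect)
    front = yaml.safe_dump(
        _front_matter_mapping(doc), sort_keys=False, default_flow_style=False,
        allow_unicode=True,
    ).rstrip("\n")
    blocks: list[str] = [f"---\n{front}\n---"]
    global_chunk = CodeChunk(label=GLOBAL_OPTIONS_LABEL, options=doc.meta.global_options)
    # the global chunk advertises every explicitly-set global option, so its
    # header is rendered against the built-in defaults, not against itself
    blocks.extend(emitter.render_chunk_blocks(global_chunk, dialect, None))
    for element in doc.elements:
        blocks.extend(emitter.render_element(element, dialect, doc.meta.global_options))
    return "\n\n".join(blocks) + "\n"


# ---------------------------------------------------------------------------
# Lifecycle operations
# ---------------------------------------------------------------------------


def _normalize_path(path: str | os.PathLike) -> Path:
    p = Path(path)
    if p.suffix.lower() not in _MARKDOWN_SUFFIXES:
        p = p.with_name(p.name + ".md")
    return p


def _normalize_authors(authors: Iterable[Author | str] | None) -> list[Author]:
    result: list[Author] = []
    for a in authors or ():
        result.append(a if isinstance(a, Author) else Author(name=a))
    return result


def create_report(
    path: str | os.PathLike,
    title: str,
    authors: Sequence[Author | str] = (),
    bibliography: str | os.PathLike | None = None,
    global_options: ChunkOptions | None = None,
    overwrite: bool = False,
    document_type: str = "html",
    dialect: str = "python",
    date: str | None = None,
) -> ReportDocument:
    """Create a new report file with front matter and global options.

    ``path`` gains a ``.md`` extension when it has no markdown extension;
    parent directories are created recursively. The date is auto-filled
    with the creation date (ISO form) unless given explicitly.

    Raises
    ------
    ValidationError
        if ``path`` or ``title`` is empty (both are mandatory).
    CollisionError
        if the target file exists and ``overwrite`` is false.
    """
    if not path or not str(path).strip() or not isinstance(title, str) or not title.strip():
        raise ValidationError("filenamepath and title are mandatory parameters")
    if document_type not in ("html", "pdf"):
        raise ValidationError(f"document_type must be 'html' or 'pdf', got {document_type!r}")
    target = _normalize_path(path)
    if target.exists() and not overwrite:
        raise CollisionError(
            f"report file {target} already exists; pass overwrite=True to replace it"
        )
    meta = ReportMeta(
        filename_path=target,
        title=title,
        authors=_normalize_authors(authors),
        document_type=document_type,
        global_options=(global_options.copy() if global_options else ChunkOptions()),
        bibliography=str(bibliography) if bibliography is not None else None,
    )
    if date is not None:
        meta.date = date
    doc = ReportDocument(meta, dialect=dialect)
    target.parent.mkdir(parents=True, exist_ok=True)
    doc._sync()
    return doc


def set_global_options(doc: ReportDocument, options: ChunkOptions | dict) -> ReportDocument:
    """Replace the document-wide chunk defaults and rewrite the file.

    Subsequent chunks inherit these defaults unless locally overridden.
    A dict is accepted and validated against the supported option keys.
    """
    if isinstance(options, dict):
        options = emitter.make_options_list(**options)
    if not isinstance(options, ChunkOptions):
        raise ValidationError("options must be a ChunkOptions or a mapping of option keys")
    options.validate()
    previous = doc.meta.global_options
    doc.meta.global_options = options.copy()
    try:
        doc._sync()
    except Exception:
        doc.meta.global_options = previous
        raise
    return doc


@dataclass(frozen=True)
class ReportSnapshot:
    path: Path
    title: str
    authors: tuple[Author, ...]
    bibliography: str | None
    global_options: ChunkOptions
    resources: tuple[Resource, ...]
    document_type: str
    dialect: str


def inspect_report(doc: ReportDocument) -> ReportSnapshot:
    """Read-only snapshot of the report's identity and accumulated state."""
    meta = doc.meta
    return ReportSnapshot(
        path=meta.filename_path,
        title=meta.title,
        authors=tuple(meta.authors),
        bibliography=meta.bibliography,
        global_options=meta.global_options.copy(),
        resources=tuple(meta.resources),
        document_type=meta.document_type,
        dialect=doc.dialect,
    )


def add_resource(
    doc: ReportDocument, source: str, description: str = "", locator: str = ""
) -> ReportDocument:
    """Register an external resource; compile renders one table row per
    resource, in insertion order, under "Resources Availability"."""
    resource = Resource(source=source, description=description, locator=locator)
    doc.meta.resources.append(resource)
    try:
        doc._sync()
    except Exception:
        doc.meta.resources.pop()
        raise
    return doc
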
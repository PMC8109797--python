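"""Parse, execute and render reports.

Compilation reads a report source (or takes an in-memory document),
executes its code chunks **in document order** inside one shared
namespace — so a binding created in chunk *k* is visible in chunk *k+1*,
exactly like running the analysis top to bottom — and renders a
standalone HTML document. Captured streams, value displays and figures
are interleaved with the echoed code according to the per-chunk
``eval``/``echo``/``include`` flags.

The rendered output always ends with a session-information section
(language version, platform, package versions); a references section is
added when a bibliography was registered and at least one citation key
occurs in the prose; a "Resources Availability" table is added when
resources were registered. The report *source* is never modified by
compilation, so repeated compiles are idempotent.
"""

from __future__ import annotations

import ast
import base64
import contextlib
import datetime as _dt
import html as _html
import importlib.metadata
import io
import logging
import platform as _platform
import re
import sys
import tempfile
import warnings as _warnings
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from ._bibtex import parse_bibtex
from .errors import CompileError, ParseError, StateError, ValidationError
from .markdown_emitter import CodeChunk, Text, Title, parse_chunk_header
from .report_model import (
    GLOBAL_OPTIONS_LABEL,
    Author,
    ReportDocument,
    ReportMeta,
    Resource,
)

__all__ = [
    "CompiledReport",
    "ExecutionResult",
    "SessionInfo",
    "collect_session_info",
    "compile_report",
    "compile_with_details",
    "execute_chunk",
    "parse_report",
]

logger = logging.getLogger("reportrail")

_PACKAGE_NAME = "reportrail"


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_HEADING_RE = re.compile(r"^(#{1,6}) (.*)$")
_AUTHOR_KEYS = {"name", "email", "affiliation", "affiliation_url", "orcid", "url"}


def parse_report(path: str | Path) -> ReportDocument:
    """Parse a report source file back into a :class:`ReportDocument`.

    The parser accepts exactly the dialect the emitter produces: YAML
    front matter delimited by ``---``, a leading global-options chunk,
    then headings, paragraphs and fenced chunks separated by blank
    lines. Re-serializing the returned document reproduces the input
    bytes for emitter-produced files.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = text.split("\n")
    if not lines or lines[0].strip() != "---":
        raise ParseError("report must begin with '---' front matter", line=1)
    try:
        close = lines.index("---", 1)
    except ValueError:
        raise ParseError("unterminated front matter (no closing '---')", line=1) from None
    meta = _parse_front_matter("\n".join(lines[1:close]), path)
    doc = ReportDocument(meta)
    _parse_body(lines, close + 1, doc)
    return doc


def _parse_front_matter(source: str, path: Path) -> ReportMeta:
    try:
        data = yaml.safe_load(source)
    except yaml.YAMLError as exc:
        raise ParseError(f"malformed front matter: {exc}", line=2) from exc
    if not isinstance(data, dict):
        raise ParseError("front matter must be a YAML mapping", line=2)
    title = data.get("title")
    if not isinstance(title, str) or not title.strip():
        raise ParseError("front matter must declare a non-empty title", line=2)
    authors: list[Author] = []
    for raw in data.get("authors") or []:
        if isinstance(raw, str):
            authors.append(Author(name=raw))
        elif isinstance(raw, dict):
            unknown = set(raw) - _AUTHOR_KEYS
            if unknown:
                raise ParseError(f"unknown author field(s) {sorted(unknown)}", line=2)
            authors.append(Author(**raw))
        else:
            raise ParseError(f"malformed author entry {raw!r}", line=2)
    resources = [
        Resource(
            source=str(r.get("source", "")),
            description=str(r.get("description", "")),
            locator=str(r.get("locator", "")),
        )
        for r in data.get("resources") or []
    ]
    meta = ReportMeta(
        filename_path=path,
        title=title,
        authors=authors,
        document_type=str(data.get("document_type", "html")),
        bibliography=data.get("bibliography"),
        resources=resources,
    )
    if "date" in data:
        meta.date = str(data["date"])
    return meta


def _parse_body(lines: list[str], start: int, doc: ReportDocument) -> None:
    i = start
    n = len(lines)
    first_chunk = True
    while i < n:
        line = lines[i]
        if not line.strip():
            i += 1
            continue
        if line.startswith("```{"):
            opening = i + 1  # 1-based
            dialect_name, label, options = parse_chunk_header(line, opening)
            code: list[str] = []
            i += 1
            while i < n and lines[i] != "```":
                code.append(lines[i])
                i += 1
            if i >= n:
                raise ParseError("unclosed code chunk fence", line=opening)
            i += 1
            if first_chunk and label == GLOBAL_OPTIONS_LABEL:
                opts = options.copy()
                opts.label = None
                doc.meta.global_options = opts
                doc.dialect = dialect_name
            else:
                options.label = label
                doc.elements.append(
                    CodeChunk(label=label, options=options, code_lines=code)
                )
                doc.chunk_counter += 1
            first_chunk = False
        elif line.startswith("```"):
            raise ParseError("unexpected fence without chunk header", line=i + 1)
        else:
            heading = _HEADING_RE.match(line)
            if heading:
                doc.elements.append(Title(len(heading.group(1)), heading.group(2)))
                i += 1
            else:
                para: list[str] = []
                while i < n and lines[i].strip() and not lines[i].startswith("```{"):
                    para.append(lines[i])
                    i += 1
                doc.elements.append(Text("\n".join(para)))
            first_chunk = False


# ---------------------------------------------------------------------------
# Execution
# ---------------------------------------------------------------------------


@dataclass
class ExecutionResult:
    """Captured effects of one executed chunk."""

    chunk_label: str
    stdout_text: str = ""
    value_displays: list[str] = field(default_factory=list)
    figures: list[Path] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    messages: str = ""
    error: tuple[str, int | None] | None = None


def _ensure_agg_backend() -> object | None:
    """Switch matplotlib to the non-interactive Agg backend, if available."""
    try:
        import matplotlib
    except ImportError:  # pragma: no cover - matplotlib is a hard dependency
        return None
    matplotlib.use("Agg", force=True)
    import matplotlib.pyplot as plt

    return plt


def execute_chunk(
    chunk: CodeChunk,
    env: dict,
    effective: dict[str, object] | None = None,
    dialect: str = "python",
    figure_dir: Path | None = None,
) -> ExecutionResult:
    """Run one chunk inside the shared ``env`` and capture its effects.

    Statements execute in order; a bare expression whose value is not
    the absent-value marker is recorded as a value display (REPL
    semantics). Figures opened through matplotlib are saved under
    ``figure_dir`` and closed. With ``eval`` false nothing runs and all
    capture fields stay empty. Only the python dialect is executable;
    chunks in other dialects are rendered but never run.
    """
    effective = effective if effective is not None else chunk.options.resolved()
    result = ExecutionResult(chunk_label=chunk.label)
    if not effective.get("eval", True):
        return result
    if dialect != "python":
        logger.warning(
            "chunk %r is in dialect %r; only python chunks are executed", chunk.label, dialect
        )
        return result

    plt = _ensure_agg_backend()
    code = "\n".join(chunk.code_lines)
    filename = f"<chunk {chunk.label}>"
    stdout, stderr = io.StringIO(), io.StringIO()
    try:
        tree = ast.parse(code, filename=filename)
    except SyntaxError as exc:
        result.error = (f"SyntaxError: {exc.msg}", exc.lineno)
        return result
    with _warnings.catch_warnings(record=True) as caught:
        _warnings.simplefilter("always")
        with contextlib.redirect_stdout(stdout), contextlib.redirect_stderr(stderr):
            for node in tree.body:
                try:
                    if isinstance(node, ast.Expr):
                        value = eval(  # noqa: S307 - chunk execution is the point
                            compile(ast.Expression(node.value), filename, "eval"), env
                        )
                        if value is not None:
                            result.value_displays.append(repr(value))
                    else:
                        module = ast.Module(body=[node], type_ignores=[])
                        exec(compile(module, filename, "exec"), env)  # noqa: S102
                except Exception as exc:
                    result.error = (
                        f"{type(exc).__name__}: {exc}",
                        getattr(node, "lineno", None),
                    )
                    break
    result.stdout_text = stdout.getvalue()
    result.messages = stderr.getvalue()
    result.warnings = [str(w.message) for w in caught]
    if plt is not None and plt.get_fignums():
        fig_dir = figure_dir or Path(tempfile.mkdtemp(prefix="reportrail-figs-"))
        fig_dir.mkdir(parents=True, exist_ok=True)
        for i, num in enumerate(plt.get_fignums(), start=1):
            fig = plt.figure(num)
            width, height = effective.get("fig_width"), effective.get("fig_height")
            if width and height:
                fig.set_size_inches(float(width), float(height))
            out = fig_dir / f"{chunk.label}-{i}.png"
            fig.savefig(out, dpi=100)
            result.figures.append(out)
        plt.close("all")
    return result


# ---------------------------------------------------------------------------
# Session info
# ---------------------------------------------------------------------------


@dataclass
class SessionInfo:
    language_version: str
    platform: str
    package_versions: dict[str, str]
    timestamp: str


def collect_session_info() -> SessionInfo:
    """Snapshot of the live runtime: language version, platform, and the
    versions of every loaded third-party distribution (always including
    this package)."""
    versions: dict[str, str] = {}
    try:
        top_level = importlib.metadata.packages_distributions()
    except Exception:  # pragma: no cover - defensive
        top_level = {}
    loaded = {name.partition(".")[0] for name in sys.modules}
    for module_name in loaded:
        for dist in top_level.get(module_name, ()):
            if dist not in versions:
                try:
                    versions[dist] = importlib.metadata.version(dist)
                except importlib.metadata.PackageNotFoundError:
                    continue
    try:
        versions[_PACKAGE_NAME] = importlib.metadata.version(_PACKAGE_NAME)
    except importlib.metadata.PackageNotFoundError:
        from . import __version__

        versions[_PACKAGE_NAME] = __version__
    return SessionInfo(
        language_version=_platform.python_version(),
        platform=_platform.platform(),
        package_versions=dict(sorted(versions.items())),
        timestamp=_dt.datetime.now().isoformat(timespec="seconds"),
    )


# ---------------------------------------------------------------------------
# Rendering helpers
# ---------------------------------------------------------------------------

_CITE_RE = re.compile(r"@([A-Za-z][A-Za-z0-9_:.+-]*)")
_CODE_SPAN_RE = re.compile(r"`([^`]+)`")
_LINK_RE = re.compile(r"\[([^\]]+)\]\(([^)\s]+)\)")
_BOLD_RE = re.compile(r"\*\*(.+?)\*\*")
_EM_RE = re.compile(r"\*([^*\n]+)\*")

_CSS = """\
body { font-family: sans-serif; max-width: 52em; margin: 2em auto; padding: 0 1em;
       line-height: 1.5; color: #222; }
h1.title { margin-bottom: 0.2em; }
div.authors, div.date { color: #555; }
pre { background: #f6f6f6; padding: 0.6em; overflow-x: auto; border-radius: 4px; }
pre.output { background: #eef6ee; }
pre.error { background: #fbeaea; color: #a00; }
pre.warning { background: #fff7e0; }
img.figure { max-width: 100%; }
table { border-collapse: collapse; }
th, td { border: 1px solid #bbb; padding: 0.3em 0.7em; text-align: left; }
"""


def _render_inline(text: str) -> str:
    """Minimal inline rendering: code spans, links, bold, emphasis."""
    pieces: list[str] = []
    pos = 0
    for match in _CODE_SPAN_RE.finditer(text):
        pieces.append(_render_plain(text[pos : match.start()]))
        pieces.append(f"<code>{_html.escape(match.group(1))}</code>")
        pos = match.end()
    pieces.append(_render_plain(text[pos:]))
    return "".join(pieces)


def _render_plain(text: str) -> str:
    out = _html.escape(text, quote=False)
    out = _LINK_RE.sub(lambda m: f'<a href="{m.group(2)}">{m.group(1)}</a>', out)
    out = _BOLD_RE.sub(r"<strong>\1</strong>", out)
    out = _EM_RE.sub(r"<em>\1</em>", out)
    return out


def _resolve_citations(text: str, entries: dict | None) -> str:
    if entries is None:
        return text

    def _sub(match: re.Match) -> str:
        key = match.group(1).rstrip(".")
        trailing = match.group(1)[len(key):]
        if key in entries:
            return f"[{key}]" + trailing
        logger.warning("unresolved citation key %r rendered verbatim", key)
        return match.group(0)

    return _CITE_RE.sub(_sub, text)


def _embed_figure(path: Path) -> str:
    data = base64.b64encode(path.read_bytes()).decode("ascii")
    return f'<img class="figure" src="data:image/png;base64,{data}" alt="{path.stem}"/>'


def _render_author(author: Author) -> str:
    bits = [_html.escape(author.name)]
    if author.email:
        bits.append(f'&lt;<a href="mailto:{author.email}">{author.email}</a>&gt;')
    if author.affiliation:
        aff = _html.escape(author.affiliation)
        if author.affiliation_url:
            aff = f'<a href="{author.affiliation_url}">{aff}</a>'
        bits.append(f"— {aff}")
    if author.orcid:
        bits.append(f'ORCID: <a href="https://orcid.org/{author.orcid}">{author.orcid}</a>')
    if author.url:
        bits.append(f'<a href="{author.url}">{author.url}</a>')
    return " ".join(bits)


# ---------------------------------------------------------------------------
# Compilation
# ---------------------------------------------------------------------------


@dataclass
class CompiledReport:
    output_path: Path
    results: list[ExecutionResult]
    session_info: SessionInfo
    env: dict


def compile_report(
    doc: ReportDocument | str | Path,
    output_format: str | None = None,
    on_error: str = "halt",
    embed_figures: bool = True,
) -> Path:
    """Compile a report (document or source path) and return the output path.

    ``on_error='halt'`` aborts on the first failing chunk with a
    :class:`CompileError` naming its label; ``'continue'`` renders the
    error text in place and proceeds. With ``embed_figures`` (default)
    the HTML is standalone, figures inlined as data URIs; otherwise they
    are written beside the output.
    """
    return compile_with_details(doc, output_format, on_error, embed_figures).output_path


def compile_with_details(
    doc: ReportDocument | str | Path,
    output_format: str | None = None,
    on_error: str = "halt",
    embed_figures: bool = True,
) -> CompiledReport:
    """As :func:`compile_report`, but also return per-chunk execution
    results, the session info and the final chunk namespace."""
    if not isinstance(doc, ReportDocument):
        doc = parse_report(doc)
    if doc.chunk_open:
        raise StateError("cannot compile: a code chunk is still open")
    if on_error not in ("halt", "continue"):
        raise ValidationError("on_error must be 'halt' or 'continue'")
    fmt = output_format or doc.meta.document_type or "html"
    if fmt == "pdf":
        raise CompileError(
            "PDF output requires an external HTML-to-PDF converter; "
            "compile to HTML and convert the result"
        )
    if fmt != "html":
        raise ValidationError(f"unsupported output format {fmt!r}")

    source_path = doc.meta.filename_path
    report_dir = source_path.parent if source_path.parent != Path("") else Path(".")
    source_before = source_path.read_bytes() if source_path.exists() else None

    entries = _load_bibliography(doc, report_dir)

    output_path = source_path.with_suffix(".html")
    figure_dir = Path(tempfile.mkdtemp(prefix="reportrail-figs-")) if embed_figures else (
        report_dir / f"{source_path.stem}_files"
    )

    env: dict = {"__name__": "__report__"}
    results: list[ExecutionResult] = []
    body_parts: list[str] = []

    with contextlib.chdir(report_dir):
        for element in doc.elements:
            if isinstance(element, Title):
                body_parts.append(
                    f"<h{element.level}>{_render_inline(element.text)}</h{element.level}>"
                )
            elif isinstance(element, Text):
                text = _resolve_citations(element.text, entries)
                body_parts.append(f"<p>{_render_inline(text)}</p>")
            else:
                effective = element.options.resolved(doc.meta.global_options)
                result = execute_chunk(
                    element, env, effective, dialect=doc.dialect, figure_dir=figure_dir
                )
                results.append(result)
                if result.error is not None and on_error == "halt":
                    message, lineno = result.error
                    where = f" (line {lineno})" if lineno else ""
                    raise CompileError(f"{message}{where}", chunk_label=element.label)
                body_parts.extend(
                    _render_chunk_output(element, effective, result, embed_figures, report_dir)
                )

    session = collect_session_info()
    html = _render_page(doc, body_parts, session, entries)
    output_path.write_text(html, encoding="utf-8")

    if source_before is not None and source_path.read_bytes() != source_before:
        raise CompileError("internal error: compile modified the report source")
    return CompiledReport(
        output_path=output_path, results=results, session_info=session, env=env
    )


def _load_bibliography(doc: ReportDocument, report_dir: Path) -> dict | None:
    keys: set[str] = set()
    for element in doc.elements:
        if isinstance(element, Text):
            keys.update(m.group(1).rstrip(".") for m in _CITE_RE.finditer(element.text))
    if not keys:
        return None
    if doc.meta.bibliography is None:
        return None
    bib_path = Path(doc.meta.bibliography)
    if not bib_path.is_absolute():
        bib_path = report_dir / bib_path
    if not bib_path.exists():
        raise CompileError(
            f"citations present but bibliography file {bib_path} does not exist"
        )
    return parse_bibtex(bib_path.read_text(encoding="utf-8"))


def _render_chunk_output(
    chunk: CodeChunk,
    effective: dict[str, object],
    result: ExecutionResult,
    embed_figures: bool,
    report_dir: Path,
) -> list[str]:
    parts: list[str] = []
    include = bool(effective.get("include", True))
    if not include:
        return parts
    if effective.get("echo", True):
        code = _html.escape("\n".join(chunk.code_lines))
        parts.append(f'<pre class="code" id="chunk-{chunk.label}"><code>{code}</code></pre>')
    if effective.get("eval", True):
        if result.stdout_text:
            parts.append(f'<pre class="output">{_html.escape(result.stdout_text)}</pre>')
        for display in result.value_displays:
            parts.append(f'<pre class="output">{_html.escape(display)}</pre>')
        if effective.get("warning", True):
            for warning in result.warnings:
                parts.append(f'<pre class="warning">{_html.escape(warning)}</pre>')
        if effective.get("message", True) and result.messages:
            parts.append(f'<pre class="warning">{_html.escape(result.messages)}</pre>')
        for figure in result.figures:
            if embed_figures:
                parts.append(_embed_figure(figure))
            else:
                rel = figure.relative_to(report_dir) if figure.is_relative_to(report_dir) else figure
                parts.append(f'<img class="figure" src="{rel}" alt="{figure.stem}"/>')
        if result.error is not None:
            message, lineno = result.error
            where = f" (line {lineno})" if lineno else ""
            parts.append(f'<pre class="error">{_html.escape(message + where)}</pre>')
    return parts


def _render_page(
    doc: ReportDocument,
    body_parts: list[str],
    session: SessionInfo,
    entries: dict | None,
) -> str:
    meta = doc.meta
    head = [
        "<!DOCTYPE html>",
        '<html lang="en">',
        "<head>",
        '<meta charset="utf-8"/>',
        f"<title>{_html.escape(meta.title)}</title>",
        f"<style>{_CSS}</style>",
        "</head>",
        "<body>",
        f'<h1 class="title">{_html.escape(meta.title)}</h1>',
    ]
    if meta.authors:
        rendered = "; ".join(_render_author(a) for a in meta.authors)
        head.append(f'<div class="authors">{rendered}</div>')
    head.append(f'<div class="date">{_html.escape(meta.date)}</div>')

    tail: list[str] = ["<h2>Session Information</h2>"]
    pkg_lines = "\n".join(f"{k}=={v}" for k, v in session.package_versions.items())
    tail.append(
        '<pre class="session">'
        + _html.escape(
            f"Python {session.language_version}\n"
            f"Platform: {session.platform}\n"
            f"Compiled: {session.timestamp}\n\n{pkg_lines}"
        )
        + "</pre>"
    )
    if entries:
        tail.append("<h2>References</h2>")
        tail.append("<ul>")
        for key in sorted(entries):
            tail.append(
                f'<li id="ref-{key}">[{_html.escape(key)}] '
                f"{_html.escape(entries[key].format_plain())}</li>"
            )
        tail.append("</ul>")
    if meta.resources:
        tail.append("<h2>Resources Availability</h2>")
        tail.append("<table><tr><th>Source</th><th>Description</th><th>Locator</th></tr>")
        for r in meta.resources:
            tail.append(
                "<tr>"
                f"<td>{_html.escape(r.source)}</td>"
                f"<td>{_html.escape(r.description)}</td>"
                f"<td>{_render_plain(r.locator)}</td>"
                "</tr>"
            )
        tail.append("</table>")
    tail.extend(["</body>", "</html>"])
    return "\n".join(head + body_parts + tail) + "\n"
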
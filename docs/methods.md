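# Methods

## The document model

A report is one UTF-8 markdown file mirrored by a `ReportDocument`: YAML
front matter (title, authors with optional email/affiliation/ORCID/URL,
ISO creation date, document type, optional bibliography path, registered
resources), then one fenced *global-options* chunk that advertises the
document-wide chunk defaults, then an ordered body of headings,
paragraphs and fenced code chunks. Serialization is canonical — blocks
joined by exactly one blank line, YAML emitted deterministically — so
two documents with equal content have byte-equal files, and
`parse_report(serialize(doc))` round-trips byte-identically.

Two invariants govern every public operation:

- **File mirror.** After any successful operation the file equals the
  serialization of the in-memory document. Writes are atomic (temp file
  + rename) and validation happens before mutation, so a failed
  operation leaves both memory and disk untouched.
- **Open-chunk buffering.** At most one chunk is open at a time; while
  open it lives only in memory and reaches the file at `close_chunk`.
  This keeps fence delimiters balanced on disk at all times and makes
  step-by-step and single-call chunk construction byte-equivalent by
  construction. It also means a crash mid-chunk loses only the unclosed
  chunk, never the file's integrity.

Re-initializing over an existing report file is an error unless
`overwrite=True`: the file is an append-only audit trail, and silently
resuming or truncating it would be the one failure mode the tool exists
to prevent.

## Chunk options

Options are tri-state (`None` = inherit): effective values are built as
built-in defaults ← document globals ← chunk. Defaults are `eval`,
`echo`, `include`, `warning`, `message` true and `cache` false; figure
dimensions (inches) are unset. A chunk header lists only options whose
explicit value differs from the current document defaults, so an
all-default header is just `` ```{python chunk-1} ``. Auto labels are
`chunk-<n>` with `n` counting completed chunks; explicit labels must be
unique. `cache` is parsed and carried but is currently a no-op at
execution time (no cross-compile result cache).

Two dialects are supported for emitted code and header spelling:
`python` (booleans `true`/`false` in headers, `True`/`False` in code,
`=` assignment, `exec(compile(open(p).read(), p, "exec"))` loaders) and
an R-compatible dialect (`TRUE`/`FALSE`, `<-`, `source()` loaders), so a
report targeting either ecosystem's renderer can be emitted. Only
python-dialect chunks are *executed* by the compiler; chunks in other
dialects render with their code shown and a logged warning that they
were not run.

## Code serialization and placeholders

`format_literal` covers booleans, integers, floats (repr-fidelity: the
shortest text that round-trips), text (dialect-quoted with escaping),
paths, the absent-value marker and flat sequences of these; evaluating
the emitted text reconstructs an equal value. Anything else — nested
structures, arbitrary objects, data frames — is refused with an error
pointing at `Placeholder`, the explicit marker that serializes as a bare
variable name. This is a deliberate design choice over string-munging
conventions: a marker type cannot collide with a legitimate string
value, and the rule "data flows by name, never by value" keeps reports
small and chunks re-executable in any environment where the name is
bound. `Raw` passes verbatim code through untouched (the analogue of
quoting an unevaluated expression). Calls are always rendered
keyword-style so they survive signature reordering.

## Tracing

`make_traced` binds the target's signature, maps each bound argument to
a literal or its placeholder name, serializes the call, appends one
complete chunk (optional heading and comment included) and then invokes
the target, returning its value unmodified. The chunk is recorded
*before* execution and is kept when the target raises: a failed attempt
is part of the provenance record. Only a serialization failure aborts
before any write. Variadic `*args`/`**kwargs` targets are rejected —
their chunks could not be rendered keyword-style faithfully.

## Compilation

Chunks execute in document order in a single fresh namespace per
compile, with the working directory set to the report's directory (so
relative data paths in chunks resolve as an analyst would expect).
Statement-level execution gives REPL semantics: a bare expression whose
value is not `None` becomes a value display. stdout, stderr and warnings
are captured per chunk; matplotlib (forced to the Agg backend) figures
are collected after each chunk, sized by `fig_width`/`fig_height` when
set, and embedded as base64 data URIs by default (`embed_figures=False`
writes them beside the output instead). Visibility follows the option
matrix exactly: code appears iff `echo ∧ include`; captured output
appears iff `eval ∧ include`; `eval=false` shows code but never runs it.

The error policy is `halt` by default (a `CompileError` naming the chunk
label and line); `continue` renders the error text in place and keeps
going, which is the right mode for long exploratory reports.

Session information (Python version, platform string, versions of every
loaded third-party distribution plus this package, timestamp) is
rendered into the *output only*, never appended to the source: repeated
compiles must not grow the document, and the source's byte-stability is
checked after every compile. References appear only when a bibliography
was registered *and* at least one `@key` citation occurs in the prose;
the list is key-sorted and unstyled (no CSL support), and unresolved
keys render verbatim with a logged warning. The bibliography is read by
a small tolerant BibTeX reader (brace- and quote-delimited values,
nested braces; `@comment`/`@preamble`/`@string` ignored). Registered
resources render as a three-column table in insertion order.

PDF is accepted as a document type but compilation raises: producing
PDF requires an external HTML-to-PDF converter, and HTML is the
supported output.

The prose-to-HTML rendering is intentionally a minimal renderer for the
narrow dialect the emitter itself produces (headings, paragraphs with
code spans/links/bold/emphasis, fenced chunks): the package controls
both ends of that grammar, and prose is stored verbatim in the source,
which remains the authoritative document.

## The synthetic demo

`generate_counts` emulates a small bulk RNA-seq design: three conditions
(treatments DEC and E2, control UNTR) with two replicates each. Gene
baseline means are log2-uniform on (0, 10) — roughly 1 to 1000 expected
counts, a realistic dynamic range at this scale — and counts are
negative-binomial with variance `mu + phi*mu^2`, dispersion `phi = 0.2`,
a typical bulk value. 10% of genes are differentially expressed with
|log2FC| = 2 in both treatment groups (random direction per gene,
shared by the two treatments), and the ground-truth flags travel with
the matrix. The default 500 genes keep the demo fast; the structure, not
the scale, is what the demo exercises.

What the generator does *not* emulate — and therefore what passing
tests do not show about real data: library-size imbalance between
samples, gene length and GC composition effects, outlier dispersion,
correlated genes, batch structure. The demo's statistics are likewise
deliberately naive: total-count CPM, SVD PCA on log2(CPM+1), a
Welch-style statistic with a normal-approximation p-value (two
replicates per group make any p-value illustrative at best). Their role
is to exercise the reporting machinery end to end, not to stand in for
a count-model differential-expression method.

`run_demo_pipeline` writes the stage functions once into a
`demo_analysis.py` next to the report; the report's first chunk sources
that file and every later chunk calls its functions through serialized
calls with placeholders, while the pipeline execs the same source for
its own in-process computation (needed so the traced volcano call
receives real results). One code path, two consumers — compiled-chunk
results and in-process results cannot drift. For a fixed seed the
pipeline is fully deterministic: report source bytes are identical
across runs and the HTML differs only in the compile timestamp.

## Problem sizes

The test suite and the acceptance script use 500 genes × 6 samples for
the end-to-end demo, 100 randomized tuples for construction
equivalence, ~21 documents for round-trip checks, the full 8-combination
option matrix, and 20 traced calls; the whole acceptance run completes
in a few seconds on one CPU.

## Known limitations

- No chunk result caching, child documents, inline code spans, or
  ref.label-style chunk reuse.
- Non-python dialects are emission/parsing only.
- The markdown parser accepts the emitter's canonical dialect; heavily
  hand-edited files may parse but re-serialize to normalized (not
  byte-identical) form.
- Citation rendering is key-based; no CSL styles.
- One report per document; no merging or file locking.
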
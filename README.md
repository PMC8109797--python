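# reportrail

Literate analysis reports with an automatic provenance trail.

Irreproducibility in omics data analysis is rarely caused by the big,
well-documented modelling steps — it comes from the small ones: a filter
threshold chosen at the console, a normalisation applied "just once", a
plot produced by a button in a GUI. `reportrail` is a Python library (and
thin CLI) for building the audit trail as the analysis happens:

- **Programmatic report construction.** A report is a plain markdown file
  with YAML front matter and fenced, labelled code chunks. You append
  headings, prose and chunks from code — either step by step
  (`open_chunk` / `add_code` / `close_chunk`) or in a single call
  (`add_complete_chunk` with an optional heading and comment).
- **Automatic call tracing.** `make_traced(f, doc, ...)` wraps any
  callable so that every invocation first records itself as a
  re-executable chunk — literal arguments inlined as code literals,
  data-bearing arguments referenced by name through `Placeholder`s — and
  then runs. This is the pattern a GUI or pipeline back-end uses to gain
  a reproducibility layer with no report code at call sites.
- **Compilation.** `compile_report` parses the source, executes the
  chunks in order in one shared namespace (capturing stdout, displayed
  values and matplotlib figures), and renders standalone HTML ending
  with a session-information section, a reference list resolved against
  a BibTeX file when the prose cites keys, and a "Resources
  Availability" table of registered external resources. The source file
  is never modified by compilation.

Chunk behaviour is controlled by knitr-style options (`eval`, `echo`,
`include`, `warning`, `message`, `cache`, `fig_width`, `fig_height`)
with document-wide defaults and per-chunk overrides; only options that
differ from the document defaults appear in a chunk header.

## Worked example

```python
import reportrail as rr

doc = rr.create_report("analysis/report", title="RNA-seq Analysis Report",
                       authors=["Dario Righelli"])
doc.add_title("Loading Counts Data", 1)
doc.open_chunk(source_files=["script/import_functions.py"])
doc.add_variable_assignment("gene_counts", 'load_counts("counts.tsv")')
doc.add_code("gene_counts.head(20)")
doc.close_chunk()

def volcano(results, alpha=0.05): ...
traced = rr.make_traced(volcano, doc, title="Volcano Plot", level=2,
                        placeholder_names={"results": "deg"})
traced(my_results)          # runs volcano() AND appends one chunk
print(rr.compile_report(doc))   # -> analysis/report.html
```

The traced call appends exactly this chunk to the source —
`volcano(results=deg, alpha=0.05)` stays re-executable because the data
argument is referenced by name, never serialized:

````markdown
## Volcano Plot

```{python chunk-2}
volcano(results=deg)
```
````

The bundled demo pipeline simulates a small bulk RNA-seq study (three
conditions — two treatments DEC and E2 plus an untreated control UNTR —
with two replicates each, negative-binomial counts with 10% of genes
truly differentially expressed at |log2FC| = 2) and records every stage
as a chunk: loading, library-size diagnostics, low-count filtering, CPM
normalisation, PCA, differential expression, and traced volcano plots.

```sh
$ reportrail demo demo_out --n-genes 500 --seed 7
report:  demo_out/rnaseq_report.md
html:    demo_out/rnaseq_report.html
n_genes: 500
n_samples: 6
n_kept: 462
n_removed: 38
n_chunks: 8
n_figures: 4
mean_abs_log2fc_de: 2.252949563671936
mean_abs_log2fc_null: 0.7196972215937453
```

462 of 500 genes survive the total-count filter (threshold 10); the
truly differentially expressed genes show a mean |log2 fold change| of
≈2.25 versus ≈0.72 for the null genes, so the simulated effect is
recovered by the recorded pipeline. The HTML report contains every
chunk's code, its captured output, four embedded figures, and the
closing session-information and resources sections.

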
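"""Synthetic RNA-seq fixtures and the end-to-end demo pipeline.

The generator emulates a small two-replicate, three-condition bulk
RNA-seq design — a treatment pair (DEC, E2) against an untreated control
(UNTR) — with counts drawn from a negative-binomial model: gene-level
means are log2-uniform over ``mean_log_range`` and the variance is
``mu + dispersion * mu**2``. A ``de_fraction`` share of genes is
differentially expressed, their treatment-group means shifted by
``effect_log2fc`` (random direction per gene), and the ground-truth
flags travel with the matrix so recovery can be checked.

:func:`run_demo_pipeline` exercises every other module: it writes the
counts and a self-contained analysis script next to a fresh report,
appends one titled, commented chunk per stage (load, diagnostics,
filter, CPM, PCA, differential expression), traces the volcano plots
through :func:`~reportrail.tracer.make_traced`, and compiles to HTML.
The stage code lives once, in the generated ``demo_analysis.py``; the
pipeline execs the same file it tells the report chunks to source, so
in-process results and compiled-chunk results cannot diverge. The demo
stages use deliberately simple math (total-count CPM, SVD-based PCA, a
Welch-style statistic with a normal-approximation p-value): their job is
to exercise the reporting machinery, not to reproduce a production
differential-expression method.
"""

from __future__ import annotations

import contextlib
import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .code_serializer import Placeholder, serialize_call, serialize_statements
from .errors import ValidationError
from .report_model import Author, ReportDocument, add_resource, create_report
from .tracer import make_traced

__all__ = [
    "CountMatrix",
    "DEFAULT_REPLICATES",
    "DemoResult",
    "generate_counts",
    "run_demo_pipeline",
]

#: two replicates for each of the three conditions of the emulated design
DEFAULT_REPLICATES: dict[str, int] = {"DEC": 2, "E2": 2, "UNTR": 2}

CONTROL_GROUP = "UNTR"


@dataclass
class CountMatrix:
    """Genes × samples integer count matrix with ground-truth DE flags."""

    genes: list[str]
    samples: list[str]
    sample_groups: list[str]
    counts: np.ndarray
    de_flags: np.ndarray
    true_log2fc: np.ndarray

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.genes), len(self.samples)):
            raise ValidationError("counts shape must be (n_genes, n_samples)")
        if (self.counts < 0).any():
            raise ValidationError("counts must be non-negative")
        if len(self.de_flags) != len(self.genes):
            raise ValidationError("de_flags length must equal gene count")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.genes, columns=self.samples)

    def write_tsv(self, path: str | Path) -> Path:
        """Write the matrix as TSV: gene_id column, one column per sample."""
        path = Path(path)
        self.to_dataframe().to_csv(path, sep="\t", index_label="gene_id")
        return path


def generate_counts(
    n_genes: int = 500,
    replicates_per_group: dict[str, int] | None = None,
    de_fraction: float = 0.1,
    effect_log2fc: float = 2.0,
    dispersion: float = 0.2,
    mean_log_range: tuple[float, float] = (0.0, 10.0),
    seed: int = 7,
) -> CountMatrix:
    """Simulate a negative-binomial count matrix with known DE genes.

    Parameters
    ----------
    n_genes:
        Number of genes (rows).
    replicates_per_group:
        Ordered mapping of condition label to replicate count; defaults
        to two replicates each of DEC, E2 and UNTR.
    de_fraction:
        Share of genes flagged differentially expressed (0..1).
    effect_log2fc:
        Absolute log2 fold change applied to flagged genes in every
        non-control group; direction is random per gene.
    dispersion:
        Negative-binomial dispersion phi, variance ``mu + phi*mu**2``.
    mean_log_range:
        Range of log2 gene-level baseline means (log2-uniform).
    seed:
        Seed for the generator; identical seeds give identical matrices.
    """
    if not isinstance(n_genes, int) or n_genes < 1:
        raise ValidationError(f"n_genes must be a positive integer, got {n_genes!r}")
    if not 0.0 <= de_fraction <= 1.0:
        raise ValidationError(f"de_fraction must lie in [0, 1], got {de_fraction!r}")
    if effect_log2fc <= 0:
        raise ValidationError("effect_log2fc must be positive")
    if dispersion <= 0:
        raise ValidationError("dispersion must be positive")
    groups = dict(replicates_per_group) if replicates_per_group else dict(DEFAULT_REPLICATES)
    for group, reps in groups.items():
        if not isinstance(reps, int) or reps < 1:
            raise ValidationError(f"replicate count for group {group!r} must be >= 1")
    lo, hi = mean_log_range
    if hi <= lo:
        raise ValidationError("mean_log_range must be an increasing pair")

    control = CONTROL_GROUP if CONTROL_GROUP in groups else list(groups)[-1]
    rng = np.random.default_rng(seed)
    base_mean = np.exp2(rng.uniform(lo, hi, size=n_genes))
    n_de = int(round(de_fraction * n_genes))
    de_index = rng.choice(n_genes, size=n_de, replace=False)
    de_flags = np.zeros(n_genes, dtype=bool)
    de_flags[de_index] = True
    signs = rng.choice([-1.0, 1.0], size=n_de)
    true_log2fc = np.zeros(n_genes)
    true_log2fc[de_index] = signs * effect_log2fc

    size = 1.0 / dispersion  # NB "number of successes" parameter
    columns: list[np.ndarray] = []
    samples: list[str] = []
    sample_groups: list[str] = []
    for group, reps in groups.items():
        mean_g = base_mean * (np.exp2(true_log2fc) if group != control else 1.0)
        for rep in range(1, reps + 1):
            p = size / (size + mean_g)
            columns.append(rng.negative_binomial(size, p))
            samples.append(f"{group}_rep{rep}")
            sample_groups.append(group)

    counts = np.column_stack(columns).astype(np.int64)
    genes = [f"gene_{i + 1:05d}" for i in range(n_genes)]
    return CountMatrix(
        genes=genes,
        samples=samples,
        sample_groups=sample_groups,
        counts=counts,
        de_flags=de_flags,
        true_log2fc=true_log2fc,
    )


# ---------------------------------------------------------------------------
# Self-contained demo analysis stages, written beside the report and
# sourced by its first chunk. Keep this file dependency-light: numpy,
# pandas and matplotlib only.
# ---------------------------------------------------------------------------

DEMO_ANALYSIS_SOURCE = '''\
"""Demo RNA-seq analysis stages (self-contained; sourced by the report)."""
import math

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def load_counts(path):
    """Read a genes x samples TSV count matrix (gene_id index column)."""
    return pd.read_csv(path, sep="\\t", index_col=0)


def sample_groups(counts):
    return [c.rsplit("_", 1)[0] for c in counts.columns]


def library_size_plot(counts):
    """Bar plot of per-sample totals; prints the library sizes."""
    sizes = counts.sum(axis=0)
    fig, ax = plt.subplots(figsize=(6.0, 3.5))
    ax.bar(range(len(sizes)), sizes.to_numpy(), color="steelblue")
    ax.set_xticks(range(len(sizes)))
    ax.set_xticklabels(sizes.index, rotation=45, ha="right")
    ax.set_ylabel("library size (total counts)")
    fig.tight_layout()
    print("library sizes:")
    print(sizes.to_string())


def filter_low_counts(counts, threshold):
    """Keep genes whose total count across samples reaches the threshold."""
    kept = counts[counts.sum(axis=1) >= threshold]
    print(f"kept {kept.shape[0]} of {counts.shape[0]} genes"
          f" (total count >= {threshold})")
    return kept


def cpm_normalise(counts):
    """Total-count scaling to counts per million (each column sums to 1e6)."""
    cpm = counts / counts.sum(axis=0) * 1_000_000.0
    print("column sums after CPM scaling:")
    print(cpm.sum(axis=0).round(3).to_string())
    return cpm


def pca_plot(cpm):
    """Scatter of the first two principal components of log2(CPM + 1)."""
    log_expr = np.log2(cpm.to_numpy(dtype=float).T + 1.0)
    centred = log_expr - log_expr.mean(axis=0)
    u, s, _ = np.linalg.svd(centred, full_matrices=False)
    coords = u[:, :2] * s[:2]
    groups = sample_groups(cpm)
    fig, ax = plt.subplots(figsize=(5.0, 4.0))
    for group in sorted(set(groups)):
        idx = [i for i, g in enumerate(groups) if g == group]
        ax.scatter(coords[idx, 0], coords[idx, 1], label=group)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.legend(title="condition")
    fig.tight_layout()
    total_var = (s ** 2).sum()
    explained = (s[:2] ** 2) / total_var * 100.0
    print(f"variance explained: PC1 {explained[0]:.1f}%, PC2 {explained[1]:.1f}%")
    return coords


def differential_expression(cpm, treatment, control):
    """Per-gene mean log2 fold change and a Welch-style two-sample statistic.

    The p-value uses a normal approximation of the statistic (erfc),
    adequate for a demonstration but not a substitute for a moderated
    count-model test.
    """
    logs = np.log2(cpm + 1.0)
    groups = np.array(sample_groups(cpm))
    treat = logs.loc[:, groups == treatment].to_numpy()
    ctrl = logs.loc[:, groups == control].to_numpy()
    lfc = treat.mean(axis=1) - ctrl.mean(axis=1)
    se = np.sqrt(
        treat.var(axis=1, ddof=1) / treat.shape[1]
        + ctrl.var(axis=1, ddof=1) / ctrl.shape[1]
    )
    stat = lfc / np.where(se > 0, se, np.nan)
    pvalue = np.array(
        [math.erfc(abs(t) / math.sqrt(2.0)) if np.isfinite(t) else 1.0 for t in stat]
    )
    result = pd.DataFrame(
        {"log2FC": lfc, "stat": stat, "pvalue": pvalue}, index=cpm.index
    )
    n_hits = int((result["pvalue"] < 0.05).sum())
    print(f"{treatment} vs {control}: {n_hits} genes with p < 0.05"
          f" of {result.shape[0]} tested")
    return result


def volcano_plot(results, label="", alpha=0.05):
    """Volcano plot: log2 fold change versus -log10 p-value."""
    x = results["log2FC"].to_numpy()
    y = -np.log10(np.maximum(results["pvalue"].to_numpy(), 1e-300))
    significant = results["pvalue"].to_numpy() < alpha
    fig, ax = plt.subplots(figsize=(5.0, 4.0))
    ax.scatter(x[~significant], y[~significant], s=6, color="grey", alpha=0.6)
    ax.scatter(x[significant], y[significant], s=6, color="crimson")
    ax.axhline(-math.log10(alpha), color="black", lw=0.5, ls="--")
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 p-value")
    if label:
        ax.set_title(label)
    fig.tight_layout()
    print(f"volcano {label}: {int(significant.sum())} genes below alpha={alpha}")
'''


@dataclass
class DemoResult:
    report_path: Path
    html_path: Path
    doc: ReportDocument
    count_matrix: CountMatrix
    summary: dict = field(default_factory=dict)


def run_demo_pipeline(
    output_dir: str | Path,
    n_genes: int = 500,
    seed: int = 7,
    filter_threshold: int = 10,
    replicates_per_group: dict[str, int] | None = None,
    de_fraction: float = 0.1,
    effect_log2fc: float = 2.0,
    dispersion: float = 0.2,
) -> DemoResult:
    """Simulate counts, build a stage-per-chunk analysis report, compile it.

    Deterministic for a fixed seed: the report source bytes are identical
    across runs and the HTML differs only in timestamps.
    """
    from .compiler import compile_with_details  # local import: avoid cycle

    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)

    matrix = generate_counts(
        n_genes=n_genes,
        replicates_per_group=replicates_per_group,
        de_fraction=de_fraction,
        effect_log2fc=effect_log2fc,
        dispersion=dispersion,
        seed=seed,
    )
    counts_path = matrix.write_tsv(out / "counts.tsv")
    analysis_path = out / "demo_analysis.py"
    analysis_path.write_text(DEMO_ANALYSIS_SOURCE, encoding="utf-8")

    groups = list(dict.fromkeys(matrix.sample_groups))
    control = CONTROL_GROUP if CONTROL_GROUP in groups else groups[-1]
    treatments = [g for g in groups if g != control]

    doc = create_report(
        out / "rnaseq_report",
        title="RNA-seq Analysis Report",
        authors=[Author(name="Demo Analyst")],
        overwrite=True,
    )
    add_resource(
        doc,
        "Synthetic counts",
        "negative-binomial simulated count matrix (genes x samples)",
        counts_path.name,
    )
    doc.add_text(
        "This report analyses a simulated bulk RNA-seq experiment with "
        f"{len(treatments) + 1} conditions ({', '.join(groups)}) and "
        f"{len(matrix.samples)} samples. Each analysis phase is recorded "
        "as its own code chunk, so the compiled document is a complete, "
        "re-executable account of the analysis."
    )

    ph = Placeholder
    doc.add_complete_chunk(
        serialize_call("load_counts", {"path": counts_path.name}, assign_to="counts").text,
        source_files=[analysis_path.name],
        title="Loading Counts Data",
        level=1,
        comment="Load the simulated raw count matrix released beside this report.",
    )
    doc.add_complete_chunk(
        serialize_call("library_size_plot", {"counts": ph("counts")}).text,
        title="Per-sample Diagnostics",
        level=1,
        comment="Library sizes per sample; gross outliers would show up here.",
    )
    doc.add_complete_chunk(
        serialize_call(
            "filter_low_counts",
            {"counts": ph("counts"), "threshold": filter_threshold},
            assign_to="filtered",
        ).text,
        title="Filtering Low-count Genes",
        level=1,
        comment="Genes with too few reads overall carry little information "
        "and are removed before normalisation.",
    )
    doc.add_complete_chunk(
        serialize_call("cpm_normalise", {"counts": ph("filtered")}, assign_to="cpm").text,
        title="CPM Normalisation",
        level=1,
        comment="Total-count scaling to counts per million makes samples "
        "with different sequencing depths comparable.",
    )
    doc.add_complete_chunk(
        serialize_call("pca_plot", {"cpm": ph("cpm")}).text,
        title="Principal Component Projection",
        level=1,
        comment="Samples projected on the first two principal components "
        "of log2(CPM + 1); replicates should cluster by condition.",
    )
    de_statements = [
        serialize_call(
            "differential_expression",
            {"cpm": ph("cpm"), "treatment": t, "control": control},
            assign_to=f"deg_{t}",
        )
        for t in treatments
    ]
    doc.add_complete_chunk(
        serialize_statements(de_statements).text,
        title="Differential Expression",
        level=1,
        comment="Per-gene mean log2 fold change and a Welch-style statistic "
        "for each treatment against the control.",
    )

    # run the same stages in-process so the traced volcano call receives
    # real results; stage prints are silenced locally (the compiled report
    # captures them from the chunks instead)
    ns: dict = {"__name__": "demo_analysis"}
    exec(compile(DEMO_ANALYSIS_SOURCE, str(analysis_path), "exec"), ns)
    with contextlib.redirect_stdout(io.StringIO()):
        counts = ns["load_counts"](str(counts_path))
        filtered = ns["filter_low_counts"](counts, filter_threshold)
        cpm = ns["cpm_normalise"](filtered)
        degs = {
            t: ns["differential_expression"](cpm, t, control) for t in treatments
        }

    doc.add_title("Volcano Plots", level=1)
    for t in treatments:
        traced_volcano = make_traced(
            ns["volcano_plot"],
            doc,
            title=f"Volcano: {t} vs {control}",
            level=2,
            comment="Rendered through a self-tracing wrapper: the call below "
            "was recorded automatically when the plot was produced.",
            placeholder_names={"results": f"deg_{t}"},
        )
        with contextlib.redirect_stdout(io.StringIO()):
            traced_volcano(degs[t], label=f"{t} vs {control}")
        ns["plt"].close("all")

    compiled = compile_with_details(doc)

    summary = _summarise(matrix, filtered, degs, compiled)
    return DemoResult(
        report_path=doc.path,
        html_path=compiled.output_path,
        doc=doc,
        count_matrix=matrix,
        summary=summary,
    )


def _summarise(matrix: CountMatrix, filtered, degs: dict, compiled) -> dict:
    flags = pd.Series(matrix.de_flags, index=matrix.genes)
    abs_lfc = None
    for deg in degs.values():
        part = deg["log2FC"].abs()
        abs_lfc = part if abs_lfc is None else abs_lfc + part
    abs_lfc = abs_lfc / len(degs)
    tested_flags = flags.reindex(abs_lfc.index).fillna(False).astype(bool)
    return {
        "n_genes": len(matrix.genes),
        "n_samples": len(matrix.samples),
        "n_kept": int(filtered.shape[0]),
        "n_removed": len(matrix.genes) - int(filtered.shape[0]),
        "n_chunks": len(compiled.results),
        "n_figures": int(sum(len(r.figures) for r in compiled.results)),
        "mean_abs_log2fc_de": float(abs_lfc[tested_flags].mean()),
        "mean_abs_log2fc_null": float(abs_lfc[~tested_flags].mean()),
    }
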
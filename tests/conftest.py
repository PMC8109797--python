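import random

import pytest
from hypothesis import HealthCheck, settings

import reportrail as rr

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture
def report(tmp_path):
    """A freshly created report document in a temporary directory."""
    return rr.create_report(
        tmp_path / "report", title="Test Report", authors=["Test Author"]
    )


@pytest.fixture(scope="session")
def demo_result(tmp_path_factory):
    """One shared run of the full synthetic RNA-seq demo pipeline."""
    out = tmp_path_factory.mktemp("demo")
    return rr.run_demo_pipeline(out, n_genes=500, seed=7, filter_threshold=10)


def random_chunk_tuple(rng: random.Random):
    """Randomized (code, options, comment, title) construction input."""
    code = "\n".join(
        f"v{i} = {rng.randint(0, 999)} + {rng.randint(0, 9)}"
        for i in range(rng.randint(1, 4))
    )
    kwargs = {}
    for flag in ("eval", "echo", "include", "warning", "message", "cache"):
        if rng.random() < 0.5:
            kwargs[flag] = rng.random() < 0.5
    if rng.random() < 0.3:
        kwargs["fig_width"] = round(rng.uniform(1, 10), 2)
        kwargs["fig_height"] = round(rng.uniform(1, 10), 2)
    options = rr.make_options_list(**kwargs)
    title = f"Stage {rng.randint(1, 99)}" if rng.random() < 0.5 else None
    level = rng.randint(1, 6)
    comment = f"comment {rng.randint(1, 99)}" if rng.random() < 0.5 else None
    return code, options, comment, title, level


def build_step_by_step(doc, code, options, comment, title, level):
    if title is not None:
        doc.add_title(title, level)
    if comment is not None:
        doc.add_text(comment)
    doc.open_chunk(options=options.copy())
    doc.add_code(code)
    doc.close_chunk()


def build_single_call(doc, code, options, comment, title, level):
    doc.add_complete_chunk(
        code, options=options.copy(), comment=comment, title=title, level=level
    )
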
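"""Emitter grammar: headings, prose, chunk construction, state machine."""

import random

import pytest

import reportrail as rr
from tests.conftest import build_single_call, build_step_by_step, random_chunk_tuple


def _fence_lines(doc):
    return [l for l in doc.path.read_text().split("\n") if l.startswith("```")]


class TestTitles:
    @pytest.mark.parametrize("level", range(1, 7))
    def test_accepts_levels_one_through_six(self, report, level):
        report.add_title("Loading Counts Data", level)
        assert f"\n{'#' * level} Loading Counts Data\n" in report.path.read_text()

    @pytest.mark.parametrize("level", [0, 7, -1, 100])
    def test_rejects_levels_outside_one_to_six(self, report, level):
        with pytest.raises(rr.ValidationError):
            report.add_title("x", level)

    def test_titled_text_equals_title_then_text(self, tmp_path):
        a = rr.create_report(tmp_path / "a", title="T")
        b = rr.create_report(tmp_path / "b", title="T")
        a.add_titled_text("Notes", 3, "comment")
        b.add_title("Notes", 3)
        b.add_text("comment")
        assert a.path.read_text() == b.path.read_text()
        assert "### Notes" in a.path.read_text()


class TestProse:
    def test_text_is_preserved_verbatim_including_markup(self, report):
        text = "We now *filter* low counts with **edge cases** and `code`."
        report.add_text(text)
        assert text in report.path.read_text()


class TestStateMachine:
    def test_prose_and_titles_rejected_while_chunk_open(self, report):
        report.open_chunk()
        with pytest.raises(rr.StateError, match="add_code"):
            report.add_text("prose")
        with pytest.raises(rr.StateError):
            report.add_title("t", 1)
        with pytest.raises(rr.StateError):
            report.open_chunk()
        with pytest.raises(rr.StateError):
            report.add_complete_chunk("x = 1")

    def test_code_operations_require_open_chunk(self, report):
        with pytest.raises(rr.StateError):
            report.add_code("x = 1")
        with pytest.raises(rr.StateError):
            report.close_chunk()
        with pytest.raises(rr.StateError):
            report.add_variable_assignment("x", "1")
        with pytest.raises(rr.StateError):
            report.include_source_files(["f.py"])


class TestChunkEmission:
    def test_golden_chunk_block(self, report):
        report.open_chunk(
            options=rr.make_options_list(eval=False),
            source_files=["script/import_functions.py"],
        )
        report.add_variable_assignment(
            "gene_counts", 'load_counts("counts.tsv")', show=False
        )
        report.add_code("gene_counts.head(20)")
        report.close_chunk()
        expected = (
            "```{python chunk-1, eval=false}\n"
            "exec(compile(open('script/import_functions.py').read(),"
            " 'script/import_functions.py', \"exec\"))\n"
            'gene_counts = load_counts("counts.tsv")\n'
            "gene_counts.head(20)\n"
            "```"
        )
        assert expected in report.path.read_text()

    def test_show_flag_adds_display_line(self, report):
        report.open_chunk()
        report.add_variable_assignment("x", "41 + 1", show=True)
        report.close_chunk()
        chunk = report.chunks()[0]
        assert chunk.code_lines == ["x = 41 + 1", "x"]

    def test_invalid_assignment_identifier_rejected(self, report):
        report.open_chunk()
        with pytest.raises(rr.ValidationError):
            report.add_variable_assignment("2x", "1")

    def test_multiline_code_preserves_line_count_and_order(self, report):
        report.open_chunk()
        report.add_code("a = 1\nb = 2\nc = a + b")
        report.close_chunk()
        assert report.chunks()[0].code_lines == ["a = 1", "b = 2", "c = a + b"]

    def test_code_list_joined_one_statement_per_line(self, report):
        report.add_complete_chunk(["a = 1", "b = a + 1"])
        assert report.chunks()[0].code_lines == ["a = 1", "b = a + 1"]

    def test_empty_source_file_list_emits_nothing(self, report):
        report.open_chunk()
        report.include_source_files([])
        report.close_chunk()
        assert report.chunks()[0].code_lines == []

    def test_complete_chunk_orders_heading_comment_fence(self, report):
        report.add_complete_chunk(
            "plot_ma(deg_list=deg_list)",
            title="Recursive Tracing Function",
            level=2,
            comment="Automatically recorded call.",
        )
        text = report.path.read_text()
        heading = text.index("## Recursive Tracing Function")
        comment = text.index("Automatically recorded call.")
        fence = text.index("```{python chunk-1}")
        assert heading < comment < fence


class TestHeadersAndLabels:
    def test_all_default_header_carries_only_dialect_and_label(self, report):
        report.add_complete_chunk("x = 1")
        assert "```{python chunk-1}\n" in report.path.read_text()

    def test_non_default_options_spelled_in_header(self, report):
        report.add_complete_chunk(
            "x = 1",
            options=rr.make_options_list(eval=False, cache=True, fig_width=5.0),
        )
        assert "```{python chunk-1, eval=false, cache=true, fig.width=5.0}" in (
            report.path.read_text()
        )

    def test_auto_labels_increment_and_duplicates_rejected(self, report):
        report.add_complete_chunk("a = 1")
        report.add_complete_chunk("b = 2", label="named")
        report.add_complete_chunk("c = 3")
        assert [c.label for c in report.chunks()] == ["chunk-1", "named", "chunk-3"]
        with pytest.raises(rr.ValidationError, match="duplicate"):
            report.add_complete_chunk("d = 4", label="named")

    def test_r_dialect_spellings(self, tmp_path):
        doc = rr.create_report(tmp_path / "r", title="T", dialect="r")
        doc.open_chunk(
            options=rr.make_options_list(eval=False), source_files=["script/fns.R"]
        )
        doc.add_variable_assignment("gene_counts", "import_data()")
        doc.close_chunk()
        text = doc.path.read_text()
        assert "```{r chunk-1, eval=FALSE}" in text
        assert 'source("script/fns.R")' in text
        assert "gene_counts <- import_data()" in text


class TestInvariants:
    def test_step_by_step_equals_single_call(self, tmp_path):
        rng = random.Random(20240901)
        for i in range(25):
            params = random_chunk_tuple(rng)
            a = rr.create_report(tmp_path / f"a{i}", title="T")
            b = rr.create_report(tmp_path / f"b{i}", title="T")
            build_step_by_step(a, *params)
            build_single_call(b, *params)
            assert a.path.read_text() == b.path.read_text()

    def test_fence_lines_always_balanced(self, report):
        assert len(_fence_lines(report)) % 2 == 0
        report.add_complete_chunk("x = 1")
        assert len(_fence_lines(report)) % 2 == 0
        report.open_chunk()  # buffered: nothing on disk yet
        assert len(_fence_lines(report)) % 2 == 0
        report.add_code("y = 2")
        report.close_chunk()
        assert len(_fence_lines(report)) % 2 == 0

    def test_file_length_grows_monotonically(self, report):
        sizes = [report.path.stat().st_size]
        report.add_title("A", 1)
        sizes.append(report.path.stat().st_size)
        report.add_text("prose")
        sizes.append(report.path.stat().st_size)
        report.add_complete_chunk("x = 1")
        sizes.append(report.path.stat().st_size)
        assert sizes == sorted(sizes)
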
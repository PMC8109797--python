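"""Parsing, chunk execution, session info and HTML compilation."""

import platform
import re

import pytest

import reportrail as rr
from reportrail.compiler import collect_session_info, execute_chunk
from reportrail.markdown_emitter import CodeChunk, make_options_list


def _build_mixed_doc(tmp_path, name="doc"):
    doc = rr.create_report(
        tmp_path / name, title="RNA-seq Analysis Report", authors=["Dario Righelli"]
    )
    doc.add_title("Loading Counts Data", 1)
    doc.add_text("We now load the counts.")
    doc.add_complete_chunk("x = 1\nprint(x)", comment="first chunk", title="Load", level=2)
    doc.add_complete_chunk("y = x + 1\ny", options=make_options_list(eval=False))
    return doc


class TestParseReport:
    def test_round_trip_is_byte_identical_with_equal_elements(self, tmp_path):
        doc = _build_mixed_doc(tmp_path)
        parsed = rr.parse_report(doc.path)
        assert parsed.serialize() == doc.path.read_text()
        assert [type(e).__name__ for e in parsed.elements] == [
            type(e).__name__ for e in doc.elements
        ]
        assert parsed.meta.title == "RNA-seq Analysis Report"
        assert parsed.chunks()[1].options.eval is False
        assert parsed.chunks()[0].code_lines == ["x = 1", "print(x)"]

    def test_global_options_recovered_from_setup_chunk(self, tmp_path):
        doc = rr.create_report(
            tmp_path / "g", title="T", global_options=make_options_list(echo=False)
        )
        parsed = rr.parse_report(doc.path)
        assert parsed.meta.global_options.echo is False

    def test_unclosed_fence_reports_opening_line(self, tmp_path):
        doc = _build_mixed_doc(tmp_path)
        text = doc.path.read_text()
        truncated = text[: text.rindex("```")]
        doc.path.write_text(truncated)
        with pytest.raises(rr.ParseError, match=r"line \d+") as err:
            rr.parse_report(doc.path)
        assert "unclosed" in str(err.value)

    def test_missing_front_matter_rejected(self, tmp_path):
        bad = tmp_path / "bad.md"
        bad.write_text("# Just a heading\n")
        with pytest.raises(rr.ParseError, match="line 1"):
            rr.parse_report(bad)


class TestExecuteChunk:
    def test_stdout_and_value_displays_captured(self):
        chunk = CodeChunk(label="c", code_lines=["print('ok')", "21 * 2"])
        result = execute_chunk(chunk, {"__name__": "t"})
        assert "ok" in result.stdout_text
        assert result.value_displays == ["42"]
        assert result.error is None

    def test_eval_false_runs_nothing_and_leaves_env_untouched(self):
        env = {"__name__": "t"}
        chunk = CodeChunk(
            label="c",
            code_lines=["leaked = 1", "print('side effect')"],
            options=make_options_list(eval=False),
        )
        result = execute_chunk(chunk, env, chunk.options.resolved())
        assert result.stdout_text == ""
        assert result.value_displays == []
        assert result.figures == []
        assert "leaked" not in env

    def test_plot_produces_exactly_one_figure(self, tmp_path):
        chunk = CodeChunk(
            label="fig",
            code_lines=[
                "import matplotlib.pyplot as plt",
                "fig, ax = plt.subplots()",
                "ax.plot([1, 2, 3])",
            ],
        )
        result = execute_chunk(chunk, {"__name__": "t"}, figure_dir=tmp_path / "figs")
        assert len(result.figures) == 1
        assert result.figures[0].exists()

    def test_error_is_recorded_with_location(self):
        chunk = CodeChunk(label="c", code_lines=["a = 1", "b = a / 0", "c = 3"])
        env = {"__name__": "t"}
        result = execute_chunk(chunk, env)
        assert result.error is not None
        message, lineno = result.error
        assert "ZeroDivisionError" in message
        assert lineno == 2
        assert "c" not in env  # statements after the failure are skipped

    def test_bindings_thread_between_chunks(self):
        env = {"__name__": "t"}
        execute_chunk(CodeChunk(label="a", code_lines=["shared = 5"]), env)
        result = execute_chunk(CodeChunk(label="b", code_lines=["shared * 2"]), env)
        assert result.value_displays == ["10"]


class TestSessionInfo:
    def test_language_version_matches_runtime_and_own_package_listed(self):
        info = collect_session_info()
        assert info.language_version == platform.python_version()
        assert "reportrail" in info.package_versions
        again = collect_session_info()
        assert info.package_versions == again.package_versions
        assert info.platform == again.platform


class TestCompile:
    @pytest.mark.parametrize("i", range(8))
    def test_option_semantics_matrix(self, tmp_path, i):
        """Code shown iff echo and include; output shown iff eval and include."""
        ev, ec, inc = bool(i & 1), bool(i & 2), bool(i & 4)
        doc = rr.create_report(tmp_path / f"m{i}", title="T")
        doc.add_complete_chunk(
            f"print(1000 + {i})",
            options=make_options_list(eval=ev, echo=ec, include=inc),
        )
        html = rr.compile_report(doc).read_text()
        code_shown = f"print(1000 + {i})" in html
        output_shown = f'<pre class="output">{1000 + i}\n</pre>' in html
        assert code_shown == (ec and inc)
        assert output_shown == (ev and inc)

    def test_compiled_report_contains_sections_in_order(self, tmp_path):
        doc = _build_mixed_doc(tmp_path)
        (tmp_path / "refs.bib").write_text(
            "@article{zkey, author={Zed, A}, title={Zt}, year={2001}}\n"
            "@article{akey, author={Ann, B}, title={At}, year={2002}}\n"
        )
        doc.meta.bibliography = "refs.bib"
        doc._sync()
        doc.add_text("Cited as @zkey and @akey.")
        rr.add_resource(doc, "GEO", "raw counts", "https://example/GSE0000")
        html = rr.compile_report(doc).read_text()
        order = [
            html.index("Loading Counts Data"),
            html.index("first chunk"),
            html.index("Session Information"),
            html.index("<h2>References</h2>"),
            html.index("Resources Availability"),
        ]
        assert order == sorted(order)
        assert html.count("Session Information") == 1
        # references are key-sorted, resources keep all three fields
        refs = html[html.index("<h2>References</h2>") :]
        assert refs.index("[akey]") < refs.index("[zkey]")
        assert "raw counts" in html and "https://example/GSE0000" in html
        # eval=false chunk: code visible, its display output absent
        assert "y = x + 1" in html

    def test_optional_sections_absent_without_bib_or_resources(self, tmp_path):
        html = rr.compile_report(_build_mixed_doc(tmp_path)).read_text()
        assert "References" not in html
        assert "Resources Availability" not in html

    def test_double_compile_leaves_source_unchanged_and_output_stable(self, tmp_path):
        doc = _build_mixed_doc(tmp_path)
        source_before = doc.path.read_bytes()
        out1 = rr.compile_report(doc).read_text()
        out2 = rr.compile_report(doc).read_text()
        assert doc.path.read_bytes() == source_before

        def strip_timestamp(html):
            return re.sub(r"Compiled: [0-9T:+-]+", "Compiled: X", html)

        assert strip_timestamp(out1) == strip_timestamp(out2)
        assert out1.count("Session Information") == 1

    def test_missing_bibliography_with_citations_is_an_error(self, tmp_path):
        doc = rr.create_report(tmp_path / "c", title="T", bibliography="nope.bib")
        doc.add_text("See @ghost2020.")
        with pytest.raises(rr.CompileError, match="bibliography"):
            rr.compile_report(doc)

    def test_unresolved_citation_renders_verbatim(self, tmp_path, caplog):
        doc = rr.create_report(tmp_path / "u", title="T", bibliography="refs.bib")
        (tmp_path / "refs.bib").write_text("@misc{known, title={K}}\n")
        doc.add_text("Known @known and unknown @ghost2020.")
        html = rr.compile_report(doc).read_text()
        assert "[known]" in html
        assert "@ghost2020" in html

    def test_halt_policy_names_failing_chunk(self, tmp_path):
        doc = rr.create_report(tmp_path / "e", title="T")
        doc.add_complete_chunk("boom()", label="explode")
        with pytest.raises(rr.CompileError, match="explode"):
            rr.compile_report(doc)

    def test_continue_policy_renders_error_in_place(self, tmp_path):
        doc = rr.create_report(tmp_path / "e2", title="T")
        doc.add_complete_chunk("boom()")
        doc.add_complete_chunk("print('still runs')")
        html = rr.compile_report(doc, on_error="continue").read_text()
        assert "NameError" in html
        assert "still runs" in html

    def test_open_chunk_blocks_compile(self, report):
        report.open_chunk()
        with pytest.raises(rr.StateError):
            rr.compile_report(report)

    def test_pdf_requires_external_converter(self, report):
        with pytest.raises(rr.CompileError, match="converter"):
            rr.compile_report(report, output_format="pdf")

    def test_compile_from_source_path(self, tmp_path):
        doc = _build_mixed_doc(tmp_path)
        out = rr.compile_report(doc.path)
        assert out.suffix == ".html"
        assert "RNA-seq Analysis Report" in out.read_text()
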
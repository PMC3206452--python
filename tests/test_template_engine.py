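"""Template compilation, record matching, chunking, embedded self-tests."""

import pytest

from cclog.template_engine import (RecordSpec, Template, TemplateError,
                                   apply_template, compile_field_spec,
                                   load_template, match_chunks,
                                   run_embedded_tests)

EIGEN_PATTERN = r"\s*{X, g:name}\s*eigenvalues \-\-{1_5F, g:eigen}"


@pytest.fixture(scope="module")
def eigen_record():
    return RecordSpec.compile("eigen", EIGEN_PATTERN, "star")


class TestFieldSpec:
    @pytest.mark.parametrize("text,expected", [
        ("1_5F, g:eigen", (1, 5, "F", "g:eigen")),
        ("X, g:name", (1, 1, "X", "g:name")),
        ("3I, g:ijk", (3, 3, "I", "g:ijk")),
        ("F, g:val", (1, 1, "F", "g:val")),
        ("A, g:rest", (1, 1, "A", "g:rest")),
    ])
    def test_grammar(self, text, expected):
        spec = compile_field_spec(text)
        assert (spec.min_count, spec.max_count, spec.value_type,
                spec.temp_ref) == expected

    @pytest.mark.parametrize("bad", ["Q, g:x", "5_2F, g:x", "3X, g:x", "F"])
    def test_malformed_specs_name_the_text(self, bad):
        with pytest.raises(TemplateError):
            compile_field_spec(bad)


class TestRecordMatch:
    def test_eigen_line_yields_named_array(self, eigen_record):
        line = ("Alpha virt. eigenvalues -- 0.11292 0.17036 0.17036 "
                "0.17036 0.53917")
        nodes = eigen_record.match(line, "tpl")
        assert len(nodes) == 1  # the X naming capture labels, not emits
        arr = nodes[0]
        assert arr.kind == "array" and arr.role == "Alpha virt."
        assert arr.typed_values()[0] == 0.11292

    def test_non_matching_line(self, eigen_record):
        assert eigen_record.match("SCF Done: E(RB3LYP)", "tpl") is None

    def test_short_line_array_end(self, eigen_record):
        nodes = eigen_record.match(
            "Alpha virt. eigenvalues -- 2.21731 2.21731 2.21731 4.16488", "tpl")
        values = nodes[0].typed_values()
        assert len(values) == 4 and values[-1] == 4.16488

    def test_single_count_emits_scalar(self):
        rec = RecordSpec.compile("e", r"\s*E =\s*{F, g:e}")
        nodes = rec.match(" E = -40.5", "tpl")
        assert nodes[0].kind == "scalar" and nodes[0].typed_value() == -40.5


class TestApplyTemplate:
    def test_example_block_parses_five_records(self, eigen_template,
                                               eigen_block):
        module = apply_template(eigen_block.splitlines(), eigen_template)
        arrays = [c for c in module.children if c.kind == "array"]
        assert len(arrays) == 5
        assert module.templateRef == "l601.alphabetaeigen"

    def test_garbage_line_degrades_to_unparsed_child(self, eigen_template,
                                                     eigen_block):
        lines = eigen_block.splitlines()
        lines[2] = "!! scrambled line !!"
        module = apply_template(lines, eigen_template)
        arrays = [c for c in module.children if c.kind == "array"]
        residue = [c for c in module.children if c.kind == "comment"]
        assert len(arrays) == 4 and len(residue) == 1
        assert residue[0].value == "!! scrambled line !!"


class TestMatchChunks:
    def test_header_block_footer(self, eigen_template, eigen_block):
        text = "header line\n" + eigen_block + "footer line\n"
        result = match_chunks(text, [eigen_template])
        assert len(result.chunks) == 1
        assert len(result.unparsed) == 2
        assert result.reassemble() == text

    def test_empty_file(self, eigen_template):
        result = match_chunks("", [eigen_template])
        assert result.chunks == [] and result.unparsed == []
        assert len(result.document.children) == 0

    def test_thousand_blocks(self, eigen_template, eigen_block):
        text = ("spacer\n" + eigen_block) * 1000
        result = match_chunks(text, [eigen_template])
        assert len(result.chunks) == 1000
        assert result.reassemble() == text

    def test_consumption_no_line_in_two_chunks(self, eigen_template,
                                               eigen_block):
        text = eigen_block * 3
        result = match_chunks(text, [eigen_template])
        seen = set()
        for c in result.chunks:
            span = set(range(c.start_line, c.end_line))
            assert not (span & seen)
            seen |= span

    def test_single_line_chunk_with_star_record(self, eigen_template):
        result = match_chunks(
            "Alpha occ. eigenvalues -- -1.0\n", [eigen_template])
        assert len(result.chunks) == 1

    def test_strict_template_backtracks_to_next(self):
        greedy = Template(id="greedy", start_pattern=r"DATA.*", strict=True,
                          children=[RecordSpec.compile("r", r"NEVERMATCHES")])
        fallback = Template(id="fallback", start_pattern=r"DATA.*",
                            children=[RecordSpec.compile("r", r"DATA {I, g:n}")])
        result = match_chunks("DATA 7\n", [greedy, fallback])
        assert [c.template_id for c in result.chunks] == ["fallback"]


class TestEmbeddedTests:
    def test_shipped_eigen_example_passes(self, eigen_template):
        assert run_embedded_tests(eigen_template).status == "passed"

    def test_wrong_expected_size_fails_naming_array(self):
        text = """<template id="t" pattern="V .*">
          <comment class="example.input" id="e">V 1.0 2.0</comment>
          <record id="r">V {1_5F, g:v}</record>
          <comment class="example.output" id="e">
            <module xmlns:cmlx="http://www.xml-cml.org/schema/cmlx">
              <array dataType="xsd:double" size="3" cmlx:temp="g:v"
                dictRef="g:v">1.0 2.0 3.0</array></module>
          </comment>
        </template>"""
        tpl = load_template(text)
        result = run_embedded_tests(tpl)
        assert result.status == "failed" and "array" in result.detail

    def test_template_without_examples_reported_untested(self):
        tpl = Template(id="t", start_pattern=r".*")
        assert run_embedded_tests(tpl).status == "untested"
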
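"""Declarative transform steps and programs."""

import pytest

from cclog.semdoc import SemNode
from cclog.template_engine import apply_template
from cclog.transform_dsl import (TransformError, TransformStep, apply_program,
                                 apply_step)


def arr(values, dictRef=None, role=None, dataType="xsd:double", size=True):
    return SemNode(kind="array", dictRef=dictRef, role=role, dataType=dataType,
                   value=[str(v) for v in values],
                   size=len(values) if size else None)


@pytest.fixture()
def raw_eigen(eigen_template, eigen_block):
    """Raw parse of the five-line eigenvalue block, before transforms."""
    return apply_template(eigen_block.splitlines(), eigen_template)


class TestSteps:
    def test_add_dictref_relabels_one_array(self, raw_eigen):
        apply_step(raw_eigen, TransformStep(
            "addDictRef", ".//array[@cmlx:temp='Alpha occ.']", "cc:alphaocc"))
        hits = [n for n in raw_eigen.iter() if n.dictRef == "cc:alphaocc"]
        assert len(hits) == 1
        assert hits[0].role is None  # the rename consumes the temp label

    def test_join_arrays_5_5_5_3_gives_18(self):
        root = SemNode(kind="module")
        for n in (5, 5, 5, 3):
            root.append(arr(range(n), dictRef="cc:alphavirt"))
        apply_step(root, TransformStep(
            "joinArrays", ".//array[@dictRef='cc:alphavirt']"))
        assert len(root.children) == 1
        assert root.children[0].size == 18
        assert len(root.children[0].value) == 18

    def test_join_single_array_is_identity(self):
        root = SemNode(kind="module")
        root.append(arr([1, 2], dictRef="cc:x"))
        apply_step(root, TransformStep("joinArrays", ".//array[@dictRef='cc:x']"))
        assert len(root.children) == 1 and root.children[0].value == ["1", "2"]

    def test_join_preserves_order_and_count(self):
        root = SemNode(kind="module")
        root.append(arr([1, 2], dictRef="cc:x"))
        root.append(arr([3], dictRef="cc:x"))
        apply_step(root, TransformStep("joinArrays", ".//array[@dictRef='cc:x']"))
        assert root.children[0].value == ["1", "2", "3"]

    def test_join_type_conflict_raises(self):
        root = SemNode(kind="module")
        root.append(arr([1], dictRef="cc:x", dataType="xsd:double"))
        root.append(arr([2], dictRef="cc:x", dataType="xsd:integer"))
        with pytest.raises(TransformError, match="dataType"):
            apply_step(root, TransformStep("joinArrays",
                                           ".//array[@dictRef='cc:x']"))

    def test_join_skips_non_adjacent_runs(self):
        root = SemNode(kind="module")
        root.append(arr([1], dictRef="cc:x"))
        root.append(SemNode(kind="scalar", value="sep"))
        root.append(arr([2], dictRef="cc:x"))
        apply_step(root, TransformStep("joinArrays", ".//array[@dictRef='cc:x']"))
        assert len([c for c in root.children if c.kind == "array"]) == 2

    def test_delete_no_match_is_noop(self, raw_eigen):
        before = len(list(raw_eigen.iter()))
        apply_step(raw_eigen, TransformStep("delete", ".//scalar[@id='nope']"))
        assert len(list(raw_eigen.iter())) == before

    def test_delete_hierarchy_lifts_children(self):
        root = SemNode(kind="module")
        inner = root.append(SemNode(kind="module", dictRef="cc:junk"))
        inner.append(SemNode(kind="scalar", value="a"))
        inner.append(SemNode(kind="scalar", value="b"))
        apply_step(root, TransformStep("deleteHierarchy",
                                       ".//module[@dictRef='cc:junk']"))
        assert [c.kind for c in root.children] == ["scalar", "scalar"]

    def test_group_siblings_wraps_run(self):
        root = SemNode(kind="module")
        root.append(arr([1], role="g:a"))
        root.append(arr([2], role="g:a"))
        root.append(SemNode(kind="scalar", value="tail"))
        apply_step(root, TransformStep("groupSiblings",
                                       ".//array[@cmlx:temp='g:a']", "cc:grp"))
        assert len(root.children) == 2
        wrapper = root.children[0]
        assert wrapper.kind == "module" and wrapper.dictRef == "cc:grp"
        assert len(wrapper.children) == 2

    def test_unknown_process_rejected_at_load(self):
        with pytest.raises(TransformError, match="frobnicate"):
            TransformStep("frobnicate", ".//scalar")


class TestPrograms:
    def appendix_steps(self):
        return [
            TransformStep("addDictRef", ".//array[@cmlx:temp='Alpha occ.']",
                          "cc:alphaocc"),
            TransformStep("addDictRef", ".//array[@cmlx:temp='Alpha virt.']",
                          "cc:alphavirt"),
            TransformStep("joinArrays", ".//array[@dictRef='g:alphaocc']"),
            TransformStep("joinArrays", ".//array[@dictRef='g:alphavirt']"),
        ]

    def test_full_program_reproduces_expected_arrays(self, raw_eigen):
        apply_program(raw_eigen, self.appendix_steps())
        arrays = [c for c in raw_eigen.children if c.kind == "array"]
        assert [a.dictRef for a in arrays] == ["cc:alphaocc", "cc:alphavirt"]
        assert [len(a.value) for a in arrays] == [5, 18]

    def test_empty_program_is_identity(self, raw_eigen):
        before = len(list(raw_eigen.iter()))
        apply_program(raw_eigen, [])
        assert len(list(raw_eigen.iter())) == before

    def test_inert_step_changes_nothing(self, eigen_template, eigen_block):
        a = apply_template(eigen_block.splitlines(), eigen_template)
        b = apply_template(eigen_block.splitlines(), eigen_template)
        steps = self.appendix_steps()
        steps_with_noop = steps[:2] + [
            TransformStep("delete", ".//scalar[@dictRef='cc:absent']")
        ] + steps[2:]
        apply_program(a, steps)
        apply_program(b, steps_with_noop)
        from cclog.semdoc import structurally_equal
        assert structurally_equal(a, b)

    def test_add_dictref_idempotent(self, raw_eigen):
        step = TransformStep("addDictRef", ".//array[@dictRef='g:eigen']",
                             "g:eigen")
        apply_step(raw_eigen, step)
        snapshot = [n.dictRef for n in raw_eigen.iter()]
        apply_step(raw_eigen, step)
        assert [n.dictRef for n in raw_eigen.iter()] == snapshot
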
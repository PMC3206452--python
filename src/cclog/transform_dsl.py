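"""Second-phase declarative normalization of raw parsed trees.

A raw parse mirrors the line structure of the logfile; these transform steps
turn it into a tractable document: relabelling temporary references with
dictionary terms, attaching units the logfile never states, stitching
wrapped lines back into single arrays, deleting noise and regrouping
siblings.  A step whose path matches nothing is a silent no-op (logged): a
strange document must never crash the process.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .paths import PathExpr
from .semdoc import SemNode

log = logging.getLogger("cclog")

__all__ = ["TransformStep", "TransformError", "apply_step", "apply_program"]

PROCESSES = {
    "addDictRef", "addUnits", "setDataType", "joinArrays", "delete",
    "deleteHierarchy", "rename", "move", "groupSiblings", "annotateModule",
}


class TransformError(Exception):
    pass


@dataclass
class TransformStep:
    process: str
    path: PathExpr
    value: str | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.process not in PROCESSES:
            raise TransformError(f"unknown transform process {self.process!r}")
        if isinstance(self.path, str):
            self.path = PathExpr.parse(self.path)


def _parent_map(root: SemNode) -> dict[int, SemNode]:
    parents = {}
    for node in root.iter():
        for c in node.children:
            parents[id(c)] = node
    return parents


def apply_step(root: SemNode, step: TransformStep) -> SemNode:
    """Apply one step in place; returns the same tree."""
    matches = step.path.select(root)
    if not matches:
        log.info("transform %s: path matched nothing (no-op)", step.process)
        return root

    if step.process == "addDictRef":
        for n in matches:
            n.dictRef = step.value
            n.role = None  # the rename consumes the temporary label
    elif step.process == "addUnits":
        for n in matches:
            n.units = step.value
    elif step.process == "setDataType":
        for n in matches:
            n.dataType = step.value
    elif step.process == "rename":
        for n in matches:
            n.dictRef = step.value
    elif step.process == "annotateModule":
        for n in matches:
            if step.value:
                n.role = step.value
            if "id" in step.extra:
                n.id = step.extra["id"]
    elif step.process == "delete":
        parents = _parent_map(root)
        for n in matches:
            p = parents.get(id(n))
            if p is not None and n in p.children:
                p.children.remove(n)
    elif step.process == "deleteHierarchy":
        parents = _parent_map(root)
        for n in matches:
            p = parents.get(id(n))
            if p is None:
                continue
            i = p.children.index(n)
            p.children[i:i + 1] = n.children
    elif step.process == "joinArrays":
        _join_arrays(root, matches)
    elif step.process == "groupSiblings":
        _group_siblings(root, matches, step)
    elif step.process == "move":
        _move(root, matches, step)
    return root


def _runs_of_siblings(root: SemNode, matches: list[SemNode]):
    """Group matches into runs of consecutive siblings (same parent,
    adjacent positions)."""
    parents = _parent_map(root)
    matched = {id(n) for n in matches}
    runs = []
    for node in root.iter():
        run = []
        for c in node.children:
            if id(c) in matched:
                run.append(c)
            else:
                if len(run) > 1:
                    runs.append((node, run))
                run = []
        if len(run) > 1:
            runs.append((node, run))
    return parents, runs


def _join_arrays(root: SemNode, matches: list[SemNode]):
    """Concatenate each run of consecutive sibling arrays with equal
    dictRef/role into the first array of the run."""
    arrays = [n for n in matches if n.kind == "array"]
    _, runs = _runs_of_siblings(root, arrays)
    for parent, run in runs:
        # split the run further on (dictRef, role) agreement
        groups, cur = [], [run[0]]
        for n in run[1:]:
            if n.dictRef == cur[-1].dictRef and n.role == cur[-1].role:
                cur.append(n)
            else:
                groups.append(cur)
                cur = [n]
        groups.append(cur)
        for grp in groups:
            if len(grp) < 2:
                continue
            head = grp[0]
            for n in grp[1:]:
                if n.dataType != head.dataType:
                    raise TransformError(
                        f"joinArrays over differing dataType: "
                        f"{head.dictRef}/{head.dataType} vs {n.dictRef}/{n.dataType}")
                head.value = list(head.value or []) + list(n.value or [])
                parent.children.remove(n)
            if head.size is not None or any(g.size is not None for g in grp):
                head.size = len(head.value)


def _group_siblings(root: SemNode, matches: list[SemNode], step: TransformStep):
    """Wrap each run of consecutive matched siblings in a new module with the
    given dictRef."""
    matched = {id(n) for n in matches}
    by_parent: dict[int, list[list[SemNode]]] = {}
    for node in root.iter():
        run = []
        for c in node.children:
            if id(c) in matched:
                run.append(c)
            else:
                if run:
                    by_parent.setdefault(id(node), []).append(run)
                run = []
        if run:
            by_parent.setdefault(id(node), []).append(run)
    for node in root.iter():
        for run in by_parent.get(id(node), []):
            i = node.children.index(run[0])
            wrapper = SemNode(kind="module", dictRef=step.value,
                              id=step.extra.get("id"))
            wrapper.children = run
            node.children[i:i + len(run)] = [wrapper]


def _move(root: SemNode, matches: list[SemNode], step: TransformStep):
    """Move matches to the end of the node selected by extra['to']."""
    to_path = step.extra.get("to")
    if not to_path:
        raise TransformError("move requires a 'to' path")
    targets = PathExpr.parse(to_path).select(root)
    if not targets:
        log.info("transform move: destination matched nothing (no-op)")
        return
    dest = targets[0]
    parents = _parent_map(root)
    for n in matches:
        if n is dest:
            continue
        p = parents.get(id(n))
        if p is not None and n in p.children:
            p.children.remove(n)
            dest.children.append(n)


def apply_program(root: SemNode, steps: list[TransformStep]) -> SemNode:
    """Apply steps strictly in order; no-match steps never abort.

    Only hard type conflicts abort, reported with the step index.
    """
    for i, step in enumerate(steps):
        try:
            apply_step(root, step)
        except TransformError as exc:
            raise TransformError(f"step {i} ({step.process}): {exc}") from exc
    return root
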
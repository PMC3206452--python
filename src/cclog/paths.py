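"""Restricted path expressions for selecting nodes in a semantic tree.

Grammar (the subset the declarative transform files need)::

    path      := ('.//' | './' | '') step ('/' step)*
    step      := nametest predicate*
    nametest  := NAME | PREFIX ':' NAME | '*'
    predicate := '[@' attr '=' "'" value "'" ']'

The leading ``.//`` selects on the descendant axis; subsequent steps use the
child axis.  Attribute predicates are conjunctive and limited to dictRef,
cmlx:temp (role), cmlx:templateRef and id.  Evaluation visits each node at
most once and results are in document order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .naming import refs_match_lenient

__all__ = ["PathExpr", "PathError"]


class PathError(ValueError):
    pass


_STEP_RE = re.compile(
    r"^(?P<name>\*|[\w.:-]+)(?P<preds>(?:\[@[\w:.-]+='[^']*'\])*)$")
_PRED_RE = re.compile(r"\[@(?P<attr>[\w:.-]+)='(?P<value>[^']*)'\]")

# attribute name in the path -> SemNode attribute
_ATTR_MAP = {
    "dictRef": "dictRef",
    "id": "id",
    "cmlx:temp": "role",
    "temp": "role",
    "cmlx:templateRef": "templateRef",
    "templateRef": "templateRef",
}


@dataclass
class Step:
    name: str                      # node kind or '*'
    predicates: list[tuple[str, str]] = field(default_factory=list)

    def matches(self, node) -> bool:
        if self.name != "*" and node.kind != self.name:
            return False
        for attr, value in self.predicates:
            actual = getattr(node, attr)
            if actual is None:
                return False
            if attr == "dictRef":
                if not refs_match_lenient(value, actual):
                    return False
            elif attr == "role":
                if actual.strip() != value.strip():
                    return False
            elif actual != value:
                return False
        return True


@dataclass
class PathExpr:
    steps: list[Step]
    descendant: bool  # first step on descendant axis (.//) vs child (./)

    @classmethod
    def parse(cls, text: str) -> "PathExpr":
        s = text.strip()
        if s.startswith(".//"):
            descendant, rest = True, s[3:]
        elif s.startswith("./"):
            descendant, rest = False, s[2:]
        elif s.startswith("//") or s.startswith("/"):
            raise PathError(f"paths must be relative (use ./ or .//): {text!r}")
        else:
            descendant, rest = False, s
        if not rest:
            raise PathError(f"empty path: {text!r}")
        steps = []
        for part in rest.split("/"):
            m = _STEP_RE.match(part.strip())
            if not m:
                raise PathError(f"bad path step {part!r} in {text!r}")
            name = m.group("name")
            if ":" in name:  # strip namespace prefix from the name test
                name = name.split(":", 1)[1]
            preds = []
            for pm in _PRED_RE.finditer(m.group("preds")):
                attr = pm.group("attr")
                if attr not in _ATTR_MAP:
                    raise PathError(f"unsupported predicate attribute @{attr}")
                preds.append((_ATTR_MAP[attr], pm.group("value")))
            steps.append(Step(name, preds))
        return cls(steps, descendant)

    def select(self, root) -> list:
        """Document-ordered matches below root (root itself excluded)."""
        first, rest = self.steps[0], self.steps[1:]
        out, seen = [], set()

        def children_chain(node, steps):
            if not steps:
                if id(node) not in seen:
                    seen.add(id(node))
                    out.append(node)
                return
            step, tail = steps[0], steps[1:]
            for c in node.children:
                if step.matches(c):
                    children_chain(c, tail)

        if self.descendant:
            def walk(node):
                for c in node.children:
                    if first.matches(c):
                        children_chain(c, rest)
                    walk(c)
            walk(root)
        else:
            for c in root.children:
                if first.matches(c):
                    children_chain(c, rest)
        return out
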
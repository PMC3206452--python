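"""Declarative template engine for record-oriented logfiles.

Quantum-chemistry programs write their logs through record-oriented
(FORTRAN-format) routines, so output arrives in recognizable *chunks* — an
eigenvalue table, a coordinate block, a thermochemistry summary.  A template
describes one chunk: a start pattern, an optional end pattern, and typed
*records* whose field specifiers (``{1_5F, g:eigen}``) capture the values.
Templates are matched top to bottom over the file; a claimed chunk is
consumed and never re-offered to later templates.  Lines nothing claims are
kept as unparsed residue, so parsed chunks plus residue always tile the
input exactly — failures are silent, never fatal.

Field specifier grammar: ``{COUNT TYPE, REF}`` with COUNT either a single
integer or ``min_max``, absent meaning 1, and TYPE one of

====  =============================  =================================
F     floating point (D or E exp.)   count > 1 emits an array
I     integer                        count > 1 emits an array
X     string token (trimmed)         always single; a ref with local
                                     name ``name`` labels its siblings
A     rest of line                   always single
====  =============================  =================================
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from lxml import etree

from . import naming
from .semdoc import SemNode, read_document, first_difference
from .transform_dsl import TransformStep, apply_program

log = logging.getLogger("cclog")

__all__ = [
    "FieldSpec", "RecordSpec", "Template", "Chunk", "ParseResult",
    "TemplateError", "compile_field_spec", "load_templates", "load_template",
    "apply_template", "match_chunks", "run_embedded_tests",
]


class TemplateError(Exception):
    """A template failed to compile."""


# Alternation-free numeric fragments: fixed shape with optional tails, so a
# line of k tokens is matched in O(k) without exponential backtracking.
_FLOAT = r"[+-]?(?:\d+\.\d*|\.\d+|\d+)(?:[EeDd][+-]?\d+)?"
_INT = r"[+-]?\d+"

_SPEC_RE = re.compile(
    r"^\s*(?:(?P<min>\d+)(?:_(?P<max>\d+))?)?(?P<type>[FIXA])\s*,\s*(?P<ref>\S+)\s*$")


@dataclass(frozen=True)
class FieldSpec:
    min_count: int
    max_count: int
    value_type: str        # F | I | X | A
    temp_ref: str          # temporary qualified name, e.g. g:eigen

    @property
    def is_array(self) -> bool:
        return self.max_count > 1


def compile_field_spec(spec_text: str) -> FieldSpec:
    """Parse the text between braces of a field specifier."""
    m = _SPEC_RE.match(spec_text)
    if not m:
        raise TemplateError(f"malformed field specifier {{{spec_text}}}")
    vtype = m.group("type")
    lo = int(m.group("min")) if m.group("min") else 1
    hi = int(m.group("max")) if m.group("max") else lo
    if vtype in ("X", "A"):
        if m.group("min"):
            raise TemplateError(
                f"{vtype} fields take no count: {{{spec_text}}}")
        lo = hi = 1
    if lo < 1 or hi < lo:
        raise TemplateError(f"bad count range in {{{spec_text}}}")
    return FieldSpec(lo, hi, vtype, m.group("ref"))


def _field_regex(spec: FieldSpec, group: str) -> str:
    if spec.value_type == "F":
        return rf"(?P<{group}>(?:\s*{_FLOAT}){{{spec.min_count},{spec.max_count}}})"
    if spec.value_type == "I":
        return rf"(?P<{group}>(?:\s*{_INT}){{{spec.min_count},{spec.max_count}}})"
    if spec.value_type == "X":
        return rf"(?P<{group}>.+?)"
    return rf"(?P<{group}>.*)"  # A


_BRACE_RE = re.compile(r"\{([^{}]*)\}")


@dataclass
class RecordSpec:
    """One single-line pattern: literal regex segments interleaved with
    field specifiers, compiled to a matcher with one group per field."""

    id: str
    pattern: str
    repeat: str = "once"           # once | star | plus | exact:<n>
    fields: list[FieldSpec] = field(default_factory=list)
    _re: re.Pattern = None

    @classmethod
    def compile(cls, rec_id: str, pattern: str, repeat: str = "once") -> "RecordSpec":
        fields, parts, last = [], [], 0
        for i, m in enumerate(_BRACE_RE.finditer(pattern)):
            parts.append(pattern[last:m.start()])
            spec = compile_field_spec(m.group(1))
            fields.append(spec)
            parts.append(_field_regex(spec, f"f{i}"))
            last = m.end()
        parts.append(pattern[last:])
        src = "".join(parts) + r"\s*"
        try:
            rx = re.compile(src)
        except re.error as exc:
            raise TemplateError(f"record {rec_id!r} does not compile: {exc}")
        return cls(rec_id, pattern, repeat, fields, rx)

    def match(self, line: str, template_id: str) -> list[SemNode] | None:
        """Match one line; None on failure, else one node per field (a
        scalar for count 1, an array otherwise), labelled with the
        temporary reference and the owning template."""
        m = self._re.fullmatch(line)
        if m is None:
            return None
        nodes, name_label = [], None
        for i, spec in enumerate(self.fields):
            raw = m.group(f"f{i}")
            if spec.value_type == "X":
                text = raw.strip()
                if naming.split_ref(spec.temp_ref)[1] == "name":
                    name_label = text     # names its sibling captures
                    continue
                nodes.append(SemNode(kind="scalar", dictRef=spec.temp_ref,
                                     role=spec.temp_ref, value=text,
                                     templateRef=template_id))
            elif spec.value_type == "A":
                nodes.append(SemNode(kind="scalar", dictRef=spec.temp_ref,
                                     role=spec.temp_ref, value=raw.strip(),
                                     templateRef=template_id))
            else:
                dt = "xsd:double" if spec.value_type == "F" else "xsd:integer"
                toks = [t.replace("D", "E").replace("d", "e") for t in raw.split()]
                if spec.is_array:
                    nodes.append(SemNode(kind="array", dictRef=spec.temp_ref,
                                         role=spec.temp_ref, dataType=dt,
                                         size=len(toks), value=toks,
                                         templateRef=template_id))
                else:
                    nodes.append(SemNode(kind="scalar", dictRef=spec.temp_ref,
                                         role=spec.temp_ref, dataType=dt,
                                         value=toks[0], templateRef=template_id))
        if name_label is not None:
            for n in nodes:
                n.role = name_label
        return nodes


@dataclass
class Template:
    id: str
    start_pattern: str
    end_pattern: str | None = None
    repeat: str = "star"
    strict: bool = False
    children: list = field(default_factory=list)    # RecordSpec | Template
    transforms: list[TransformStep] = field(default_factory=list)
    embedded_examples: list[tuple[str, str]] = field(default_factory=list)
    _start_re: re.Pattern = None
    _end_re: re.Pattern = None

    def __post_init__(self):
        if self._start_re is None:
            try:
                self._start_re = re.compile(self.start_pattern)
            except re.error as exc:
                raise TemplateError(
                    f"template {self.id!r} start pattern: {exc}")
        if self._end_re is None and self.end_pattern is not None:
            try:
                self._end_re = re.compile(self.end_pattern)
            except re.error as exc:
                raise TemplateError(f"template {self.id!r} end pattern: {exc}")

    def starts(self, line: str) -> bool:
        return self._start_re.fullmatch(line) is not None

    def ends(self, line: str) -> bool:
        return self._end_re is not None and self._end_re.fullmatch(line) is not None


@dataclass(frozen=True)
class Chunk:
    """Half-open line range claimed by one template."""
    start_line: int
    end_line: int
    template_id: str
    text: str = ""


@dataclass
class ParseResult:
    document: SemNode
    chunks: list[Chunk]
    unparsed: list[Chunk]          # template_id == "" for residue

    def reassemble(self) -> str:
        pieces = sorted(self.chunks + self.unparsed, key=lambda c: c.start_line)
        return "".join(p.text for p in pieces)

    @property
    def unparsed_fraction(self) -> float:
        total = sum(c.end_line - c.start_line for c in self.chunks + self.unparsed)
        if total == 0:
            return 0.0
        res = sum(c.end_line - c.start_line for c in self.unparsed)
        return res / total


# ---------------------------------------------------------------------------
# Template XML loading
# ---------------------------------------------------------------------------

def _local(tag):
    return tag.rsplit("}", 1)[-1] if isinstance(tag, str) and "}" in tag else tag


def _load_template_element(el) -> Template:
    tid = el.get("id")
    if not tid:
        raise TemplateError("template element without id")
    pattern = el.get("pattern")
    if not pattern:
        raise TemplateError(f"template {tid!r} has no start pattern")
    tpl = Template(
        id=tid,
        start_pattern=pattern,
        end_pattern=el.get("endPattern"),
        repeat=el.get("repeat", "star"),
        strict=el.get("strict", "false").lower() in ("1", "true", "yes"),
    )
    example_inputs, example_outputs = {}, {}
    for sub in el:
        if not isinstance(sub.tag, str):
            continue
        name = _local(sub.tag)
        if name == "record":
            rid = sub.get("id") or f"{tid}.r{len(tpl.children)}"
            repeat = {"*": "star", "+": "plus"}.get(sub.get("repeat", ""),
                                                   sub.get("repeat", "once"))
            tpl.children.append(RecordSpec.compile(rid, (sub.text or "").strip("\n"),
                                                   repeat))
        elif name == "template":
            tpl.children.append(_load_template_element(sub))
        elif name == "transform":
            path = sub.get("xpath") or sub.get("path")
            if not path:
                raise TemplateError(f"transform in {tid!r} without path")
            extra = {k: v for k, v in sub.attrib.items()
                     if k not in ("process", "xpath", "path", "value")}
            tpl.transforms.append(TransformStep(sub.get("process"), path,
                                                sub.get("value"), extra))
        elif name == "comment":
            cls_ = sub.get("class", "")
            body = sub.text or ""
            if cls_ == "example.input":
                example_inputs[sub.get("id", "")] = body
            elif cls_ == "example.output":
                example_outputs[sub.get("id", "")] = (
                    "".join(etree.tostring(c, encoding="unicode") for c in sub)
                    or body)
    for key, inp in example_inputs.items():
        if key in example_outputs:
            tpl.embedded_examples.append((inp, example_outputs[key]))
    return tpl


def load_template(text: str | bytes) -> Template:
    """Load a single template file."""
    tpls = load_templates(text)
    if len(tpls) != 1:
        raise TemplateError(f"expected one template, found {len(tpls)}")
    return tpls[0]


def load_templates(text: str | bytes) -> list[Template]:
    """Load a template file: either one <template> or a <templateList>."""
    if isinstance(text, str):
        text = text.encode("utf-8")
    try:
        root = etree.fromstring(text)
    except etree.XMLSyntaxError as exc:
        raise TemplateError(f"template file is not well-formed XML: {exc}")
    if _local(root.tag) == "template":
        return [_load_template_element(root)]
    out = []
    for sub in root:
        if isinstance(sub.tag, str) and _local(sub.tag) == "template":
            out.append(_load_template_element(sub))
    return out


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def _strip_eol(line: str) -> str:
    return line.rstrip("\r\n")


def apply_template(lines: list[str], tpl: Template) -> SemNode:
    """Parse one claimed chunk into a raw module.

    Each line is offered to the template's children in declared order; the
    first record that matches emits its nodes, a nested template claims a
    sub-chunk, and a line matching nothing degrades to an unparsed text
    child.  Never raises on content.
    """
    module = SemNode(kind="module", templateRef=tpl.id)
    i = 0
    while i < len(lines):
        line = _strip_eol(lines[i])
        consumed = False
        for child in tpl.children:
            if isinstance(child, RecordSpec):
                nodes = child.match(line, tpl.id)
                if nodes is not None:
                    module.children.extend(nodes)
                    i += 1
                    consumed = True
                    break
            else:  # nested template
                if child.starts(line):
                    end = _chunk_end(lines, i, child)
                    module.append(apply_template(lines[i:end], child))
                    i = end
                    consumed = True
                    break
        if not consumed:
            module.append(SemNode(kind="comment", value=line,
                                  extra={"class": "cclog:unparsed"}))
            i += 1
    return module


def _record_matches_any(tpl: Template, line: str) -> bool:
    for child in tpl.children:
        if isinstance(child, RecordSpec):
            if child._re.fullmatch(line):
                return True
        elif child.starts(line):
            return True
    return False


def _chunk_end(lines: list[str], start: int, tpl: Template) -> int:
    """Exclusive end index of the chunk tpl claims at lines[start].

    The chunk extends while lines keep matching the template's records or
    nested templates (maximal munch); a line matching the end pattern stops
    it unconditionally and is not consumed.  Always consumes at least the
    start line, guaranteeing progress.
    """
    n = len(lines)
    j = start + 1
    while j < n:
        line = _strip_eol(lines[j])
        if tpl.ends(line) or not _record_matches_any(tpl, line):
            break
        j += 1
    return j


def match_chunks(text: str, templates: list[Template], *,
                 apply_transforms: bool = True) -> ParseResult:
    """Scan a logfile top to bottom, letting the first template whose start
    pattern matches claim a chunk; claimed lines are consumed and never
    re-offered.  Returns the raw document in chunk order plus the residue;
    chunk lines and unparsed lines exactly tile the input.
    """
    lines = text.splitlines(keepends=True)
    n = len(lines)
    doc = SemNode(kind="module", id="raw")
    chunks: list[Chunk] = []
    unparsed: list[Chunk] = []
    i = 0
    pending_start = None
    while i < n:
        line = _strip_eol(lines[i])
        claimed = False
        for tpl in templates:
            if not tpl.starts(line):
                continue
            end = _chunk_end(lines, i, tpl)
            module = apply_template(lines[i:end], tpl)
            got_content = any(
                c.kind != "comment" or c.extra.get("class") != "cclog:unparsed"
                for c in module.children)
            if tpl.strict and not got_content:
                continue  # rewind: offer the line to the next template
            if apply_transforms and tpl.transforms:
                apply_program(module, tpl.transforms)
            if pending_start is not None:
                unparsed.append(Chunk(pending_start, i, "",
                                      "".join(lines[pending_start:i])))
                pending_start = None
            doc.append(module)
            chunks.append(Chunk(i, end, tpl.id, "".join(lines[i:end])))
            i = end
            claimed = True
            break
        if not claimed:
            if pending_start is None:
                pending_start = i
            i += 1
    if pending_start is not None:
        unparsed.append(Chunk(pending_start, n, "",
                              "".join(lines[pending_start:n])))
    return ParseResult(doc, chunks, unparsed)


# ---------------------------------------------------------------------------
# Embedded self-tests
# ---------------------------------------------------------------------------

@dataclass
class EmbeddedTestResult:
    template_id: str
    status: str                      # passed | failed | untested
    detail: str = ""


def run_embedded_tests(tpl: Template) -> EmbeddedTestResult:
    """Run the template's embedded example(s): parse the example input,
    apply the template's transforms, and compare structurally with the
    expected output tree."""
    if not tpl.embedded_examples:
        return EmbeddedTestResult(tpl.id, "untested", "no embedded examples")
    for inp, expected_xml in tpl.embedded_examples:
        body = inp.strip("\n")
        result = match_chunks(body, [tpl])
        mods = [c for c in result.document.children]
        if len(mods) != 1:
            return EmbeddedTestResult(
                tpl.id, "failed", f"expected 1 chunk, parsed {len(mods)}")
        expected = read_document(expected_xml)
        diff = first_difference(mods[0], expected, ignore_id=True,
                                lenient_template_ref=True)
        if diff:
            return EmbeddedTestResult(tpl.id, "failed", diff)
    return EmbeddedTestResult(tpl.id, "passed")
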
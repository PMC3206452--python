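"""Semantic dictionaries: term definitions with dataType and units.

Every ``dictRef`` in a converted document should resolve to an entry in a
dictionary; the compchem dictionary shipped as package data holds the
code-independent concepts (jobs, energies, frequencies, thermochemistry),
while code-specific ``g:`` terms and unassigned ``x:`` temporaries are
allowed to float as warnings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

from lxml import etree

from .naming import alias_of, split_ref
from .semdoc import SemNode

__all__ = [
    "DictEntry", "Dictionary", "DictionaryError", "UnresolvedPrefixError",
    "UnresolvedTermError", "ValidationFinding", "ValidationReport",
    "load_dictionary", "load_compchem_dictionary", "resolve", "validate_refs",
]


class DictionaryError(Exception):
    pass


class UnresolvedPrefixError(DictionaryError):
    pass


class UnresolvedTermError(DictionaryError):
    pass


@dataclass
class DictEntry:
    id: str
    term: str
    dataType: str | None = None
    unitType: str | None = None
    units: str | None = None
    definition: str = ""
    description: str = ""
    examples: list[str] = field(default_factory=list)


@dataclass
class Dictionary:
    prefix: str
    title: str = ""
    entries: dict[str, DictEntry] = field(default_factory=dict)
    contributors: list[str] = field(default_factory=list)
    issues: list[str] = field(default_factory=list)

    def __contains__(self, entry_id: str) -> bool:
        return entry_id in self.entries

    def __getitem__(self, entry_id: str) -> DictEntry:
        return self.entries[entry_id]


def _local(tag):
    return tag.rsplit("}", 1)[-1] if isinstance(tag, str) and "}" in tag else tag


def _text_of(el) -> str:
    return " ".join("".join(el.itertext()).split())


def load_dictionary(text: str | bytes, *, on_duplicate: str = "error") -> Dictionary:
    """Load a dictionary file.

    Truncated entries (id present, body elided) load with an empty
    description.  Duplicate ids raise by default; ``on_duplicate="flag"``
    keeps the first entry and records the clash in ``Dictionary.issues``
    instead of silently picking one.
    """
    if isinstance(text, str):
        text = text.encode("utf-8")
    try:
        root = etree.fromstring(text)
    except etree.XMLSyntaxError as exc:
        raise DictionaryError(f"dictionary is not well-formed XML: {exc}")
    dic = Dictionary(prefix=root.get("dictionaryPrefix", ""),
                     title=root.get("title", ""))
    for i, el in enumerate(root.iter()):
        if _local(el.tag) == "contributor":
            dic.contributors.append(_text_of(el))
    for pos, el in enumerate(e for e in root.iter() if _local(e.tag) == "entry"):
        eid = el.get("id")
        if not eid:
            raise DictionaryError(f"entry #{pos} has no id attribute")
        if eid != eid.strip() or " " in eid:
            raise DictionaryError(f"entry id {eid!r} contains whitespace")
        entry = DictEntry(
            id=eid,
            term=el.get("term", ""),
            dataType=el.get("dataType"),
            unitType=el.get("unitType"),
            units=el.get("units"),
        )
        for sub in el:
            name = _local(sub.tag)
            if name == "definition":
                entry.definition = _text_of(sub)
            elif name == "description":
                entry.description = _text_of(sub)
                for p in sub.iter():
                    if (p.get("class") or "").endswith("example"):
                        entry.examples.append(_text_of(p))
        if eid in dic.entries:
            msg = f"duplicate entry id {eid!r}"
            if on_duplicate == "flag":
                dic.issues.append(msg)
                continue
            raise DictionaryError(msg)
        dic.entries[eid] = entry
    return dic


def load_compchem_dictionary() -> Dictionary:
    """The compchem dictionary shipped as package data."""
    text = resources.files("cclog.data").joinpath("compchem.xml").read_text()
    return load_dictionary(text)


def resolve(ref: str, dicts: list[Dictionary]) -> DictEntry:
    """Resolve ``prefix:local`` against the dictionaries via the alias table
    (``cc`` and ``compchem`` both alias the compchem dictionary)."""
    prefix, local = split_ref(ref)
    target = alias_of(prefix)
    if target is None:
        raise UnresolvedPrefixError(f"prefix {prefix!r} in {ref!r} names no dictionary")
    for d in dicts:
        if alias_of(d.prefix) == target or d.prefix == target:
            if local in d.entries:
                return d.entries[local]
            raise UnresolvedTermError(f"{ref!r}: no entry {local!r} in "
                                      f"dictionary {d.prefix!r}")
    raise UnresolvedPrefixError(
        f"{ref!r}: no dictionary loaded for prefix {prefix!r}")


@dataclass
class ValidationFinding:
    severity: str       # error | warning
    path: str
    code: str
    message: str


@dataclass
class ValidationReport:
    findings: list[ValidationFinding] = field(default_factory=list)

    @property
    def errors(self) -> list[ValidationFinding]:
        return [f for f in self.findings if f.severity == "error"]

    @property
    def warnings(self) -> list[ValidationFinding]:
        return [f for f in self.findings if f.severity == "warning"]

    @property
    def ok(self) -> bool:
        return not self.errors

    def add(self, severity, path, code, message):
        self.findings.append(ValidationFinding(severity, path, code, message))


def validate_refs(root: SemNode, dicts: list[Dictionary]) -> ValidationReport:
    """Check every dictRef in a document against the dictionaries.

    Unresolved terms are warnings (code-specific and temporary prefixes are
    expected to float); a node whose *explicit* dataType disagrees with its
    entry's declared dataType is an error.  A node without a dataType is not
    a mismatch — the dictionary supplies the type.
    """
    report = ValidationReport()

    def walk(node: SemNode, path: str):
        p = f"{path}/{node.kind}" + (f"[@id='{node.id}']" if node.id else "")
        if node.dictRef:
            try:
                entry = resolve(node.dictRef, dicts)
            except UnresolvedPrefixError as exc:
                report.add("warning", p, "unresolved-prefix", str(exc))
            except UnresolvedTermError as exc:
                report.add("warning", p, "unresolved-term", str(exc))
            else:
                if (node.dataType and entry.dataType
                        and node.dataType != entry.dataType):
                    report.add("error", p, "type-mismatch",
                               f"{node.dictRef}: node dataType {node.dataType} "
                               f"but dictionary declares {entry.dataType}")
        for c in node.children:
            walk(c, p)

    walk(root, "")
    return report
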
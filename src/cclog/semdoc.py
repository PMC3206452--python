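"""Typed semantic document tree and its XML dialect.

The tree mirrors the module/scalar/array/matrix vocabulary that structured
quantum-chemistry documents use: ``module`` elements give the document its
shape, ``scalar``/``array``/``matrix`` carry the individual typed fields, and
``molecule``/``atom``/``bond``/``formula`` carry chemistry.  Reading and
writing are bit-faithful at the level that matters for science: numeric
payloads are kept as their original decimal strings alongside parsed values,
so serialization never changes printed precision.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

from lxml import etree

from . import naming
from .naming import CML_URI, CMLX_URI, refs_equal

__all__ = [
    "SemNode", "MoleculeView", "DocumentError", "IntegrityError",
    "NotFoundError", "AmbiguityError", "read_document", "write_document",
    "find_nodes", "extract_scalar", "find_scalars", "structurally_equal",
    "first_difference",
]


class DocumentError(Exception):
    """Base class for document reading/writing problems."""


class IntegrityError(DocumentError):
    """A node violates a structural invariant (e.g. size vs payload length)."""


class NotFoundError(DocumentError):
    pass


class AmbiguityError(DocumentError):
    pass


# Elements of the dialect that become typed nodes.  Everything else is
# preserved opaquely so unknown content survives a round trip.
KNOWN_KINDS = {
    "module", "list", "parameterList", "parameter", "propertyList",
    "property", "scalar", "array", "matrix", "table", "molecule",
    "atomArray", "atom", "bondArray", "bond", "formula", "comment",
}

_LEAF_KINDS = {"scalar", "array", "matrix", "comment"}

_DATATYPES = {"xsd:string", "xsd:integer", "xsd:double", "xsd:date"}


def _parse_double(tok: str) -> float:
    # Fortran-style exponents (1.0D-05) are accepted and normalized.
    return float(tok.replace("D", "E").replace("d", "e"))


@dataclass
class SemNode:
    """One node of the semantic document tree.

    ``value`` holds the literal payload: a string for scalars and comments, a
    list of token strings for arrays and matrices, raw XML text for opaque
    nodes.  Typed access goes through :meth:`typed_value` / :meth:`typed_values`.
    """

    kind: str
    id: str | None = None
    dictRef: str | None = None
    units: str | None = None
    dataType: str | None = None
    role: str | None = None            # the temporary cmlx:temp label
    templateRef: str | None = None
    convention: str | None = None
    delimiter: str | None = None
    size: int | None = None
    rows: int | None = None
    columns: int | None = None
    children: list["SemNode"] = field(default_factory=list)
    value: object = None
    extra: dict = field(default_factory=dict)

    # -- construction -----------------------------------------------------
    def append(self, child: "SemNode") -> "SemNode":
        self.children.append(child)
        return child

    # -- traversal --------------------------------------------------------
    def iter(self):
        """Pre-order (document order) traversal including self."""
        yield self
        for c in self.children:
            yield from c.iter()

    def find(self, path):
        return find_nodes(self, path)

    # -- typed payload access ---------------------------------------------
    @property
    def effective_datatype(self) -> str:
        return self.dataType or "xsd:string"

    def typed_value(self):
        """Scalar payload parsed per dataType (absent dataType -> string)."""
        if self.kind != "scalar":
            raise DocumentError(f"typed_value on non-scalar node {self.kind}")
        v = self.value if self.value is not None else ""
        dt = self.effective_datatype
        if dt == "xsd:integer":
            return int(v)
        if dt == "xsd:double":
            return _parse_double(v)
        return v

    def typed_values(self) -> list:
        """Array/matrix payload parsed per dataType."""
        if self.kind not in ("array", "matrix"):
            raise DocumentError(f"typed_values on non-array node {self.kind}")
        toks = list(self.value or [])
        dt = self.effective_datatype
        if dt == "xsd:integer":
            return [int(t) for t in toks]
        if dt == "xsd:double":
            return [_parse_double(t) for t in toks]
        return toks

    # -- invariants --------------------------------------------------------
    def check(self, path="."):
        """Raise IntegrityError on the first violated invariant below self."""
        mypath = f"{path}/{self.kind}" + (f"[@id='{self.id}']" if self.id else "")
        if self.kind == "scalar":
            if self.children:
                raise IntegrityError(f"{mypath}: scalar must not have children")
        if self.kind == "array":
            n = len(self.value or [])
            if self.size is not None and self.size != n:
                raise IntegrityError(
                    f"{mypath}: declared size {self.size} != payload length {n}")
        if self.kind == "matrix":
            n = len(self.value or [])
            if self.rows is not None and self.columns is not None \
                    and self.rows * self.columns != n:
                raise IntegrityError(
                    f"{mypath}: {self.rows}x{self.columns} matrix has {n} values")
        if self.dictRef is not None and not naming.is_valid_ref(self.dictRef):
            raise IntegrityError(f"{mypath}: malformed dictRef {self.dictRef!r}")
        for child in self.children:
            child.check(mypath)

    # -- molecule view -----------------------------------------------------
    def molecule(self) -> "MoleculeView":
        if self.kind != "molecule":
            raise DocumentError("molecule() on non-molecule node")
        return MoleculeView(self)


class MoleculeView:
    """Flattened chemistry view of a molecule node (atoms/bonds/formulas)."""

    def __init__(self, node: SemNode):
        self.node = node
        self.atoms: list[SemNode] = []
        self.bonds: list[SemNode] = []
        self.formulas: list[SemNode] = []
        for child in node.children:
            if child.kind == "atomArray":
                self.atoms.extend(c for c in child.children if c.kind == "atom")
            elif child.kind == "bondArray":
                self.bonds.extend(c for c in child.children if c.kind == "bond")
            elif child.kind == "formula":
                self.formulas.append(child)

    def check(self):
        """Molecule invariants: unique atom ids, bonds reference atoms,
        concise formula is element/count pairs."""
        ids = [a.id for a in self.atoms]
        if len(ids) != len(set(ids)):
            raise IntegrityError(f"molecule {self.node.id}: duplicate atom ids")
        idset = set(ids)
        for b in self.bonds:
            refs = (b.extra.get("atomRefs2") or "").split()
            if len(refs) != 2 or any(r not in idset for r in refs):
                raise IntegrityError(
                    f"molecule {self.node.id}: bond {b.id} references unknown atom")
        for f in self.formulas:
            concise = f.extra.get("concise")
            if concise is not None:
                toks = concise.split()
                if len(toks) % 2 != 0:
                    raise IntegrityError(
                        f"molecule {self.node.id}: malformed concise formula {concise!r}")
                for cnt in toks[1::2]:
                    try:
                        float(cnt)
                    except ValueError:
                        raise IntegrityError(
                            f"molecule {self.node.id}: malformed concise formula {concise!r}")

    def coords(self) -> list[tuple[str, float, float, float]]:
        out = []
        for a in self.atoms:
            out.append((a.extra.get("elementType", ""),
                        _parse_double(a.extra.get("x3", "0")),
                        _parse_double(a.extra.get("y3", "0")),
                        _parse_double(a.extra.get("z3", "0"))))
        return out


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------

_CORE_ATTRS = {
    "id", "dictRef", "units", "dataType", "convention", "delimiter",
}
_INT_ATTRS = {"size", "rows", "columns"}


def _localname(tag: str) -> str:
    return tag.rsplit("}", 1)[-1] if "}" in tag else tag


def read_document(text: str | bytes) -> SemNode:
    """Parse XML-dialect text into a SemNode tree.

    Unknown elements are preserved as opaque nodes; numeric payloads are
    parsed per dataType (and re-serialized from their literal strings so no
    precision is lost).  Malformed XML raises with line/column; a size
    attribute conflicting with the payload length raises IntegrityError.
    """
    if isinstance(text, str):
        text = text.encode("utf-8")
    try:
        root = etree.fromstring(text)
    except etree.XMLSyntaxError as exc:
        raise DocumentError(f"malformed XML: {exc}") from exc
    return _read_element(root, ".")


def _read_element(el, path) -> SemNode:
    kind = _localname(el.tag)
    if kind not in KNOWN_KINDS:
        raw = etree.tostring(el, encoding="unicode")
        return SemNode(kind="opaque", value=raw, extra={"tag": kind})

    node = SemNode(kind=kind)
    mypath = f"{path}/{kind}"
    for name, val in el.attrib.items():
        local = _localname(name)
        if local in _CORE_ATTRS:
            setattr(node, local, val)
        elif local in _INT_ATTRS:
            try:
                setattr(node, local, int(val))
            except ValueError:
                raise IntegrityError(f"{mypath}: non-integer {local}={val!r}")
        elif local == "templateRef":
            node.templateRef = val
        elif local == "temp":
            node.role = val
        else:
            node.extra[local] = val
    if node.id:
        mypath += f"[@id='{node.id}']"

    if kind in ("scalar", "comment"):
        if kind == "scalar":
            node.value = (el.text or "").strip()
            for sub in el:
                if isinstance(sub.tag, str):
                    raise IntegrityError(f"{mypath}: scalar must not have children")
            _check_typed(node, mypath)
        else:  # comments keep raw text
            node.value = (el.text or "").strip("\n")
    elif kind in ("array", "matrix"):
        text = el.text or ""
        for sub in el:  # mixed content is not expected in leaves
            text += (sub.tail or "")
        node.value = _split_payload(text, node.delimiter)
        if kind == "array" and node.size is not None and node.size != len(node.value):
            raise IntegrityError(
                f"{mypath}: size {node.size} != payload length {len(node.value)}")
        if kind == "matrix" and node.rows is not None and node.columns is not None \
                and node.rows * node.columns != len(node.value):
            raise IntegrityError(
                f"{mypath}: {node.rows}x{node.columns} != {len(node.value)} values")
        _check_typed(node, mypath)
    else:
        for sub in el:
            if isinstance(sub.tag, str):  # skip XML comments/PIs
                node.append(_read_element(sub, mypath))
    return node


def _split_payload(text: str, delimiter: str | None) -> list[str]:
    if delimiter is None or delimiter.strip() == "":
        return text.split()
    toks = [t.strip() for t in text.strip().split(delimiter)]
    # enclosing delimiters produce empty leading/trailing fields: drop them
    while toks and toks[0] == "":
        toks.pop(0)
    while toks and toks[-1] == "":
        toks.pop()
    return toks


def _check_typed(node: SemNode, path: str):
    try:
        node.typed_values() if node.kind in ("array", "matrix") else node.typed_value()
    except (ValueError, TypeError) as exc:
        raise IntegrityError(f"{path}: payload does not parse as "
                             f"{node.effective_datatype}: {exc}")


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

_WRITE_NSMAP = {
    None: CML_URI,
    "cmlx": CMLX_URI,
    "cc": naming.PREFIX_URIS["cc"],
    "g": naming.PREFIX_URIS["g"],
    "x": naming.PREFIX_URIS["x"],
    "nonsi": naming.PREFIX_URIS["nonsi"],
    "u": naming.PREFIX_URIS["u"],
    "xsd": naming.PREFIX_URIS["xsd"],
    "convention": naming.PREFIX_URIS["convention"],
}


def write_document(root: SemNode) -> str:
    """Serialize a SemNode tree; inverse of read_document up to layout.

    Invariants are checked before any output is produced.
    """
    root.check()
    el = _write_element(root, nsmap=_WRITE_NSMAP)
    etree.indent(el, space="  ")
    return etree.tostring(el, encoding="unicode", pretty_print=False)


def _normalize_date(v: str) -> str:
    if v.endswith("Z"):
        return v
    try:
        dt = _dt.datetime.fromisoformat(v)
    except ValueError:
        return v
    return dt.strftime("%Y-%m-%dT%H:%M:%SZ")


def _write_element(node: SemNode, nsmap=None):
    if node.kind == "opaque":
        return etree.fromstring(node.value.encode("utf-8"))
    el = etree.Element(f"{{{CML_URI}}}{node.kind}", nsmap=nsmap)
    if node.id is not None:
        el.set("id", node.id)
    if node.dictRef is not None:
        el.set("dictRef", node.dictRef)
    if node.dataType is not None:
        el.set("dataType", node.dataType)
    if node.units is not None:
        el.set("units", node.units)
    if node.convention is not None:
        el.set("convention", node.convention)
    if node.delimiter is not None:
        el.set("delimiter", node.delimiter)
    if node.size is not None:
        el.set("size", str(node.size))
    if node.rows is not None:
        el.set("rows", str(node.rows))
    if node.columns is not None:
        el.set("columns", str(node.columns))
    if node.templateRef is not None:
        el.set(f"{{{CMLX_URI}}}templateRef", node.templateRef)
    if node.role is not None:
        el.set(f"{{{CMLX_URI}}}temp", node.role)
    for k, v in node.extra.items():
        if k != "tag":
            el.set(k, v)

    if node.kind in ("scalar", "comment"):
        v = node.value if node.value is not None else ""
        if node.kind == "scalar" and node.dataType == "xsd:date":
            v = _normalize_date(v)
        el.text = v
    elif node.kind in ("array", "matrix"):
        toks = list(node.value or [])
        d = node.delimiter
        if d is None or d.strip() == "":
            el.text = " ".join(toks)
        else:
            el.text = d + d.join(toks) + d if toks else ""
    else:
        for child in node.children:
            el.append(_write_element(child))
    return el


# ---------------------------------------------------------------------------
# Search and extraction
# ---------------------------------------------------------------------------

def find_nodes(root: SemNode, path) -> list[SemNode]:
    """Evaluate a restricted path expression; document-ordered matches."""
    from .paths import PathExpr  # local import: paths has no semdoc dependency
    expr = path if isinstance(path, PathExpr) else PathExpr.parse(path)
    return expr.select(root)


def node_path(root: SemNode, target: SemNode) -> str:
    """Slash path of target inside root (for error messages)."""
    def walk(node, acc):
        if node is target:
            return acc
        for i, c in enumerate(node.children):
            r = walk(c, acc + f"/{c.kind}[{i}]")
            if r is not None:
                return r
        return None
    r = walk(root, f"/{root.kind}")
    return r if r is not None else "<not in tree>"


def find_scalars(root: SemNode, ref: str) -> list[SemNode]:
    """All scalars carrying a term, directly or via a parameter/property
    wrapper whose dictRef names the term (the usual document layout)."""
    out = []
    def walk(node):
        for c in node.children:
            if c.kind == "scalar":
                if (c.dictRef and refs_equal(c.dictRef, ref)) or (
                        node.kind in ("parameter", "property")
                        and node.dictRef and refs_equal(node.dictRef, ref)):
                    out.append(c)
            else:
                walk(c)
    walk(root)
    return out


def extract_scalar(root: SemNode, ref: str):
    """(typed value, units) for the unique scalar with a dictRef term."""
    hits = find_scalars(root, ref)
    if not hits:
        raise NotFoundError(f"no scalar with dictRef {ref}")
    if len(hits) > 1:
        paths = ", ".join(node_path(root, h) for h in hits)
        raise AmbiguityError(f"{len(hits)} scalars with dictRef {ref}: {paths}")
    node = hits[0]
    return node.typed_value(), node.units


def find_arrays(root: SemNode, ref: str) -> list[SemNode]:
    out = []
    def walk(node):
        for c in node.children:
            if c.kind == "array":
                if (c.dictRef and refs_equal(c.dictRef, ref)) or (
                        node.kind in ("parameter", "property")
                        and node.dictRef and refs_equal(node.dictRef, ref)):
                    out.append(c)
            else:
                walk(c)
    walk(root)
    return out


# ---------------------------------------------------------------------------
# Structural equality
# ---------------------------------------------------------------------------

def _payload_equal(a: SemNode, b: SemNode) -> bool:
    if a.kind in ("array", "matrix"):
        ta, tb = a.typed_values(), b.typed_values()
        return ta == tb
    if a.kind == "scalar":
        return a.typed_value() == b.typed_value()
    if a.kind in ("comment", "opaque"):
        return (a.value or "").strip() == (b.value or "").strip()
    return True


def first_difference(a: SemNode, b: SemNode, path="/", *, ignore_id=False,
                     ignore_role=False, lenient_template_ref=False) -> str | None:
    """Path of the first structural difference between two trees, or None.

    Numeric payloads compare by parsed value (so 1.0938 == 1.09380); strings
    compare exactly.  dictRef comparison honours the prefix alias table.
    With ``lenient_template_ref`` an absent templateRef in ``b`` matches any
    templateRef in ``a`` (expected trees usually label only the module).
    """
    p = path + a.kind
    if a.kind != b.kind:
        return p + f" (kind {a.kind} vs {b.kind})"
    if (a.dictRef is None) != (b.dictRef is None) or (
            a.dictRef and b.dictRef and not refs_equal(a.dictRef, b.dictRef)):
        return p + f" (dictRef {a.dictRef} vs {b.dictRef})"
    for attr in ("units", "dataType", "templateRef", "delimiter", "size",
                 "rows", "columns", "convention"):
        if attr == "templateRef" and lenient_template_ref and b.templateRef is None:
            continue
        if getattr(a, attr) != getattr(b, attr):
            return p + f" ({attr} {getattr(a, attr)} vs {getattr(b, attr)})"
    if not ignore_id and a.id != b.id:
        return p + f" (id {a.id} vs {b.id})"
    if not ignore_role and a.role != b.role:
        return p + f" (role {a.role!r} vs {b.role!r})"
    if a.extra != b.extra:
        return p + f" (attributes {a.extra} vs {b.extra})"
    if a.kind in ("scalar", "array", "matrix", "comment", "opaque"):
        if not _payload_equal(a, b):
            return p + f" (payload {a.value!r} vs {b.value!r})"
    if len(a.children) != len(b.children):
        return p + f" ({len(a.children)} vs {len(b.children)} children)"
    for i, (ca, cb) in enumerate(zip(a.children, b.children)):
        d = first_difference(ca, cb, p + f"/[{i}]", ignore_id=ignore_id,
                             ignore_role=ignore_role,
                             lenient_template_ref=lenient_template_ref)
        if d:
            return d
    return None


def structurally_equal(a: SemNode, b: SemNode, **kw) -> bool:
    return first_difference(a, b, **kw) is None
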
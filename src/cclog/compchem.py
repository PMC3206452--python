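"""The compchem convention: jobList -> job -> environment / initialization /
calculation / finalization.

A raw parse is a flat sequence of chunk modules in source order.  Rule-driven
restructuring groups them into jobs (a new job begins at each program-restart
marker), assigns each chunk to one of the four role modules, wraps loose
fields in parameter/property elements, builds molecules from coordinate
tables, and collects anything unassignable under a per-job
``cc:userDefinedModule`` with a warning — content is conserved, never lost.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .dictionary import ValidationReport
from .semdoc import SemNode, MoleculeView, IntegrityError

log = logging.getLogger("cclog")

__all__ = ["RestructureRules", "restructure", "validate_convention",
           "iter_jobs", "job_role"]

ROLES = ("environment", "initialization", "calculation", "finalization")

#: atomic number -> element symbol, enough for organic/main-group logs
ELEMENTS = {
    1: "H", 2: "He", 3: "Li", 4: "Be", 5: "B", 6: "C", 7: "N", 8: "O",
    9: "F", 10: "Ne", 11: "Na", 12: "Mg", 13: "Al", 14: "Si", 15: "P",
    16: "S", 17: "Cl", 18: "Ar", 19: "K", 20: "Ca", 26: "Fe", 29: "Cu",
    30: "Zn", 35: "Br", 53: "I",
}


@dataclass
class RestructureRules:
    """Mapping from template ids to convention roles.

    ``job_start``: template ids that mark the beginning of a new job.
    ``role_map``: template id -> one of the four role names.  ``molecule``:
    template ids whose chunk is a coordinate table to convert into a
    molecule (placed in initialization).  ``drop``: marker templates whose
    chunks carry no payload and are discarded.
    """
    job_start: set[str] = field(default_factory=set)
    role_map: dict[str, str] = field(default_factory=dict)
    molecule: set[str] = field(default_factory=set)
    drop: set[str] = field(default_factory=set)

    @classmethod
    def from_text(cls, text: str) -> "RestructureRules":
        """Flat key=value format: lines ``templateId=role`` where role is one
        of the four roles, ``jobstart``, ``molecule`` or ``drop``."""
        rules = cls()
        for raw in text.splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if val == "jobstart":
                rules.job_start.add(key)
            elif val == "molecule":
                rules.molecule.add(key)
            elif val == "drop":
                rules.drop.add(key)
            elif val in ROLES:
                rules.role_map[key] = val
            else:
                raise ValueError(f"unknown role {val!r} for template {key!r}")
        return rules


def _has_payload(module: SemNode) -> bool:
    return any(n.kind in ("scalar", "array", "matrix")
               for n in module.iter())


def _wrap_fields(module: SemNode, wrapper_kind: str, list_kind: str) -> list[SemNode]:
    """Lift a chunk module's leaf fields into parameter/property wrappers
    under a parameterList/propertyList, preserving order."""
    lst = SemNode(kind=list_kind)
    for child in module.children:
        if child.kind in ("scalar", "array"):
            w = SemNode(kind=wrapper_kind, dictRef=child.dictRef)
            w.append(child)
            lst.append(w)
        elif child.kind == "comment":
            continue  # unparsed residue lives in the sidecar, not the document
        else:
            lst.append(child)
    return [lst] if lst.children else []


def _build_molecule(module: SemNode, mol_id: str) -> SemNode | None:
    """Turn an orientation-table chunk (serial / atomic-number / xyz rows)
    into a molecule with atoms and a concise formula."""
    rows = []
    serial = atnum = None
    for n in module.children:
        if n.kind == "scalar" and n.role and n.role.endswith("serial"):
            serial = int(n.value)
        elif n.kind == "scalar" and n.role and n.role.endswith("atomicnumber"):
            atnum = int(n.value)
        elif n.kind == "array" and n.role and n.role.endswith("xyz"):
            if atnum is not None:
                rows.append((serial, atnum, list(n.value)))
            serial = atnum = None
    if not rows:
        return None
    mol = SemNode(kind="molecule", id=mol_id)
    atoms = SemNode(kind="atomArray")
    counts: dict[str, int] = {}
    for i, (ser, z, xyz) in enumerate(rows, start=1):
        sym = ELEMENTS.get(z, f"Z{z}")
        counts[sym] = counts.get(sym, 0) + 1
        atoms.append(SemNode(kind="atom", id=f"a{ser if ser else i}",
                             extra={"elementType": sym, "x3": xyz[0],
                                    "y3": xyz[1], "z3": xyz[2]}))
    mol.append(atoms)
    concise = " ".join(f"{s} {c}" for s, c in counts.items())
    mol.append(SemNode(kind="formula", extra={"concise": concise,
                                              "formalCharge": "0"}))
    return mol


def restructure(raw: SemNode, rules: RestructureRules) -> SemNode:
    """Raw chunk-ordered tree -> compchem document.

    The output root is a convention module holding one ``cc:jobList`` of
    ``cc:job`` modules.  Leftover chunks go under a per-job
    ``cc:userDefinedModule`` with a warning; every payload in the raw tree
    appears exactly once in the output.
    """
    root = SemNode(kind="module", convention="convention:compchem")
    joblist = root.append(SemNode(kind="module", id="jobList1",
                                  dictRef="cc:jobList"))

    # split chunk modules into jobs at the job-start markers
    jobs_chunks: list[list[SemNode]] = []
    current: list[SemNode] = []
    for module in raw.children:
        tid = module.templateRef or ""
        if tid in rules.job_start:
            if current:
                jobs_chunks.append(current)
            current = []
            if _has_payload(module):
                current.append(module)
            continue
        current.append(module)
    if current or not jobs_chunks:
        jobs_chunks.append(current)

    for jobno, chunk_modules in enumerate(jobs_chunks, start=1):
        job = joblist.append(SemNode(kind="module", id=f"job{jobno}",
                                     dictRef="cc:job"))
        by_role: dict[str, list[SemNode]] = {r: [] for r in ROLES}
        molecules: list[SemNode] = []
        leftovers: list[SemNode] = []
        for module in chunk_modules:
            tid = module.templateRef or ""
            if tid in rules.drop and not _has_payload(module):
                continue
            if tid in rules.molecule:
                mol = _build_molecule(module, f"mol.{tid}")
                if mol is not None:
                    molecules.append(mol)
                    continue
            role = rules.role_map.get(tid)
            if role is None:
                leftovers.append(module)
                log.warning("job %d: chunk %r has no role; kept under "
                            "cc:userDefinedModule", jobno, tid)
            else:
                by_role[role].append(module)

        for role in ROLES:
            mods = by_role[role]
            if not mods and not (role == "initialization" and molecules):
                continue
            rm = job.append(SemNode(kind="module", id=role,
                                    dictRef=f"cc:{role}"))
            if role in ("environment", "initialization"):
                fields = []
                for m in mods:
                    fields.extend(_wrap_fields(m, "parameter", "parameterList"))
                # merge the parameterLists of the role's chunks into one
                merged = SemNode(kind="parameterList")
                for lst in fields:
                    merged.children.extend(lst.children)
                if merged.children:
                    rm.append(merged)
                if role == "initialization":
                    for mol in molecules:
                        rm.append(mol)
            elif role == "finalization":
                merged = SemNode(kind="propertyList")
                for m in mods:
                    for lst in _wrap_fields(m, "property", "propertyList"):
                        merged.children.extend(lst.children)
                if merged.children:
                    rm.append(merged)
            else:  # calculation: keep chunk modules as-is
                for m in mods:
                    rm.append(m)
        if leftovers:
            udm = job.append(SemNode(kind="module", id="otherComponents",
                                     dictRef="cc:userDefinedModule"))
            for m in leftovers:
                udm.append(m)
    return root


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def _is_role(node: SemNode, role: str) -> bool:
    return node.kind == "module" and node.dictRef is not None and \
        node.dictRef.split(":", 1)[-1] == role


def _find_joblist(doc: SemNode) -> SemNode | None:
    if _is_role(doc, "jobList"):
        return doc
    for c in doc.children:
        if _is_role(c, "jobList"):
            return c
    return None


def iter_jobs(doc: SemNode) -> list[SemNode]:
    jl = _find_joblist(doc)
    if jl is None:
        return []
    return [c for c in jl.children if _is_role(c, "job")]


def job_role(job: SemNode, role: str) -> SemNode | None:
    for c in job.children:
        if _is_role(c, role):
            return c
    return None


def validate_convention(doc: SemNode) -> ValidationReport:
    """Check conformance with the jobList/job/role structure.

    Errors: missing jobList, no jobs, duplicate role modules, missing
    initialization or finalization, broken molecules.  Warnings: misplaced
    parameters/properties, final molecule without formula.
    """
    report = ValidationReport()
    jl = _find_joblist(doc)
    if jl is None:
        report.add("error", "/", "no-joblist",
                   "document has no cc:jobList module at or under the root")
        return report
    jobs = [c for c in jl.children if _is_role(c, "job")]
    if not jobs:
        report.add("error", "/jobList", "no-jobs", "jobList contains no cc:job")
    for c in jl.children:
        if not _is_role(c, "job"):
            report.add("warning", "/jobList", "unexpected-child",
                       f"non-job child {c.kind} ({c.dictRef}) in jobList")

    for jn, job in enumerate(jobs, start=1):
        jpath = f"/jobList/job[{jn}]"
        for role in ROLES:
            count = sum(1 for c in job.children if _is_role(c, role))
            if count > 1:
                report.add("error", jpath, "duplicate-role",
                           f"{count} {role} modules in one job")
        for role in ("initialization", "finalization"):
            if job_role(job, role) is None:
                report.add("error", jpath, f"missing-{role}",
                           f"job has no {role} module")

        init = job_role(job, "initialization")
        if init is not None:
            for n in init.iter():
                if n.kind == "property":
                    report.add("warning", jpath + "/initialization",
                               "misplaced-property",
                               "property inside initialization")
        fin = job_role(job, "finalization")
        if fin is not None:
            for n in fin.iter():
                if n.kind == "parameter":
                    report.add("warning", jpath + "/finalization",
                               "misplaced-parameter",
                               "parameter inside finalization")
        # parameters must live under a parameterList
        def check_wrapping(node, inside_plist, inside_proplist, path):
            for c in node.children:
                if c.kind == "parameter" and not inside_plist:
                    report.add("warning", path, "misplaced-parameter",
                               "parameter outside parameterList")
                if c.kind == "property" and not inside_proplist:
                    report.add("warning", path, "misplaced-property",
                               "property outside propertyList")
                check_wrapping(c, inside_plist or c.kind == "parameterList",
                               inside_proplist or c.kind == "propertyList",
                               path + "/" + c.kind)
        check_wrapping(job, False, False, jpath)

        for n in job.iter():
            if n.kind == "molecule":
                try:
                    MoleculeView(n).check()
                except IntegrityError as exc:
                    report.add("error", jpath, "bad-molecule", str(exc))
        if fin is not None:
            for n in fin.iter():
                if n.kind == "molecule" and not MoleculeView(n).formulas:
                    report.add("warning", jpath + "/finalization",
                               "missing-formula",
                               "final molecule carries no formula")
    return report
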
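"""Desk-scale index of converted calculations.

Each ingested job becomes one entry summarizing the four convention
criteria: environment (program), initialization (formula, method, basis,
atom count), calculation, and finalization (numeric properties with units).
The store is a single embedded SQLite file; entries are searchable by field
equality and numeric property ranges, and exportable as N-Triples-style
lines.  Identical documents may be ingested repeatedly — deliberately, no
duplicate check is made — each ingest yields a fresh entry id.
"""

from __future__ import annotations

import hashlib
import json
import sqlite3
from dataclasses import dataclass, field

from .compchem import iter_jobs, job_role, validate_convention
from .dictionary import Dictionary, load_compchem_dictionary, resolve, DictionaryError
from .semdoc import SemNode, write_document, find_scalars

__all__ = ["EntryRecord", "Triple", "IndexStore", "StoreError", "QueryError",
           "UnitConversionError"]


class StoreError(Exception):
    pass


class QueryError(StoreError):
    pass


class UnitConversionError(QueryError):
    pass


#: units attribute -> (canonical unit, multiplicative factor).
#: Energies canonicalize to hartree (1 Eh = 2625499.62 J/mol).
UNIT_CONVERSIONS = {
    "nonsi:hartree": ("hartree", 1.0),
    "u:hartree": ("hartree", 1.0),
    "u:jmol-1": ("hartree", 1.0 / 2625499.62),
    "u:kjmol-1": ("hartree", 1.0 / 2625.49962),
    "u:ev": ("hartree", 1.0 / 27.211386),
    "nonsi:debye": ("debye", 1.0),
    "nonsi:cm-1": ("cm-1", 1.0),
    "u:cm-1": ("cm-1", 1.0),
}

_FIELDS = ("entry_id", "source_path", "formula_concise", "program", "method",
           "basis", "natoms", "created")


@dataclass
class EntryRecord:
    entry_id: str
    source_path: str = ""
    formula_concise: str | None = None
    program: str | None = None
    method: str | None = None
    basis: str | None = None
    natoms: int | None = None
    properties: dict[str, tuple[float, str | None]] = field(default_factory=dict)
    created: int = 0


@dataclass(frozen=True)
class Triple:
    subject: str
    predicate: str
    object: object

    def nt(self) -> str:
        obj = self.object
        if isinstance(obj, float):
            lit = f'"{obj!r}"^^xsd:double'
        elif isinstance(obj, int):
            lit = f'"{obj}"^^xsd:integer'
        else:
            lit = json.dumps(str(obj))
        return f"<entry:{self.subject}> <{self.predicate}> {lit} ."


def _first_scalar(node: SemNode | None, ref: str):
    if node is None:
        return None
    hits = find_scalars(node, ref)
    return hits[0].typed_value() if hits else None


class IndexStore:
    """Embedded single-file store of EntryRecords."""

    def __init__(self, path: str = ":memory:",
                 dictionaries: list[Dictionary] | None = None):
        self.conn = sqlite3.connect(path)
        self.dicts = dictionaries if dictionaries is not None \
            else [load_compchem_dictionary()]
        self.conn.executescript("""
            CREATE TABLE IF NOT EXISTS entries (
                entry_id TEXT PRIMARY KEY,
                source_path TEXT, formula_concise TEXT, program TEXT,
                method TEXT, basis TEXT, natoms INTEGER, created INTEGER
            );
            CREATE TABLE IF NOT EXISTS properties (
                entry_id TEXT, term TEXT, value REAL, units TEXT,
                canonical REAL, canonical_unit TEXT
            );
        """)

    def close(self):
        self.conn.close()

    # -- ingest -----------------------------------------------------------
    def ingest(self, doc: SemNode, source_path: str = "") -> list[EntryRecord]:
        """One EntryRecord per job; rejects convention-invalid documents."""
        report = validate_convention(doc)
        if not report.ok:
            msgs = "; ".join(f.code for f in report.errors)
            raise StoreError(f"document failed convention validation: {msgs}")
        records = []
        for job in iter_jobs(doc):
            records.append(self._ingest_job(job, source_path))
        self.conn.commit()
        return records

    def _ingest_job(self, job: SemNode, source_path: str) -> EntryRecord:
        n = self.conn.execute("SELECT COUNT(*) FROM entries").fetchone()[0]
        digest = hashlib.sha256(
            write_document(job).encode("utf-8")).hexdigest()[:12]
        entry_id = f"{n + 1:06d}-{digest}"

        env = job_role(job, "environment")
        init = job_role(job, "initialization")
        fin = job_role(job, "finalization")

        formula = None
        for scope in (init, fin):
            if scope is None:
                continue
            for node in scope.iter():
                if node.kind == "formula" and node.extra.get("concise"):
                    formula = node.extra["concise"]
                    break
            if formula:
                break

        rec = EntryRecord(
            entry_id=entry_id,
            source_path=source_path,
            formula_concise=formula,
            program=_first_scalar(env, "cc:program"),
            method=_first_scalar(init, "cc:method"),
            basis=_first_scalar(init, "cc:basis"),
            natoms=_first_scalar(init, "cc:natoms"),
            created=n + 1,
        )
        if fin is not None:
            for node in fin.iter():
                if node.kind != "scalar" or node.dataType != "xsd:double":
                    continue
                term = node.dictRef
                if term is None:
                    continue
                try:
                    resolve(term, self.dicts)
                except DictionaryError:
                    continue
                if term not in rec.properties:
                    rec.properties[term] = (node.typed_value(), node.units)
            # wrapped properties: dictRef on the property element
            for node in fin.iter():
                if node.kind != "property" or node.dictRef is None:
                    continue
                try:
                    resolve(node.dictRef, self.dicts)
                except DictionaryError:
                    continue
                for c in node.children:
                    if c.kind == "scalar" and c.dataType == "xsd:double" \
                            and node.dictRef not in rec.properties:
                        rec.properties[node.dictRef] = (c.typed_value(), c.units)

        self.conn.execute(
            "INSERT INTO entries VALUES (?,?,?,?,?,?,?,?)",
            (rec.entry_id, rec.source_path, rec.formula_concise, rec.program,
             rec.method, rec.basis, rec.natoms, rec.created))
        for term, (value, units) in rec.properties.items():
            canon, cunit = self._canonicalize(value, units)
            self.conn.execute(
                "INSERT INTO properties VALUES (?,?,?,?,?,?)",
                (rec.entry_id, term, value, units, canon, cunit))
        return rec

    @staticmethod
    def _canonicalize(value: float, units: str | None):
        if units is None:
            return value, None
        if units in UNIT_CONVERSIONS:
            cunit, factor = UNIT_CONVERSIONS[units]
            return value * factor, cunit
        return None, None

    # -- query ------------------------------------------------------------
    def query(self, **criteria) -> list[EntryRecord]:
        """Conjunctive search: field=value for string/int fields, term=(lo,
        hi) ranges for numeric properties in canonical units."""
        wheres, params, joins = [], [], 0
        sql = "SELECT e.entry_id FROM entries e"
        for key, val in criteria.items():
            if ":" in key:
                if not (isinstance(val, (tuple, list)) and len(val) == 2):
                    raise QueryError(f"range criterion {key} needs (lo, hi)")
                bad = self.conn.execute(
                    "SELECT COUNT(*) FROM properties WHERE term=? AND "
                    "canonical IS NULL", (key,)).fetchone()[0]
                if bad:
                    raise UnitConversionError(
                        f"{bad} stored {key} values have units outside the "
                        f"conversion table; range query is not meaningful")
                joins += 1
                alias = f"p{joins}"
                sql += (f" JOIN properties {alias} ON "
                        f"{alias}.entry_id = e.entry_id")
                wheres.append(f"{alias}.term=? AND {alias}.canonical "
                              f"BETWEEN ? AND ?")
                params.extend([key, float(val[0]), float(val[1])])
            else:
                col = {"formula": "formula_concise",
                       "formula_concise": "formula_concise",
                       "program": "program", "method": "method",
                       "basis": "basis", "natoms": "natoms",
                       "source_path": "source_path",
                       "entry_id": "entry_id"}.get(key)
                if col is None:
                    raise QueryError(f"unknown field {key!r}")
                wheres.append(f"e.{col}=?")
                params.append(val)
        if wheres:
            sql += " WHERE " + " AND ".join(wheres)
        sql += " ORDER BY e.created, e.entry_id"
        ids = [r[0] for r in self.conn.execute(sql, params)]
        return [self.get(i) for i in ids]

    def get(self, entry_id: str) -> EntryRecord:
        row = self.conn.execute(
            "SELECT * FROM entries WHERE entry_id=?", (entry_id,)).fetchone()
        if row is None:
            raise StoreError(f"no entry {entry_id!r}")
        rec = EntryRecord(entry_id=row[0], source_path=row[1],
                          formula_concise=row[2], program=row[3],
                          method=row[4], basis=row[5], natoms=row[6],
                          created=row[7])
        for term, value, units in self.conn.execute(
                "SELECT term, value, units FROM properties WHERE entry_id=? "
                "ORDER BY term", (entry_id,)):
            rec.properties[term] = (value, units)
        return rec

    # -- triples ----------------------------------------------------------
    def export_triples(self, entry_id: str) -> list[Triple]:
        """Deterministic sorted triples covering every indexed field."""
        rec = self.get(entry_id)
        triples = [Triple(entry_id, "cclog:created", rec.created)]
        if rec.source_path:
            triples.append(Triple(entry_id, "cclog:source", rec.source_path))
        for pred, val in (("cc:formula", rec.formula_concise),
                          ("cc:program", rec.program),
                          ("cc:method", rec.method),
                          ("cc:basis", rec.basis),
                          ("cc:natoms", rec.natoms)):
            if val is not None:
                triples.append(Triple(entry_id, pred, val))
        for term, (value, units) in sorted(rec.properties.items()):
            triples.append(Triple(entry_id, term, value))
            if units:
                triples.append(Triple(entry_id, f"{term}#units", units))
        return sorted(triples, key=lambda t: (t.predicate, str(t.object)))

    @staticmethod
    def record_from_triples(triples: list[Triple]) -> EntryRecord:
        """Reconstruct an EntryRecord from its exported triples."""
        if not triples:
            raise StoreError("no triples given")
        rec = EntryRecord(entry_id=triples[0].subject)
        units_map = {}
        for t in triples:
            if t.subject != rec.entry_id:
                raise StoreError("triples span multiple subjects")
            if t.predicate == "cclog:created":
                rec.created = int(t.object)
            elif t.predicate == "cclog:source":
                rec.source_path = str(t.object)
            elif t.predicate == "cc:formula":
                rec.formula_concise = str(t.object)
            elif t.predicate == "cc:program":
                rec.program = str(t.object)
            elif t.predicate == "cc:method":
                rec.method = str(t.object)
            elif t.predicate == "cc:basis":
                rec.basis = str(t.object)
            elif t.predicate == "cc:natoms":
                rec.natoms = int(t.object)
            elif t.predicate.endswith("#units"):
                units_map[t.predicate[:-6]] = str(t.object)
            else:
                rec.properties[t.predicate] = (float(t.object), None)
        for term, units in units_map.items():
            if term in rec.properties:
                rec.properties[term] = (rec.properties[term][0], units)
        return rec
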
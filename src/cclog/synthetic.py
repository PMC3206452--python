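"""Deterministic generator of Gaussian-style logfiles with ground truth.

The generator emulates the *shape* of a Gaussian log — route line, charge/
multiplicity, orientation table, basis summary, SCF energy, orbital
eigenvalue blocks wrapped five per line, frequency/thermochemistry sections,
chained jobs — with numeric values drawn from seeded ranges plausible for
each term.  No quantum chemistry is computed: the point is to test parsing
fidelity against a machine-readable ground truth, not physics.  A mutator
injects the irregularities real logs suffer from (truncation, error
messages, whitespace drift, duplicated blocks).
"""

from __future__ import annotations

import random
import re
from dataclasses import dataclass, field

from .semdoc import SemNode, find_scalars, find_arrays
from .compchem import iter_jobs

__all__ = ["LogSpec", "GroundTruth", "SpecError", "MOLECULES",
           "generate_logfile", "mutate_logfile", "recovery_score",
           "random_logspec"]


class SpecError(ValueError):
    pass


#: tiny molecule library: name -> list of (element, Z, mass, x, y, z [Angstrom])
MOLECULES = {
    "CH4": [("C", 6, 12.011, 0.0, 0.0, 0.0),
            ("H", 1, 1.008, 0.0, 0.0, 1.113),
            ("H", 1, 1.008, 1.049347, 0.0, -0.371),
            ("H", 1, 1.008, -0.524673, -0.908761, -0.371),
            ("H", 1, 1.008, -0.524673, 0.908761, -0.371)],
    "H2O": [("O", 8, 15.999, 0.0, 0.0, 0.117),
            ("H", 1, 1.008, 0.0, 0.757, -0.469),
            ("H", 1, 1.008, 0.0, -0.757, -0.469)],
    "NH3": [("N", 7, 14.007, 0.0, 0.0, 0.116),
            ("H", 1, 1.008, 0.0, 0.939, -0.27),
            ("H", 1, 1.008, 0.813, -0.469, -0.27),
            ("H", 1, 1.008, -0.813, -0.469, -0.27)],
    "CO2": [("C", 6, 12.011, 0.0, 0.0, 0.0),
            ("O", 8, 15.999, 0.0, 0.0, 1.16),
            ("O", 8, 15.999, 0.0, 0.0, -1.16)],
}

_METHODS = ["RB3LYP", "RHF", "RMP2", "RPBE1PBE"]
_BASES = ["6-31G(d)", "6-311+G(d,p)", "STO-3G", "cc-pVDZ"]
_POINTGROUPS = ["C1", "CS", "C2V", "C3V", "TD", "D*H"]


@dataclass
class LogSpec:
    """Conditions for one synthetic logfile."""
    molecule: list[tuple]                  # (element, Z, mass, x, y, z)
    charge: int = 0
    multiplicity: int = 1
    method: str = "RB3LYP"
    basis: str = "6-31G(d)"
    jobs: list[str] = field(default_factory=lambda: ["opt"])
    n_occ: int = 5
    n_virt: int = 18
    seed: int = 42

    def validate(self):
        if self.multiplicity < 1:
            raise SpecError(f"multiplicity must be >= 1, got {self.multiplicity}")
        if self.n_occ < 0 or self.n_virt < 0:
            raise SpecError("orbital counts must be >= 0")
        if not self.molecule:
            raise SpecError("molecule must have at least one atom")
        for job in self.jobs:
            if job not in ("opt", "freq", "sp"):
                raise SpecError(f"unknown job kind {job!r}")
        if not self.jobs:
            raise SpecError("at least one job required")


@dataclass
class GroundTruth:
    """Expected values per job, keyed by dictionary term.

    Scalar terms map to a typed value; array terms map to a list of floats.
    """
    jobs: list[dict] = field(default_factory=list)

    def to_text(self) -> str:
        lines = []
        for i, job in enumerate(self.jobs, start=1):
            for key, val in job.items():
                lines.append(f"job{i}.{key}={val!r}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "GroundTruth":
        import ast
        jobs: dict[int, dict] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            head, _, sval = line.partition("=")
            jobtag, _, key = head.partition(".")
            jobs.setdefault(int(jobtag[3:]), {})[key] = ast.literal_eval(sval)
        return cls([jobs[k] for k in sorted(jobs)])


def _wrap(prefix: str, values, per_line: int, fmt: str) -> list[str]:
    """Wrap values N per line exactly as FORTRAN format routines do."""
    lines = []
    for i in range(0, len(values), per_line):
        chunk = values[i:i + per_line]
        lines.append(prefix + "".join(fmt % v for v in chunk))
    return lines


def generate_logfile(spec: LogSpec) -> tuple[str, GroundTruth]:
    """Deterministic logfile text plus its ground truth."""
    spec.validate()
    rng = random.Random(spec.seed)
    lines: list[str] = []
    truth = GroundTruth()

    natoms = len(spec.molecule)
    nelec = sum(z for _, z, *_ in spec.molecule) - spec.charge
    alphae = (nelec + spec.multiplicity - 1) // 2
    betae = nelec - alphae
    molmass = sum(m for _, _, m, *_ in spec.molecule)
    counts: dict[str, int] = {}
    for el, *_ in spec.molecule:
        counts[el] = counts.get(el, 0) + 1
    formula = " ".join(f"{el} {n}" for el, n in counts.items())
    pointgroup = rng.choice(_POINTGROUPS)
    basiscount = rng.randint(2 * natoms, 40 * natoms)
    primbasis = basiscount + rng.randint(0, 3 * basiscount)

    for jobno, jobkind in enumerate(spec.jobs, start=1):
        job: dict = {}
        lines.append(" Entering Link 1")
        if jobno == 1:
            lines.append(" Gaussian 03:  x86-Linux-G03RevB.04")
        keyword = {"opt": "Opt", "freq": "Freq", "sp": "SP"}[jobkind]
        lines.append(f" #N {spec.method}/{spec.basis} {keyword}")
        job["cc:method"] = spec.method
        job["cc:basis"] = spec.basis
        lines.append(f" Charge = {spec.charge:2d} Multiplicity = {spec.multiplicity}")
        job["cc:formalCharge"] = spec.charge
        job["cc:multiplicity"] = spec.multiplicity
        lines.append(f" NAtoms=  {natoms:4d} NActive=  {natoms:4d}")
        job["cc:natoms"] = natoms
        job["cc:nactiveatoms"] = natoms

        lines.append("                         Standard orientation:")
        sep = " " + "-" * 69
        lines.append(sep)
        lines.append(" Center     Atomic      Atomic             Coordinates (Angstroms)")
        lines.append(" Number     Number       Type             X           Y           Z")
        lines.append(sep)
        jitter = 0.0 if jobkind != "opt" else 0.001
        for i, (el, z, m, x, y, zz) in enumerate(spec.molecule, start=1):
            dx = rng.uniform(-jitter, jitter)
            lines.append(f"  {i:5d}  {z:9d}  {0:10d}    "
                         f"{x + dx:12.6f}{y + dx:12.6f}{zz + dx:12.6f}")
        lines.append(sep)
        job["cc:formula"] = formula

        lines.append(f" Standard basis: {spec.basis} (6D, 7F)")
        job["cc:diffuse"] = "(6D, 7F)"
        lines.append(f"   {basiscount:4d} basis functions,   {primbasis:5d} "
                     f"primitive gaussians,   {basiscount:5d} cartesian basis functions")
        job["cc:basiscount"] = basiscount
        lines.append(f"   {alphae:4d} alpha electrons   {betae:6d} beta electrons")
        job["cc:alphae"] = alphae
        job["cc:betae"] = betae

        symmnumber = rng.choice([1, 2, 3, 4, 6, 12])
        lines.append(f" Full point group         {pointgroup:>8s}   {symmnumber:4d}")
        job["cc:pointgroup"] = pointgroup
        job["cc:symmnumber"] = symmnumber

        nucrep = round(rng.uniform(1.0, 300.0), 10)
        lines.append(f" nuclear repulsion energy    {nucrep:16.10f} Hartrees.")
        job["cc:nucrepener"] = float(f"{nucrep:16.10f}")

        scf = round(rng.uniform(-600.0, -1.0), 7)
        cycles = rng.randint(4, 30)
        lines.append(f" SCF Done:  E({spec.method}) =  {scf:.7f}     "
                     f"A.U. after   {cycles:2d} cycles")
        job["cc:hfenergy"] = float(f"{scf:.7f}")

        occ = sorted(rng.uniform(-12.0, -0.2) for _ in range(spec.n_occ))
        virt = sorted(rng.uniform(0.05, 5.0) for _ in range(spec.n_virt))
        occ = [float(f"{v:.5f}") for v in occ]
        virt = [float(f"{v:.5f}") for v in virt]
        if occ:
            lines.extend(_wrap(" Alpha occ. eigenvalues --", occ, 5, "%11.5f"))
            job["cc:alphaocc"] = occ
        if virt:
            lines.extend(_wrap(" Alpha virt. eigenvalues --", virt, 5, "%11.5f"))
            job["cc:alphavirt"] = virt

        if jobkind == "freq":
            nmodes = max(1, 3 * natoms - 6)
            freqs = sorted(rng.uniform(100.0, 4000.0) for _ in range(nmodes))
            freqs = [float(f"{v:.4f}") for v in freqs]
            irint = [float(f"{rng.uniform(0.0, 120.0):.4f}") for _ in range(nmodes)]
            lines.extend(_wrap(" Frequencies --", freqs, 5, "%12.4f"))
            lines.extend(_wrap(" IR Inten    --", irint, 5, "%12.4f"))
            job["cc:frequency"] = freqs
            job["cc:irintensity"] = irint
            zpe = round(rng.uniform(1.0e4, 5.0e5), 1)
            lines.append(" Temperature   298.150 Kelvin.  Pressure   1.00000 Atm.")
            job["cc:temp"] = 298.150
            job["cc:press"] = 1.00000
            lines.append(f" Molecular mass: {molmass:11.5f} amu.")
            job["cc:molmass"] = float(f"{molmass:11.5f}")
            lines.append(f" Zero-point vibrational energy {zpe:12.1f} (Joules/Mol)")
            job["cc:zpe"] = float(f"{zpe:12.1f}")

        lines.append(" Normal termination of Gaussian 03.")
        truth.jobs.append(job)

    return "\n".join(lines) + "\n", truth


def random_logspec(seed: int) -> LogSpec:
    """A plausible random study condition: small molecule, common method and
    basis, one or two chained jobs."""
    rng = random.Random(seed)
    name = rng.choice(sorted(MOLECULES))
    jobs = rng.choice([["opt"], ["sp"], ["freq"], ["opt", "freq"]])
    return LogSpec(
        molecule=MOLECULES[name],
        charge=rng.choice([-1, 0, 0, 0, 1]),
        multiplicity=rng.choice([1, 1, 1, 2, 3]),
        method=rng.choice(_METHODS),
        basis=rng.choice(_BASES),
        jobs=list(jobs),
        n_occ=rng.randint(1, 25),
        n_virt=rng.randint(1, 40),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Mutation
# ---------------------------------------------------------------------------

MUTATION_MODES = ("truncate_tail", "inject_error_message",
                  "shuffle_whitespace", "duplicate_block")

_ERROR_LINE = (" Error termination via Lnk1e in /disk/g03/l9999.exe at "
               "Mon Nov 20 14:40:23 2006.")

_WS_RUN = re.compile(r"  +")


def mutate_logfile(text: str, mode: str, seed: int = 0) -> str:
    """Deterministically inject one class of real-log irregularity."""
    if mode not in MUTATION_MODES:
        raise ValueError(f"unknown mutation mode {mode!r}")
    rng = random.Random(seed)
    lines = text.splitlines()
    if not lines:
        return text
    if mode == "truncate_tail":
        k = rng.randint(1, max(1, len(lines) // 4))
        lines = lines[:-k] if k < len(lines) else lines[:1]
    elif mode == "inject_error_message":
        pos = rng.randint(0, len(lines))
        lines = lines[:pos] + [_ERROR_LINE] + lines[pos:]
    elif mode == "shuffle_whitespace":
        out = []
        for line in lines:
            if rng.random() < 0.4:
                line = _WS_RUN.sub(lambda m: m.group(0) + " " * rng.randint(1, 3),
                                   line)
            if rng.random() < 0.2:
                line = line + " " * rng.randint(1, 4)
            out.append(line)
        lines = out
    elif mode == "duplicate_block":
        start = rng.randrange(len(lines))
        width = rng.randint(1, min(10, len(lines) - start))
        lines = lines[:start + width] + lines[start:start + width] + \
            lines[start + width:]
    return "\n".join(lines) + ("\n" if text.endswith("\n") else "")


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------

def _close(a: float, b: float, rtol=1e-9) -> bool:
    return abs(a - b) <= rtol * max(1.0, abs(a), abs(b))


def _match_value(expected, got) -> bool:
    if isinstance(expected, float):
        return isinstance(got, (int, float)) and _close(expected, float(got))
    if isinstance(expected, int):
        try:
            return int(got) == expected
        except (TypeError, ValueError):
            return False
    return str(got) == str(expected)


def recovery_score(truth: GroundTruth, parsed: SemNode) -> float:
    """Fraction of ground-truth keys recovered from a converted document.

    Jobs pair by order; doubles must agree to 1e-9 relative.  1.0 means
    every recorded concept was captured; 0.0 means nothing was.
    """
    jobs = iter_jobs(parsed)
    total = hit = 0
    for i, tj in enumerate(truth.jobs):
        pj = jobs[i] if i < len(jobs) else None
        for key, expected in tj.items():
            total += 1
            if pj is None:
                continue
            if key == "cc:formula":
                got = None
                for n in pj.iter():
                    if n.kind == "formula":
                        got = n.extra.get("concise")
                        break
                if got is not None and _match_value(expected, got):
                    hit += 1
                continue
            if isinstance(expected, list):
                arrays = find_arrays(pj, key)
                if arrays:
                    got = arrays[0].typed_values()
                    if len(got) == len(expected) and all(
                            _match_value(e, g) for e, g in zip(expected, got)):
                        hit += 1
            else:
                scalars = find_scalars(pj, key)
                if scalars and _match_value(expected, scalars[0].typed_value()):
                    hit += 1
    return hit / total if total else 0.0
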
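# Methods

## The problem

Quantum-chemistry programs (Gaussian, NWChem, GAMESS, ...) write their
results as free-text logfiles produced by record-oriented FORTRAN format
routines.  The information content — the model chemistry (method + basis
set), the molecular geometry, SCF energies, orbital eigenvalues, vibrational
frequencies, thermochemistry — is regular at the level of individual output
routines but has no machine-readable structure at the file level.  `cclog`
converts such logfiles into a typed semantic document following the
*compchem* convention (`jobList → job → environment / initialization /
calculation / finalization`), validates every term against a semantic
dictionary, and indexes converted calculations for field and numeric-range
search.

## Template matching

A **template** describes one chunk of logfile: a start pattern (a regex that
must match the chunk's first line), an optional end pattern, and an ordered
list of **records** — single-line patterns interleaving literal regex with
typed field specifiers:

```
{COUNT TYPE, REF}     COUNT := INT | INT "_" INT   (absent → 1)
                      TYPE  := F (double) | I (integer) | X (token) | A (rest of line)
```

`{1_5F, g:eigen}` captures one to five doubles into an array labelled with
the temporary reference `g:eigen`.  An `X` field whose reference has local
name `name` is a *naming field*: its captured text becomes the temporary
`cmlx:temp` label of the record's other captures (this is how eigenvalue
rows get labelled `Alpha occ.` / `Alpha virt.`).  X-captures are trimmed of
surrounding whitespace.

The engine scans the file top to bottom.  At each line the *first* template
(in pack order) whose start pattern matches claims a chunk; claimed lines
are consumed and never re-offered to other templates.  A chunk extends
while lines keep matching the template's records or nested templates
(maximal munch); a line matching the end pattern stops it unconditionally
and is not consumed.  A template marked `strict` that consumes none of its
chunk's content rewinds, and the chunk is offered to the next template.
Lines claimed by nothing become **unparsed residue**; by construction,
parsed chunks plus residue tile the input byte-for-byte (the partition
property, enforced by property tests).  Failures are silent: malformed
interior lines degrade to unparsed text, never to an exception, because
real logs contain error messages and syntax drift that must not abort a
batch of thousands of files.

Field specifiers compile to bounded, alternation-free regex fragments
(`(?:\s*FLOAT){m,n}`), so matching a line of *k* tokens is linear in *k*;
naively concatenating per-value capture groups is known to behave
exponentially on long lines.  Fortran `D` exponents (`1.0D-05`) are accepted
wherever a double is and normalized to `E` on storage.  Record `repeat`
attributes are parsed but advisory: every record is offered to every line of
its chunk in declared order, which is equivalent for all templates shipped
here and considerably more robust.

Templates may embed an example input and expected output; `run_embedded_tests`
(and the CLI `selftest` command) parses the example with the template,
applies its transforms, and compares structurally — templates are
self-testing.  In the comparison an absent `templateRef` in the expected
tree is unconstrained, since hand-written expected outputs label only the
chunk module.

## Transform programs

The raw parse mirrors line structure, not meaning.  A second declarative
phase normalizes it with an ordered program of steps, each addressing nodes
through a restricted path language (`.//array[@dictRef='cc:frequency']`,
child/descendant axes, conjunctive attribute predicates on `dictRef`,
`cmlx:temp`, `cmlx:templateRef`, `id` — no functions or indices, so
evaluation is linear and each node is visited once).  Steps: `addDictRef`
(which also consumes the temporary `cmlx:temp` label), `addUnits`,
`setDataType`, `rename`, `joinArrays`, `delete`, `deleteHierarchy`,
`groupSiblings`, `annotateModule`, `move`.  `joinArrays` concatenates each
run of *consecutive* sibling arrays with equal labels — the wrapped-line
stitching case; non-adjacent merging requires an explicit `groupSiblings`
first.  Joining arrays of different dataType is the one hard error.  A step
matching nothing is a logged no-op: transform programs must survive strange
documents.

Source transform files mix the code-specific `g:` prefix with the canonical
`cc:` for the same concept (a `joinArrays` addressing `g:alphaocc`
immediately after an `addDictRef` assigned `cc:alphaocc`).  The path matcher
therefore unifies prefixes that alias known dictionaries when local names
agree, logging each tolerated mismatch.

## Documents, dictionaries, conventions

The document tree (`SemNode`) carries the standard vocabulary: `module`,
`scalar`, `array`, `matrix`, `table`, `parameter(List)`, `property(List)`,
`molecule/atom/bond/formula`.  Numeric payloads are stored as their original
decimal strings alongside parsed values, so write → read never changes
printed precision; declared `size` and `rows×columns` are enforced against
payload length on both read and write.  Delimited arrays
(`delimiter="|"`) drop the empty fields produced by enclosing delimiters.
Namespace prefixes are treated as opaque strings — term equality goes
through an alias table (`cc` and `compchem` both name the compchem
dictionary), never through URI resolution.  Dates are normalized to
ISO-8601 with a trailing `Z` on write.  Unknown elements round-trip as
opaque nodes.

Dictionaries (~90 code-independent terms shipped as package data) declare
per-term `dataType`, `unitType` and `units`.  `validate_refs` reports every
unresolvable reference as a *warning* — code-specific `g:` and temporary
`x:` terms are expected to float — and reports a *type mismatch error* only
when a node's **explicit** dataType contradicts the dictionary; an absent
dataType is supplied by the dictionary, not flagged, since reference
documents routinely omit it.  The dictionary loader rejects duplicate entry
ids by default and offers a `flag` mode that records the clash instead of
silently picking one entry.

Convention restructuring is rule-driven: a role file maps each template id
to `environment` / `initialization` / `calculation` / `finalization`, to
`jobstart` (a program-restart marker opening a new job), to `molecule` (a
coordinate table converted into an `atomArray` + concise formula), or to
`drop` (payload-free markers).  Chunks with no rule are conserved under a
per-job `cc:userDefinedModule` with a warning.  The environment module is
optional — single-point logs parsed on a machine that prints no banner are
still valid — as is `calculation`; `initialization` and `finalization` are
required.  Validation checks role multiplicities, parameter/property
placement (`parameterList` in initialization, `propertyList` in
finalization) and molecule integrity (unique atom ids, resolvable bond
endpoints, well-formed concise formulas).

## Synthetic logfiles

The generator emits Gaussian-style logs with machine-readable ground truth
so the whole stack is testable without external data.  Emulated features:
the route line (`#N method/basis keywords`), charge/multiplicity, atom
counts, a standard-orientation coordinate table, basis-set and electron
counts, point group, nuclear repulsion energy, `SCF Done` energy, orbital
eigenvalue blocks wrapped exactly five per line, and for frequency jobs the
frequency/IR-intensity arrays and a thermochemistry block; chained jobs
(`opt` then `freq`) produce one `Entering Link 1` section each.  Values are
drawn from seeded ranges plausible for each term — occupied orbital energies
in (−12, −0.2) hartree sorted below the virtuals in (0.05, 5), SCF energies
negative, frequencies in 100–4000 cm⁻¹ — and the ground truth records each
value *as printed*, so recovery is exact-match (doubles to 1e-9 relative).
No quantum chemistry is computed: the generator tests parsing fidelity, not
physics.  Two deliberate simplifications relative to real Gaussian output:
frequency blocks are emitted as one contiguous wrapped run per quantity
rather than interleaved three-mode groups (array stitching is defined over
consecutive siblings), and the SCF summary plays the role of the archive
section as the finalization energy source.  Consequently, passing tests
demonstrate the engine and convention machinery end-to-end, not coverage of
every real Gaussian dialect; real logs need a fuller template pack, which is
exactly the extension path the template design exists for.

The mutator injects the irregularity classes real logs suffer:
`truncate_tail` (killed jobs), `inject_error_message`, `shuffle_whitespace`
(which perturbs only runs of two or more spaces, the FORTRAN field-padding
that carries no meaning), and `duplicate_block`.  The pipeline must
terminate normally with the partition property intact under all four;
whitespace shuffling must additionally leave ground-truth recovery at 1.0.

`recovery_score` pairs ground-truth jobs with converted jobs by order and
reports the fraction of recorded concepts whose extracted value matches.

## Index

Each job of a convention-valid document becomes one entry: formula, program,
method, basis, atom count, and every resolvable double-valued finalization
property with its units.  Entry ids are an ingest counter plus a content
hash of the canonical job serialization, so identical documents may be
ingested repeatedly — deliberately, no duplicate check is made.  Numeric
range queries run in canonical units via a fixed conversion table (energies
to hartree: 1 Eh = 2625499.62 J/mol); a stored value whose units fall
outside the table makes a range query on that term an explicit error, never
a silent miss.  Triple export writes deterministic, sorted N-Triples-style
lines from which the entry record reconstructs exactly.

## Numerical and design choices

- Recovery comparisons use 1e-9 *relative* tolerance for doubles; everything
  else is exact string/integer equality.
- Test problem sizes: the seeded-recovery sweep uses 100 random
  specifications (seeds 1–100, molecules of 3–5 atoms, up to 65 orbital
  eigenvalues, one or two jobs); the partition property runs over 1000
  randomized inputs of up to ~12 lines; oracle equivalence over 500.  These
  sizes exercise every code path while keeping the default suite in seconds.
- Document order everywhere is pre-order (serialization order); `find_nodes`
  and transform matching inherit it.
- Line handling: input is split on `\n` with line endings retained for
  reassembly and stripped (`\r` included) for matching.

## Known limitations

- The shipped Gaussian pack is demonstrative (~14 templates), not a full
  per-code library; untemplated sections land in the unparsed residue by
  design.
- Beta-spin eigenvalue relabelling is not wired up (the shipped transforms
  cover closed-shell alpha blocks); beta lines still parse into labelled raw
  arrays.
- The unit conversion table covers the energy and spectroscopy units the
  shipped dictionary uses; extending it is a data change.
- No incremental build tracking: the CLI is explicit batch commands, and
  idempotent re-runs produce byte-identical outputs instead.
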
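# cclog

Quantum-chemistry programs write their results as free-text logfiles.  The
numbers a chemist needs — the model chemistry (method + basis set, e.g.
RB3LYP/6-31G(d)), the geometry, SCF energies, orbital eigenvalues,
vibrational frequencies, thermochemistry — are buried in record-oriented
text that every program formats differently.  `cclog` is a conversion stack
for such logfiles, aimed at anyone who wants their calculations
machine-readable and searchable at the scale of a laptop:

- a **declarative template engine** that recognizes logfile chunks
  (eigenvalue tables, coordinate blocks, SCF summaries) with typed field
  specifiers like `{1_5F, g:eigen}` (one to five doubles) and degrades
  gracefully — anything unrecognized is preserved as unparsed residue, so
  parsed chunks plus residue always reassemble the input byte-for-byte;
- a **transform language** (`addDictRef`, `joinArrays`, `delete`, ...) that
  normalizes the raw parse: relabelling temporary captures with dictionary
  terms, attaching units the logfile never states, stitching wrapped lines
  back into single arrays;
- the **compchem convention**: documents restructured into
  `jobList → job → environment / initialization / calculation /
  finalization`, with every `dictRef` validated against a ~90-term semantic
  dictionary shipped as package data;
- a **synthetic log generator** with machine-readable ground truth, so the
  whole stack is testable end-to-end with no external data;
- a **local index** (single-file SQLite) searchable by formula, method,
  basis and numeric property ranges in canonical units, with N-Triples-style
  export.

Templates are self-testing: each can embed an example input and expected
output, and `cclog selftest` replays them all.

## Worked example

Generate a synthetic two-job methane log (an optimization chained with a
frequency job), convert it, and index the result:

```
$ cclog generate --molecule CH4 --jobs opt,freq --seed 42 -o ch4.log
wrote ch4.log (62 lines) and ch4.log.truth

$ head -5 ch4.log
 Entering Link 1
 Gaussian 03:  x86-Linux-G03RevB.04
 #N RB3LYP/6-31G(d) Opt
 Charge =  0 Multiplicity = 1
 NAtoms=     5 NActive=     5

$ cclog convert ch4.log -o out
ch4.log: converted (unparsed fraction 0.000, 0 convention errors, 0 type errors)
1 converted, 0 failed
```

`out/ch4.cml.xml` is the compchem document (two `cc:job` modules whose
initialization carries the method, basis, charge/multiplicity and input
molecule, and whose finalization carries the energies and frequency data);
`out/ch4.residue.txt` holds any lines no template claimed — here empty, an
unparsed fraction of 0.000.  The sidecar `ch4.log.truth` records every
value the generator printed (`job1.cc:hfenergy=-347.26883`, ...), which is
how the test suite asserts that conversion recovers 100 % of the recorded
concepts.

```
$ cclog index out/ch4.cml.xml -s store.db
000001-130fd15e82bb  C 1 H 4  RB3LYP/6-31G(d)
000002-f8ccd7f8ffed  C 1 H 4  RB3LYP/6-31G(d)
ingested 2 entries

$ cclog search -s store.db --range "cc:hfenergy=-600:0" --triples | head -4
<entry:000001-130fd15e82bb> <cc:basis> "6-31G(d)" .
<entry:000001-130fd15e82bb> <cc:formula> "C 1 H 4" .
<entry:000001-130fd15e82bb> <cc:hfenergy> "-347.26883"^^xsd:double .
<entry:000001-130fd15e82bb> <cc:hfenergy#units> "nonsi:hartree" .
```

The range query runs in canonical units (energies in hartree); each job of
the document became one searchable entry.

The same machinery is a library: `cclog.convert_text(text)` returns the
document, the chunk/residue partition, and the validation reports;
`cclog.read_document` / `write_document` round-trip the XML dialect without
losing printed precision.

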
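"""Convention restructuring and validation."""

import pytest

from cclog.compchem import (RestructureRules, iter_jobs, job_role,
                            restructure, validate_convention)
from cclog.convert import convert_text
from cclog.semdoc import SemNode, find_nodes, find_scalars
from cclog.synthetic import LogSpec, MOLECULES, generate_logfile
from cclog.template_engine import match_chunks


@pytest.fixture()
def chained_result(gaussian_pack, gaussian_rules):
    spec = LogSpec(molecule=MOLECULES["CH4"], jobs=["opt", "freq"], seed=7)
    text, truth = generate_logfile(spec)
    return convert_text(text, gaussian_pack, gaussian_rules), truth


class TestRestructure:
    def test_chained_jobs_split_in_order(self, chained_result):
        result, _ = chained_result
        jobs = iter_jobs(result.document)
        assert len(jobs) == 2
        init2 = job_role(jobs[1], "initialization")
        params = [n for n in init2.iter() if n.kind == "parameter"]
        assert params, "second job initialization carries keyword parameters"

    def test_environment_optional(self, chained_result):
        result, _ = chained_result
        jobs = iter_jobs(result.document)
        # banner appears only in the first job section
        assert job_role(jobs[0], "environment") is not None
        assert job_role(jobs[1], "environment") is None
        assert validate_convention(result.document).errors == []

    def test_molecule_built_from_orientation_table(self, chained_result):
        result, _ = chained_result
        init = job_role(iter_jobs(result.document)[0], "initialization")
        mols = [n for n in init.iter() if n.kind == "molecule"]
        assert len(mols) == 1
        view = mols[0].molecule()
        assert len(view.atoms) == 5
        assert view.formulas[0].extra["concise"] == "C 1 H 4"

    def test_unassignable_chunks_go_to_user_defined_module(self, gaussian_rules):
        raw = SemNode(kind="module")
        for _ in range(2):
            m = raw.append(SemNode(kind="module", templateRef="mystery.tpl"))
            m.append(SemNode(kind="array", dictRef="g:eigen",
                             dataType="xsd:double", value=["1.0"], size=1))
        doc = restructure(raw, gaussian_rules)
        jobs = iter_jobs(doc)
        assert len(jobs) == 1
        udm = find_nodes(jobs[0], ".//module[@dictRef='cc:userDefinedModule']")
        assert len(udm) == 1 and len(udm[0].children) == 2

    def test_content_conserved(self, gaussian_pack, gaussian_rules):
        spec = LogSpec(molecule=MOLECULES["H2O"], jobs=["sp"], seed=3)
        text, _ = generate_logfile(spec)
        parse = match_chunks(text, gaussian_pack)
        molecule_chunks = {"l202.orient"}

        def payloads(root, skip_molecule_chunks):
            out = []
            def walk(n, in_mol_chunk):
                if n.kind == "module" and n.templateRef in molecule_chunks:
                    in_mol_chunk = True
                for c in n.children:
                    if c.kind in ("scalar", "array") and not (
                            skip_molecule_chunks and in_mol_chunk):
                        out.append(tuple(c.value) if isinstance(c.value, list)
                                   else c.value)
                    walk(c, in_mol_chunk)
            walk(root, False)
            return sorted(map(str, out))

        raw_payloads = payloads(parse.document, skip_molecule_chunks=True)
        doc = restructure(parse.document, gaussian_rules)
        assert payloads(doc, skip_molecule_chunks=False) == raw_payloads

    def test_rules_parser_rejects_unknown_role(self):
        with pytest.raises(ValueError, match="sideways"):
            RestructureRules.from_text("a.tpl=sideways")


class TestValidateConvention:
    def test_reference_document_is_clean(self, ch4_doc):
        assert validate_convention(ch4_doc).errors == []

    def test_removed_finalization_gives_exactly_one_error(self, ch4_doc):
        job1 = find_nodes(ch4_doc, ".//module[@id='job1']")[0]
        job1.children = [c for c in job1.children
                         if (c.dictRef or "") != "cc:finalization"]
        report = validate_convention(ch4_doc)
        assert len(report.errors) == 1
        assert report.errors[0].code == "missing-finalization"

    def test_duplicate_role_is_error(self, ch4_doc):
        job1 = find_nodes(ch4_doc, ".//module[@id='job1']")[0]
        fin = job_role(job1, "finalization")
        job1.append(SemNode(kind="module", dictRef="cc:finalization"))
        report = validate_convention(ch4_doc)
        assert any(f.code == "duplicate-role" for f in report.errors)
        assert fin is not None

    def test_property_inside_initialization_warns(self, ch4_doc):
        job1 = find_nodes(ch4_doc, ".//module[@id='job1']")[0]
        init = job_role(job1, "initialization")
        plist = init.append(SemNode(kind="propertyList"))
        prop = plist.append(SemNode(kind="property", dictRef="cc:temp"))
        prop.append(SemNode(kind="scalar", dataType="xsd:double", value="1.0"))
        report = validate_convention(ch4_doc)
        assert report.errors == []
        assert any(f.code == "misplaced-property" for f in report.warnings)

    def test_no_joblist_is_error(self):
        report = validate_convention(SemNode(kind="module"))
        assert [f.code for f in report.errors] == ["no-joblist"]

    def test_broken_bond_reference_is_error(self, ch4_doc):
        mol = find_nodes(ch4_doc, ".//molecule[@id='mol9999']")[0]
        bonds = [c for c in mol.children if c.kind == "bondArray"][0]
        bonds.children[0].extra["atomRefs2"] = "a1 a99"
        report = validate_convention(ch4_doc)
        assert any(f.code == "bad-molecule" for f in report.errors)
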
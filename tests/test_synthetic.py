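"""Synthetic log generator, mutator, and recovery scoring."""

import pytest

from cclog.convert import convert_text
from cclog.synthetic import (GroundTruth, LogSpec, MOLECULES, SpecError,
                             generate_logfile, mutate_logfile, random_logspec,
                             recovery_score)
from cclog.semdoc import SemNode


@pytest.fixture(scope="module")
def ch4_spec():
    return LogSpec(molecule=MOLECULES["CH4"], n_occ=5, n_virt=18, seed=42)


class TestGenerate:
    def test_deterministic_for_fixed_seed(self, ch4_spec):
        assert generate_logfile(ch4_spec)[0] == generate_logfile(ch4_spec)[0]

    def test_eigenvalue_wrapping_five_per_line(self, ch4_spec):
        text, truth = generate_logfile(ch4_spec)
        occ = [l for l in text.splitlines() if "occ. eigenvalues" in l]
        virt = [l for l in text.splitlines() if "virt. eigenvalues" in l]
        assert len(occ) == 1 and len(virt) == 4  # 5 and 18 wrapped by 5
        job = truth.jobs[0]
        assert job["cc:natoms"] == 5 and job["cc:alphae"] == 5
        assert len(job["cc:alphaocc"]) == 5

    def test_occupied_below_virtual(self, ch4_spec):
        _, truth = generate_logfile(ch4_spec)
        job = truth.jobs[0]
        assert job["cc:alphaocc"] == sorted(job["cc:alphaocc"])
        assert max(job["cc:alphaocc"]) < min(job["cc:alphavirt"])

    def test_chained_jobs_emit_two_sections(self):
        spec = LogSpec(molecule=MOLECULES["H2O"], jobs=["opt", "freq"], seed=1)
        text, truth = generate_logfile(spec)
        assert text.count(" Entering Link 1") == 2
        assert len(truth.jobs) == 2
        assert "cc:frequency" in truth.jobs[1]

    @pytest.mark.parametrize("bad", [
        dict(multiplicity=0), dict(n_occ=-1), dict(jobs=["dance"]),
        dict(molecule=[]),
    ])
    def test_invalid_specs_rejected(self, bad):
        kw = dict(molecule=MOLECULES["CH4"], seed=1)
        kw.update(bad)
        with pytest.raises(SpecError):
            LogSpec(**kw).validate()

    def test_truth_sidecar_round_trips(self, ch4_spec):
        _, truth = generate_logfile(ch4_spec)
        again = GroundTruth.from_text(truth.to_text())
        assert again.jobs == truth.jobs


class TestMutate:
    @pytest.mark.parametrize("mode", ["truncate_tail", "inject_error_message",
                                      "shuffle_whitespace", "duplicate_block"])
    def test_mutation_changes_text_deterministically(self, ch4_spec, mode):
        text, _ = generate_logfile(ch4_spec)
        m1 = mutate_logfile(text, mode, seed=5)
        assert m1 != text
        assert m1 == mutate_logfile(text, mode, seed=5)

    def test_truncated_tail_still_yields_initialization(self, gaussian_pack,
                                                        gaussian_rules):
        spec = LogSpec(molecule=MOLECULES["NH3"], jobs=["freq"], seed=9)
        text, _ = generate_logfile(spec)
        mutated = mutate_logfile(text, "truncate_tail", seed=9)
        result = convert_text(mutated, gaussian_pack, gaussian_rules)
        init = [n for n in result.document.iter()
                if n.dictRef == "cc:initialization"]
        assert init, "initialization content survives truncation"

    def test_injected_error_lands_in_residue(self, ch4_spec, gaussian_pack,
                                             gaussian_rules):
        text, _ = generate_logfile(ch4_spec)
        mutated = mutate_logfile(text, "inject_error_message", seed=2)
        result = convert_text(mutated, gaussian_pack, gaussian_rules)
        assert result.parse.reassemble() == mutated
        residue = "".join(c.text for c in result.parse.unparsed)
        in_chunks = any("Error termination" in n.value
                        for n in result.raw.iter()
                        if n.kind == "comment" and n.value)
        assert "Error termination" in residue or in_chunks

    def test_whitespace_shuffle_leaves_recovery_intact(self, ch4_spec,
                                                       gaussian_pack,
                                                       gaussian_rules):
        text, truth = generate_logfile(ch4_spec)
        mutated = mutate_logfile(text, "shuffle_whitespace", seed=3)
        result = convert_text(mutated, gaussian_pack, gaussian_rules)
        assert recovery_score(truth, result.document) == 1.0

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError):
            mutate_logfile("x", "scramble", 1)


class TestRecoveryScore:
    def test_unmutated_output_scores_one(self, gaussian_pack, gaussian_rules):
        text, truth = generate_logfile(random_logspec(11))
        result = convert_text(text, gaussian_pack, gaussian_rules)
        assert recovery_score(truth, result.document) == 1.0

    def test_empty_parse_scores_zero(self, ch4_spec):
        _, truth = generate_logfile(ch4_spec)
        assert recovery_score(truth, SemNode(kind="module")) == 0.0

    def test_partial_loss_scores_strictly_between(self, ch4_spec,
                                                  gaussian_pack,
                                                  gaussian_rules):
        text, truth = generate_logfile(ch4_spec)
        kept = [l for l in text.splitlines()
                if "eigenvalues" not in l and "SCF Done" not in l]
        result = convert_text("\n".join(kept) + "\n", gaussian_pack,
                              gaussian_rules)
        score = recovery_score(truth, result.document)
        assert 0.0 < score < 1.0
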
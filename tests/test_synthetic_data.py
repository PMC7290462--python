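import numpy as np
import pytest

from dgrscout import synthetic_data as sd


class TestMutateTrToVr:
    def test_zero_rates_leave_tr_untouched(self, panel):
        spec = sd.CassetteSpec(p_aton=0.0, non_aton_rate=0.0, seed=1)
        vr, log = sd.mutate_tr_to_vr(panel["tr"], spec)
        assert vr == panel["tr"]
        assert log == ()

    def test_full_rate_substitutes_every_eligible_adenine(self, panel):
        tr = panel["tr"]
        spec = sd.CassetteSpec(p_aton=1.0, non_aton_rate=0.0, seed=2)
        vr, log = sd.mutate_tr_to_vr(tr, spec, avoid_stops=False)
        eligible = {i for i in range(len(tr) - spec.imh_len) if tr[i] == "A"}
        assert {pos for pos, _, _ in log} == eligible
        assert all(old == "A" and new != "A" for _, old, new in log)

    def test_imh_suffix_never_touched(self, panel):
        tr = panel["tr"]
        for seed in range(5):
            spec = sd.CassetteSpec(p_aton=0.9, non_aton_rate=0.2, seed=seed)
            vr, _ = sd.mutate_tr_to_vr(tr, spec)
            assert vr[-spec.imh_len:] == tr[-spec.imh_len:]

    def test_deterministic_per_seed(self, panel):
        spec = sd.CassetteSpec(seed=9)
        assert sd.mutate_tr_to_vr(panel["tr"], spec) == sd.mutate_tr_to_vr(panel["tr"], spec)

    def test_exact_counts(self, panel):
        spec = sd.CassetteSpec(n_aton=21, n_non_aton=2, seed=4)
        vr, log = sd.mutate_tr_to_vr(panel["tr"], spec)
        aton = sum(1 for _, old, _ in log if old == "A")
        assert aton == 21
        assert len(log) - aton == 2


class TestGenerateGenome:
    def test_truth_substitutions_match_emitted_sequences(self):
        genome, truth = sd.generate_genome_with_cassette(sd.CassetteSpec(seed=17))
        vr = genome.sequence[slice(*truth.elements["VR"])]
        tr = genome.sequence[slice(*truth.elements["TR"])]
        observed = {(i, t, v) for i, (v, t) in enumerate(zip(vr, tr)) if v != t}
        assert observed == set(truth.substitutions)

    def test_imh_suffixes_identical(self):
        genome, truth = sd.generate_genome_with_cassette(sd.CassetteSpec(seed=18))
        s = genome.sequence
        assert s[slice(*truth.elements["IMH"])] == s[slice(*truth.elements["IMH*"])]

    def test_absent_class_has_anchors_only(self):
        genome, truth = sd.generate_genome_with_cassette(
            sd.CassetteSpec(class_label="absent", seed=19)
        )
        assert set(truth.elements) == {"TNP", "HP", "IHF"}

    def test_tr_deleted_variant_lacks_tr(self):
        genome, truth = sd.generate_genome_with_cassette(
            sd.CassetteSpec(class_label=sd.VARIANT_TR_DELETED, seed=20)
        )
        assert "VR" in truth.elements and "TR" not in truth.elements

    def test_reproducible(self):
        a, _ = sd.generate_genome_with_cassette(sd.CassetteSpec(seed=21))
        b, _ = sd.generate_genome_with_cassette(sd.CassetteSpec(seed=21))
        assert a.sequence == b.sequence

    def test_minimum_length_enforced(self):
        with pytest.raises(ValueError):
            sd.generate_genome_with_cassette(sd.CassetteSpec(seed=1), genome_len=5000)


class TestGenerateCohort:
    def test_mix_respected_exactly(self):
        genomes, truths = sd.generate_cohort(
            9, {"complete": 3, "incomplete": 3, "absent": 3}, seed=2, genome_len=20_000
        )
        assert len(genomes) == 9
        coarse = ["complete" if t.class_label == "complete"
                  else "absent" if t.class_label == "absent" else "incomplete"
                  for t in truths]
        assert sorted(coarse) == ["absent"] * 3 + ["complete"] * 3 + ["incomplete"] * 3

    def test_mismatched_mix_rejected(self):
        with pytest.raises(ValueError, match="sums to"):
            sd.generate_cohort(5, {"complete": 3}, seed=1)

    def test_same_seed_identical_output(self):
        a, _ = sd.generate_cohort(3, {"complete": 3}, seed=5, genome_len=20_000)
        b, _ = sd.generate_cohort(3, {"complete": 3}, seed=5, genome_len=20_000)
        assert [g.sequence for g in a] == [g.sequence for g in b]


class TestFlagship:
    def test_flagship_matches_emulated_locus_statistics(self, flagship):
        genome, truth = flagship
        assert genome.length == 98_458
        tr = genome.sequence[slice(*truth.elements["TR"])]
        assert len(tr) == 105 and tr.count("A") == 28
        aton = sum(1 for _, old, _ in truth.substitutions if old == "A")
        assert aton == 21 and len(truth.substitutions) == 23
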
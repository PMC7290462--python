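import numpy as np
import pytest

from dgrscout.seq_io import GenomeRecord, OrfRecord, find_orfs
from dgrscout.dgr_core import (
    assemble_cassette,
    classify_architecture,
    detect_cassettes,
    detect_rt,
    find_repeat_pairs,
    orient_with_refinement,
)
from dgrscout import synthetic_data as sd


def _orf(protein, start=0, label=None):
    end = start + 3 * (len(protein) + 1)
    return OrfRecord("g", start, end, "+", start % 3, protein, label=label)


class TestDetectRt:
    def test_motif_mode_flags_catalytic_pattern(self):
        rng = np.random.default_rng(0)
        aa = "".join(rng.choice(list("ACEFGHIKLNPQRSTW"), size=350))
        prot = aa[:200] + "YMDD" + aa[204:]
        assert detect_rt([_orf(prot)], mode="motif")
        assert detect_rt([_orf(prot)], mode="motif")[0].label == "RT"

    def test_no_pattern_no_hit(self):
        assert detect_rt([_orf("MKLAGE" * 50)], mode="motif") == []

    def test_size_window_enforced(self):
        short = "MYMDD" + "A" * 40  # 45 aa, below the RT size window
        assert detect_rt([_orf(short)], mode="motif") == []

    def test_reference_mode_flags_diverged_copy(self, panel):
        ref = panel["protein"]["RT"]
        rng = np.random.default_rng(1)
        diverged = list(ref)
        for i in rng.choice(len(ref), size=len(ref) // 10, replace=False):
            diverged[i] = "ACDEFGHIKLMNPQRSTVWY"[rng.integers(20)]
        hits = detect_rt([_orf("".join(diverged))], mode="reference",
                         refs={"RT": ref}, score_min=60)
        assert len(hits) == 1

    def test_reference_mode_requires_refs(self):
        with pytest.raises(ValueError):
            detect_rt([], mode="reference")


class TestClassifyArchitecture:
    def test_complete(self):
        label, arch = classify_architecture(True, True, True, True, True, True, True, True)
        assert label == "complete"
        assert arch == "TG-VR(IMH)-TR(IMH*)-RT"

    def test_absent(self):
        assert classify_architecture(*([False] * 8)) == ("absent", "")

    def test_truncated_genes_with_orphan_vr(self):
        label, arch = classify_architecture(
            target_gene_present=True, target_full_length=False,
            vr_present=True, imh_present=False,
            tr_present=False, imh_star_present=False,
            rt_present=True, rt_full_length=False,
        )
        assert label == "incomplete"
        assert arch == "tg'-VR-rt'"


class TestAssembleCassette:
    def test_planted_complete_cassette(self, complete_genome):
        genome, truth = complete_genome
        cassettes = detect_cassettes(genome)
        assert len(cassettes) == 1
        c = cassettes[0]
        assert c.cassette_class == "complete"
        assert c.architecture == "TG-VR(IMH)-TR(IMH*)-RT"
        assert c.target_gene is not None and c.rt is not None
        assert abs(c.vr[0] - truth.elements["VR"][0]) <= 3

    def test_pair_without_target_gene_is_partial(self):
        # repeats planted into a gene-free random background
        rng = np.random.default_rng(7)
        tr = sd._sample_tr(rng, 35, 0.27)
        spec = sd.CassetteSpec(seed=7)
        vr, _ = sd.mutate_tr_to_vr(tr, spec, rng)
        bg = "".join(rng.choice(list("ACGT"), size=4000, p=[0.33, 0.17, 0.17, 0.33]))
        seq = bg[:1000] + vr + bg[1000:2000] + tr + bg[2000:]
        genome = GenomeRecord("g", seq)
        pairs = find_repeat_pairs(genome)
        assert pairs
        oriented = [orient_with_refinement(genome, p) for p in pairs]
        cassettes = assemble_cassette(genome, [], oriented, [])
        assert cassettes
        assert cassettes[0].cassette_class == "incomplete"
        assert cassettes[0].target_gene is None

    def test_two_cassettes_both_recovered_and_ranked(self):
        g1, t1 = sd.generate_genome_with_cassette(sd.CassetteSpec(seed=31))
        g2, t2 = sd.generate_genome_with_cassette(sd.CassetteSpec(seed=32))
        lo = min(v[0] for v in t2.elements.values()) - 200
        hi = max(v[1] for v in t2.elements.values()) + 200
        locus2 = g2.sequence[lo:hi]
        seq = g1.sequence[:5000] + locus2 + g1.sequence[5000 + len(locus2):]
        cassettes = detect_cassettes(GenomeRecord("two", seq))
        assert len(cassettes) == 2
        assert all(c.cassette_class == "complete" for c in cassettes)
        assert cassettes[0].score >= cassettes[1].score
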
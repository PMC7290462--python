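import numpy as np
import pytest

from dgrscout.seq_io import GenomeRecord
from dgrscout.cohort import (
    anchor_scan,
    exhaustive_anchor_score,
    extract_region,
    round_half_up_percent,
    screen_cohort,
    screen_genome,
)
from dgrscout import synthetic_data as sd


def _random_genome(n, seed):
    rng = np.random.default_rng(seed)
    return GenomeRecord(f"rand{seed}",
                        "".join(rng.choice(list("ACGT"), size=n,
                                           p=[0.33, 0.17, 0.17, 0.33])))


class TestAnchorScan:
    def test_planted_anchor_found_at_planted_interval(self, complete_genome, anchor_refs):
        genome, truth = complete_genome
        hits = {h.anchor_label: h for h in anchor_scan(genome, anchor_refs)}
        assert "TNP" in hits
        h = hits["TNP"]
        t = truth.elements["TNP"]
        ov = min(h.interval[1], t[1]) - max(h.interval[0], t[0])
        assert ov / (t[1] - t[0]) >= 0.9
        assert h.strand == "+"

    def test_random_genome_has_no_hits(self, anchor_refs):
        genome = _random_genome(10_000, 123)
        # oracle: even exhaustive Smith-Waterman stays below the threshold
        assert all(exhaustive_anchor_score(genome, ref) < 60
                   for ref in anchor_refs.values())
        assert anchor_scan(genome, anchor_refs, score_min=60) == []

    def test_hits_only_in_genome_carrying_anchor(self, complete_genome, anchor_refs):
        genome, _ = complete_genome
        with_anchor = anchor_scan(genome, anchor_refs)
        without = anchor_scan(_random_genome(10_000, 321), anchor_refs)
        assert with_anchor and not without

    def test_empty_reference_set_rejected(self, complete_genome):
        with pytest.raises(ValueError):
            anchor_scan(complete_genome[0], {})


class TestExtractRegion:
    def test_downstream_exact_span(self, complete_genome, anchor_refs):
        genome, _ = complete_genome
        h = anchor_scan(genome, anchor_refs)[0]
        region = extract_region(genome, h, span=7500, side="downstream")
        assert len(region.sequence) == 7500
        assert region.offset == h.interval[1]

    def test_upstream_clipped_at_genome_start(self, complete_genome, anchor_refs):
        genome, _ = complete_genome
        from dgrscout.cohort import AnchorHit

        near_start = AnchorHit(genome.id, "TNP", (100, 400), "+", 99.0, (0, 100), 100)
        region = extract_region(genome, near_start, span=7500, side="upstream")
        assert region.offset == 0
        assert len(region.sequence) == 100

    def test_roundtrip_coordinates(self, complete_genome, anchor_refs):
        genome, _ = complete_genome
        h = anchor_scan(genome, anchor_refs)[0]
        region = extract_region(genome, h, span=7500)
        x = 42
        assert genome.sequence[region.to_genome(x)] == region.sequence[x]


class TestScreenCohort:
    def test_all_complete_cohort(self, anchor_refs):
        genomes, _ = sd.generate_cohort(4, {"complete": 4}, seed=11)
        summary = screen_cohort(genomes, anchor_refs)
        assert summary.counts == {"complete": 4}
        assert summary.percentages == {"complete": 100}

    def test_empty_cohort_rejected(self, anchor_refs):
        with pytest.raises(ValueError, match="no genomes"):
            screen_cohort([], anchor_refs)

    def test_mixed_classes_match_planted_labels(self, anchor_refs):
        mix = {"complete": 2, sd.VARIANT_TG_TRUNCATED: 2,
               sd.VARIANT_TR_DELETED: 2, sd.VARIANT_RT_TRUNCATED: 2, "absent": 2}
        genomes, truths = sd.generate_cohort(10, mix, seed=23)
        summary = screen_cohort(genomes, anchor_refs)
        for result, truth in zip(summary.per_genome, truths):
            planted = ("complete" if truth.class_label == "complete"
                       else "absent" if truth.class_label == "absent"
                       else "incomplete")
            assert result.cassette_class == planted, (result, truth.class_label)
        assert sum(summary.counts.values()) == 10

    def test_vr_without_tr_reported(self, anchor_refs, panel):
        # reference-based VR calling needs the genus-shared template, as in
        # a cohort: the panel T-CFP's C-terminus is the undiversified VR
        genome, _ = sd.generate_genome_with_cassette(
            sd.CassetteSpec(class_label=sd.VARIANT_TR_DELETED, seed=77,
                            tr_seq=panel["tr"])
        )
        result = screen_genome(genome, anchor_refs)
        assert "VR" in result.elements
        assert "TR" not in result.elements


class TestRounding:
    @pytest.mark.parametrize("count,total,expected",
                             [(15, 91, 16), (66, 91, 73), (10, 91, 11), (1, 200, 1)])
    def test_round_half_up(self, count, total, expected):
        assert round_half_up_percent(count, total) == expected
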
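import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dgrscout.seq_io import (
    GenomeRecord,
    extract_orf_dna,
    find_orfs,
    read_fasta,
    read_genbank,
    revcomp,
    translate,
    write_fasta,
)

dna = st.text(alphabet="ACGT", min_size=0, max_size=300)


def _write(tmp_path, text, name="in.fasta"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadFasta:
    def test_normalizes_case_and_rna(self, tmp_path):
        recs = read_fasta(_write(tmp_path, ">g1\nacgu\n"))
        assert len(recs) == 1
        assert recs[0].id == "g1"
        assert recs[0].sequence == "ACGT"
        assert recs[0].length == 4

    def test_multiple_entries_in_file_order(self, tmp_path):
        recs = read_fasta(_write(tmp_path, ">a\nAC\n>b\nGT\n"))
        assert [r.id for r in recs] == ["a", "b"]

    def test_illegal_character_names_position(self, tmp_path):
        with pytest.raises(ValueError, match="position 2"):
            read_fasta(_write(tmp_path, ">g\nACXGT\n"))

    def test_missing_and_empty_files(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_fasta(tmp_path / "nope.fasta")
        with pytest.raises(ValueError, match="no FASTA records"):
            read_fasta(_write(tmp_path, ""))

    def test_roundtrip_byte_identical(self, tmp_path):
        recs = [GenomeRecord("r1", "ACGTN" * 40), GenomeRecord("r2", "TTTT")]
        out = tmp_path / "out.fasta"
        write_fasta(recs, out)
        back = read_fasta(out)
        assert [(r.id, r.sequence) for r in back] == [(r.id, r.sequence) for r in recs]


class TestReadGenbank:
    @staticmethod
    def _minimal_gb(tmp_path, with_cds=True):
        from Bio.Seq import Seq
        from Bio.SeqRecord import SeqRecord
        from Bio.SeqFeature import SeqFeature, SimpleLocation
        from Bio import SeqIO

        seq = "ATG" + "GCA" * 18 + "TAA"  # 60 bp ORF
        rec = SeqRecord(Seq(seq), id="mini", annotations={"molecule_type": "DNA"})
        if with_cds:
            rec.features.append(SeqFeature(SimpleLocation(0, 60, strand=1), type="CDS"))
        p = tmp_path / "mini.gb"
        SeqIO.write(rec, p, "genbank")
        return p

    def test_cds_coordinates_half_open(self, tmp_path):
        genome, orfs = read_genbank(self._minimal_gb(tmp_path))
        assert genome.length == 60
        assert len(orfs) == 1
        assert (orfs[0].start, orfs[0].end, orfs[0].strand) == (0, 60, "+")
        assert orfs[0].protein == "M" + "A" * 18

    def test_record_without_cds(self, tmp_path):
        genome, orfs = read_genbank(self._minimal_gb(tmp_path, with_cds=False))
        assert genome.length == 60
        assert orfs == []


class TestTranslate:
    @pytest.mark.parametrize(
        "dna_in,expected",
        [("ATGGCA", "MA"), ("", ""), ("TAA", "*"), ("ATGNNN", "MX")],
    )
    def test_examples(self, dna_in, expected):
        assert translate(dna_in) == expected

    def test_rejects_partial_codon(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            translate("ATGG")

    def test_rejects_illegal_base(self):
        with pytest.raises(ValueError):
            translate("ATQ")


class TestFindOrfs:
    def test_single_orf_with_protein(self):
        orfs = find_orfs(GenomeRecord("g", "ATGAAA" + "GCT" * 8 + "TAA"), min_len=30)
        assert len(orfs) == 1
        o = orfs[0]
        assert (o.start, o.end, o.strand) == (0, 33, "+")
        assert o.protein == "MK" + "A" * 8

    def test_no_orfs_in_homopolymer(self):
        assert find_orfs(GenomeRecord("g", "C" * 300), min_len=30) == []

    def test_min_len_validation(self):
        with pytest.raises(ValueError):
            find_orfs(GenomeRecord("g", "ATG" * 100), min_len=20)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(dna)
    def test_strand_symmetry(self, seq):
        g = GenomeRecord("g", seq)
        fwd = find_orfs(g, min_len=30)
        rc = find_orfs(GenomeRecord("g", revcomp(seq)), min_len=30)
        n = len(seq)
        mirrored = sorted(
            (n - o.end, n - o.start, "+" if o.strand == "-" else "-") for o in rc
        )
        assert sorted((o.start, o.end, o.strand) for o in fwd) == mirrored

    def test_translation_consistency(self, complete_genome):
        genome, _ = complete_genome
        for o in find_orfs(genome)[:30]:
            cds = extract_orf_dna(genome, o)
            assert translate(cds).rstrip("*") == o.protein
            assert (o.end - o.start) % 3 == 0
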
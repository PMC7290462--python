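"""Genome sequence I/O, ORF calling and translation.

Coordinate convention: 0-based half-open intervals on the forward strand,
everywhere. GenBank's 1-based inclusive locations are converted at the
parsing boundary; GFF3 output converts back on the way out.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq

DNA_ALPHABET = frozenset("ACGTN")
STOP_CODONS_11 = frozenset({"TAA", "TAG", "TGA"})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeRecord:
    """One genome sequence with identifier and source metadata."""

    id: str
    sequence: str
    source: str = ""

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(self.sequence) if c in bad)
            raise ValueError(
                f"illegal character {self.sequence[pos]!r} at position {pos} "
                f"in record {self.id!r}"
            )


@dataclass(frozen=True)
class OrfRecord:
    """A called open reading frame.

    ``start``/``end`` are 0-based half-open forward-strand coordinates of the
    full start-to-stop span (stop codon included). ``protein`` excludes the
    terminal stop. ``frame`` is 0..2 on the ORF's own strand.
    """

    genome_id: str
    start: int
    end: int
    strand: str
    frame: int
    protein: str
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError("ORF span must be a multiple of 3")
        if not (0 <= self.start < self.end):
            raise ValueError("require 0 <= start < end")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")

    @property
    def nt_length(self) -> int:
        return self.end - self.start

    @property
    def aa_length(self) -> int:
        return len(self.protein)


def _normalize(seq: str, record_id: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - DNA_ALPHABET
    if bad:
        pos = next(i for i, c in enumerate(s) if c in bad)
        raise ValueError(
            f"illegal character {s[pos]!r} at position {pos} in record {record_id!r}"
        )
    return s


def read_fasta(path: str | os.PathLike) -> list[GenomeRecord]:
    """Read a (multi-)FASTA file into GenomeRecords.

    Sequences are uppercased and RNA U is mapped to T; any character outside
    {A,C,G,T,N} raises with the offending position named.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    records = [
        GenomeRecord(id=rec.id, sequence=_normalize(str(rec.seq), rec.id), source=path)
        for rec in SeqIO.parse(path, "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_genbank(path: str | os.PathLike) -> tuple[GenomeRecord, list[OrfRecord]]:
    """Read a GenBank flat file: sequence plus any annotated CDS features.

    GenBank 1-based inclusive locations become 0-based half-open intervals.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    rec = SeqIO.read(path, "genbank")
    if len(rec.seq) == 0:
        raise ValueError(f"GenBank record in {path} has no ORIGIN sequence")
    genome = GenomeRecord(id=rec.id, sequence=_normalize(str(rec.seq), rec.id), source=path)
    orfs: list[OrfRecord] = []
    for feat in rec.features:
        if feat.type != "CDS":
            continue
        start = int(feat.location.start)
        end = int(feat.location.end)
        strand = "+" if (feat.location.strand or 1) >= 0 else "-"
        span = genome.sequence[start:end]
        cds = span if strand == "+" else revcomp(span)
        if len(cds) % 3:  # malformed annotation; skip rather than fail the genome
            continue
        prot = translate(cds).rstrip("*")
        label = None
        product = feat.qualifiers.get("product") or feat.qualifiers.get("gene")
        if product:
            label = str(product[0])
        frame = start % 3 if strand == "+" else (genome.length - end) % 3
        orfs.append(
            OrfRecord(genome.id, start, end, strand, frame, prot, label=label)
        )
    return genome, orfs


def translate(dna: str, code: int = 11) -> str:
    """Translate a DNA string whose length is a multiple of 3.

    Internal stops render as '*'; codons containing N render as 'X'.
    Default genetic code 11 (bacteria/archaea/phage).
    """
    if len(dna) % 3:
        raise ValueError(f"length {len(dna)} is not a multiple of 3")
    if not dna:
        return ""
    s = _normalize(dna, "<translate>")
    return str(Seq(s).translate(table=code))


def _scan_strand(seq: str, min_len: int, starts: frozenset[str], code: int):
    """Yield (start, end, frame, protein) ORFs on the given sequence, + sense."""
    n = len(seq)
    for frame in range(3):
        orf_start = None  # first start codon since last stop, this frame
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in STOP_CODONS_11:
                if orf_start is not None:
                    end = pos + 3
                    if end - orf_start >= min_len:
                        prot = translate(seq[orf_start:pos], code)
                        yield orf_start, end, frame, prot
                    orf_start = None
            elif orf_start is None and codon in starts:
                orf_start = pos


def find_orfs(
    genome: GenomeRecord,
    min_len: int = 150,
    starts: Iterable[str] = ("ATG",),
    code: int = 11,
) -> list[OrfRecord]:
    """Call all maximal start-to-stop ORFs on both strands, all 3 frames.

    Maximal means: from the first start codon after the previous in-frame stop
    to the next stop. Coordinates are always reported on the forward strand;
    output is sorted by (start, end, strand).
    """
    if min_len < 30 or min_len % 3:
        raise ValueError("min_len must be >= 30 and a multiple of 3")
    starts = frozenset(s.upper() for s in starts)
    out: list[OrfRecord] = []
    for s0, e0, frame, prot in _scan_strand(genome.sequence, min_len, starts, code):
        out.append(OrfRecord(genome.id, s0, e0, "+", frame, prot))
    rc = revcomp(genome.sequence)
    n = genome.length
    for s0, e0, frame, prot in _scan_strand(rc, min_len, starts, code):
        out.append(OrfRecord(genome.id, n - e0, n - s0, "-", frame, prot))
    out.sort(key=lambda o: (o.start, o.end, o.strand))
    return out


def write_orfs_gff3(orfs: Iterable[OrfRecord], path: str | os.PathLike, source: str = "dgrscout") -> None:
    """Write ORFs as GFF3 (1-based inclusive per the standard)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, o in enumerate(orfs, 1):
            attrs = f"ID=orf{i}"
            if o.label:
                attrs += f";Name={o.label}"
            fh.write(
                f"{o.genome_id}\t{source}\tCDS\t{o.start + 1}\t{o.end}\t.\t{o.strand}\t0\t{attrs}\n"
            )


def write_orfs_tsv(orfs: Iterable[OrfRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("# genome_id\tstart\tend\tstrand\tframe\taa_length\tlabel\tprotein\n")
        for o in orfs:
            fh.write(
                f"{o.genome_id}\t{o.start}\t{o.end}\t{o.strand}\t{o.frame}\t"
                f"{o.aa_length}\t{o.label or '.'}\t{o.protein}\n"
            )


def extract_orf_dna(genome: GenomeRecord, orf: OrfRecord) -> str:
    """The ORF's coding sequence 5'->3' on its own strand (stop included)."""
    span = genome.sequence[orf.start : orf.end]
    return span if orf.strand == "+" else revcomp(span)
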
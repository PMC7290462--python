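"""Cohort screening: anchor genes, locus extraction, architecture tabulation.

Workflow per genome: locate conserved anchor genes (tail needle protein and
integration host factor) by translated local alignment against a labelled
protein reference panel, extract the ~7.5 kb region downstream of the TNP
anchor, run cassette detection inside it, and classify the genome's DGR
architecture. The summary tabulates classes, element presence and
round-half-up integer percentages across the cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from Bio.Seq import Seq

from .seq_io import GenomeRecord, OrfRecord, find_orfs, revcomp
from .dgr_core import (
    assemble_cassette,
    classify_architecture,
    detect_rt,
    find_repeat_pairs,
    orient_with_refinement,
)
from ._align import local_protein_alignment

DEFAULT_SCORE_MIN = 60.0
DEFAULT_SPAN = 7_500
DEFAULT_SEED_AA = 6
TRUNCATION_FRACTION = 0.60  # gene shorter than this fraction of its reference is truncated


@dataclass(frozen=True)
class AnchorHit:
    """Best translated-alignment hit of one labelled reference in a genome."""

    genome_id: str
    anchor_label: str
    interval: tuple[int, int]  # genomic, 0-based half-open, forward strand
    strand: str
    score: float
    ref_span: tuple[int, int]  # aligned region on the reference protein
    ref_len: int


@dataclass(frozen=True)
class Region:
    """A genome subsequence carrying its original-coordinate offset."""

    genome_id: str
    sequence: str
    offset: int

    def to_genome(self, pos: int) -> int:
        return self.offset + pos


@dataclass(frozen=True)
class GenomeScreenResult:
    genome_id: str
    cassette_class: str
    architecture: str
    elements: tuple[str, ...]
    anchored: bool
    error: Optional[str] = None


@dataclass(frozen=True)
class CohortSummary:
    per_genome: tuple[GenomeScreenResult, ...]
    counts: dict
    percentages: dict
    element_counts: dict

    def to_json_dict(self) -> dict:
        return {
            "n_genomes": len(self.per_genome),
            "counts": dict(self.counts),
            "percentages": dict(self.percentages),
            "element_counts": dict(self.element_counts),
            "per_genome": [
                {
                    "genome_id": r.genome_id,
                    "class": r.cassette_class,
                    "architecture": r.architecture,
                    "elements": list(r.elements),
                    "anchored": r.anchored,
                    "error": r.error,
                }
                for r in self.per_genome
            ],
        }


def round_half_up_percent(count: int, total: int) -> int:
    """Integer percent with ties rounded up: 15/91 -> 16, 10/91 -> 11."""
    return int(math.floor(100.0 * count / total + 0.5))


# ---------------------------------------------------------------------------
# anchor scanning
# ---------------------------------------------------------------------------

def _frames(genome: GenomeRecord):
    """Six reading-frame translations: (strand, frame, protein)."""
    seq = genome.sequence
    rc = revcomp(seq)
    for strand, s in (("+", seq), ("-", rc)):
        for f in range(3):
            n = (len(s) - f) // 3 * 3
            yield strand, f, str(Seq(s[f : f + n]).translate(table=11))


def _frame_to_genome(strand: str, frame: int, aa_start: int, aa_end: int, n: int) -> tuple[int, int]:
    s = frame + 3 * aa_start
    e = frame + 3 * aa_end
    if strand == "+":
        return s, e
    return n - e, n - s


def anchor_scan(
    genome: GenomeRecord,
    refs: dict[str, str],
    score_min: float = DEFAULT_SCORE_MIN,
    seed_aa: int = DEFAULT_SEED_AA,
) -> list[AnchorHit]:
    """Best local-alignment hit per reference label across six reading frames.

    Exact ``seed_aa``-mer protein seeds select candidate windows; each window
    is aligned with BLOSUM62 Smith-Waterman (the exhaustive all-frame
    alignment is kept as a test oracle). Hits below ``score_min`` are dropped;
    one best hit is retained per label.
    """
    if not refs:
        raise ValueError("empty reference set")
    n = genome.length
    best: dict[str, AnchorHit] = {}
    for strand, frame, prot in _frames(genome):
        index: dict[str, list[int]] = {}
        for i in range(len(prot) - seed_aa + 1):
            index.setdefault(prot[i : i + seed_aa], []).append(i)
        for label, ref in refs.items():
            positions: list[tuple[int, int]] = []
            for r in range(len(ref) - seed_aa + 1):
                for t in index.get(ref[r : r + seed_aa], ()):
                    positions.append((t - r, t))
            if not positions:
                continue
            positions.sort()
            # group seeds into diagonal bands, one window per band
            windows: list[tuple[int, int]] = []
            band_start = 0
            for i in range(1, len(positions) + 1):
                if i == len(positions) or positions[i][0] - positions[i - 1][0] > 30:
                    ts = [t for _, t in positions[band_start:i]]
                    w0 = max(0, min(ts) - len(ref))
                    w1 = min(len(prot), max(ts) + len(ref) + seed_aa)
                    windows.append((w0, w1))
                    band_start = i
            merged: list[list[int]] = []
            for w0, w1 in sorted(windows):
                if merged and w0 <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], w1)
                else:
                    merged.append([w0, w1])
            for w0, w1 in merged:
                score, ref_span, t_span = local_protein_alignment(ref, prot[w0:w1])
                if score < score_min:
                    continue
                g0, g1 = _frame_to_genome(strand, frame, w0 + t_span[0], w0 + t_span[1], n)
                hit = AnchorHit(genome.id, label, (g0, g1), strand, score, ref_span, len(ref))
                if label not in best or score > best[label].score:
                    best[label] = hit
    return sorted(best.values(), key=lambda h: h.interval[0])


def exhaustive_anchor_score(genome: GenomeRecord, ref: str) -> float:
    """Oracle: full Smith-Waterman of a reference against all six frames."""
    return max(local_protein_alignment(ref, prot)[0] for _, _, prot in _frames(genome))


def extract_region(
    genome: GenomeRecord,
    anchor: AnchorHit,
    span: int = DEFAULT_SPAN,
    side: str = "downstream",
) -> Region:
    """Clip a region of up to ``span`` nt adjacent to an anchor hit.

    Downstream/upstream are in forward-strand coordinates; the returned
    Region retains the genomic offset so element calls map back via
    ``region.to_genome``.
    """
    if anchor.genome_id != genome.id:
        raise ValueError("anchor does not belong to this genome")
    a0, a1 = anchor.interval
    if side == "downstream":
        s, e = a1, min(genome.length, a1 + span)
    elif side == "upstream":
        s, e = max(0, a0 - span), a0
    elif side == "both":
        s, e = max(0, a0 - span), min(genome.length, a1 + span)
    else:
        raise ValueError(f"unknown side {side!r}")
    return Region(genome.id, genome.sequence[s:e], s)


# ---------------------------------------------------------------------------
# per-genome screening
# ---------------------------------------------------------------------------

def _overlapping_orf(orfs: Sequence[OrfRecord], interval: tuple[int, int]) -> Optional[OrfRecord]:
    s, e = interval
    best, best_ov = None, 0
    for o in orfs:
        ov = min(o.end, e) - max(o.start, s)
        if ov > best_ov:
            best, best_ov = o, ov
    return best


def screen_genome(
    genome: GenomeRecord,
    refs: dict[str, str],
    score_min: float = DEFAULT_SCORE_MIN,
    span: int = DEFAULT_SPAN,
    **detect_kwargs,
) -> GenomeScreenResult:
    """Classify one genome's DGR architecture between the anchor genes."""
    hits = {h.anchor_label: h for h in anchor_scan(genome, refs, score_min=score_min)}
    anchored = "TNP" in hits
    if anchored:
        region = extract_region(genome, hits["TNP"], span=span, side="downstream")
        sub = GenomeRecord(id=genome.id, sequence=region.sequence, source="region")
        offset = region.offset
    else:
        sub, offset = genome, 0

    orfs = find_orfs(sub)
    pairs = find_repeat_pairs(sub, **{k: v for k, v in detect_kwargs.items()
                                      if k in ("seed_k", "l_min", "l_max", "id_min", "sep_max")})
    oriented = [op for op in (orient_with_refinement(sub, p) for p in pairs)
                if not op.ambiguous]
    # with a reference RT in the panel, reference mode alone decides RT
    # presence; the bare catalytic-motif scan is the no-reference fallback
    rt_refs = {k: v for k, v in refs.items() if k == "RT"} or None
    if rt_refs:
        rts = detect_rt(orfs, mode="reference", refs=rt_refs, score_min=score_min)
    else:
        rts = detect_rt(orfs, mode="motif")
    cassettes = assemble_cassette(sub, orfs, oriented, rts)
    best_cassette = cassettes[0] if cassettes else None

    # target gene: ORF overlapping the T-CFP reference hit (region coordinates)
    tg_orf = None
    tg_ref_len = len(refs.get("T-CFP", "")) or None
    tcfp_hit = hits.get("T-CFP")
    if tcfp_hit is not None:
        h0, h1 = tcfp_hit.interval
        tg_orf = _overlapping_orf([o for o in orfs if o.strand == "+"], (h0 - offset, h1 - offset))
    if tg_orf is None and best_cassette is not None:
        tg_orf = best_cassette.target_gene
    tg_present = tg_orf is not None
    tg_full = tg_present and (tg_ref_len is None or tg_orf.aa_length >= TRUNCATION_FRACTION * tg_ref_len)

    # VR: from a detected repeat pair, else from reference coverage of the
    # target gene's C-terminal repeat region (VRs exist without their TR)
    vr_present = best_cassette is not None
    imh_present = best_cassette is not None and best_cassette.imh is not None
    if not vr_present and tcfp_hit is not None and tg_full and tg_ref_len:
        r0, r1 = tcfp_hit.ref_span
        vr_aa0 = tg_ref_len - 35
        covered = min(r1, tg_ref_len) - max(r0, vr_aa0)
        vr_present = covered >= 0.5 * 35
    tr_present = best_cassette is not None and best_cassette.tr is not None

    rt_ref_len = len(refs.get("RT", "")) or None
    rt_hit = hits.get("RT")
    rt_orf = None
    if rt_hit is not None:
        rt_orf = _overlapping_orf(orfs, (rt_hit.interval[0] - offset, rt_hit.interval[1] - offset))
    if rt_orf is None and rts:
        rt_orf = rts[0]
    rt_present = rt_orf is not None
    rt_full = rt_present and (rt_ref_len is None or rt_orf.aa_length >= TRUNCATION_FRACTION * rt_ref_len)

    order = []
    if tg_orf is not None:
        order.append(("TG", tg_orf.start))
    if best_cassette is not None and best_cassette.tr is not None:
        order.append(("TR", best_cassette.tr[0]))
    if rt_orf is not None:
        order.append(("RT", rt_orf.start))
    label, arch = classify_architecture(
        target_gene_present=tg_present,
        target_full_length=tg_full,
        vr_present=vr_present,
        imh_present=imh_present,
        tr_present=tr_present,
        imh_star_present=imh_present,
        rt_present=rt_present,
        rt_full_length=rt_full,
        order=order or None,
    )
    elements = []
    if tg_present:
        elements.append("T-CFP" if tg_full else "t-cfp'")
    if vr_present:
        elements.append("VR")
    if tr_present:
        elements.append("TR")
    if rt_present:
        elements.append("RT" if rt_full else "rt'")
    return GenomeScreenResult(genome.id, label, arch, tuple(elements), anchored)


def screen_cohort(
    genomes: Sequence[GenomeRecord],
    refs: dict[str, str],
    score_min: float = DEFAULT_SCORE_MIN,
    span: int = DEFAULT_SPAN,
    **detect_kwargs,
) -> CohortSummary:
    """Screen a cohort and tabulate architecture classes.

    Per-genome failures are recorded in the result rather than raised; every
    genome receives exactly one class and counts sum to the cohort size.
    """
    if not genomes:
        raise ValueError("no genomes")
    results = []
    for g in genomes:
        try:
            results.append(screen_genome(g, refs, score_min=score_min, span=span, **detect_kwargs))
        except Exception as exc:  # error isolation: one genome must not sink the screen
            results.append(GenomeScreenResult(g.id, "error", "", (), False, error=str(exc)))
    counts: dict[str, int] = {}
    for r in results:
        counts[r.cassette_class] = counts.get(r.cassette_class, 0) + 1
    total = len(results)
    percentages = {cls: round_half_up_percent(c, total) for cls, c in counts.items()}
    element_counts: dict[str, int] = {}
    for r in results:
        for el in {e.rstrip("'").upper() for e in r.elements}:
            element_counts[el] = element_counts.get(el, 0) + 1
    return CohortSummary(tuple(results), counts, percentages, element_counts)


def summary_to_tsv(summary: CohortSummary, path) -> None:
    import pandas as pd

    df = pd.DataFrame(
        [
            {
                "genome_id": r.genome_id,
                "class": r.cassette_class,
                "architecture": r.architecture,
                "elements": ",".join(r.elements),
                "anchored": r.anchored,
                "error": r.error or "",
            }
            for r in summary.per_genome
        ]
    )
    with open(path, "w") as fh:
        fh.write("# per-genome DGR screen\n")
        df.to_csv(fh, sep="\t", index=False)


def architecture_report(summary: CohortSummary) -> str:
    """Group genomes by architecture string, most common first."""
    groups: dict[str, list[str]] = {}
    for r in summary.per_genome:
        groups.setdefault(r.architecture or "(none)", []).append(r.genome_id)
    lines = ["architecture\tn_genomes\tgenomes"]
    for arch, ids in sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0])):
        lines.append(f"{arch}\t{len(ids)}\t{','.join(ids)}")
    return "\n".join(lines) + "\n"
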
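"""Candidate DGR cassette detection.

Pipeline: seed-and-extend repeat-pair discovery -> TR/VR orientation by
adenine bias of the mismatched columns -> IMH/IMH* boundary annotation at the
repeats' 3' ends -> reverse-transcriptase (RT) gene identification -> cassette
assembly and architecture classification.

The directionality rule is the biological one: during mutagenic retrohoming
the RT copies the TR through an error-prone cDNA in which adenines are
substituted, so at mismatched alignment columns the template copy carries A.
"""

from __future__ import annotations

import re
from math import comb
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .seq_io import GenomeRecord, OrfRecord, revcomp

# Repeat-finder defaults bracket a 105-nt repeat pair at ~78-80% identity
# (35 codons, ~21-23 mismatches) with margin on both sides.
DEFAULT_SEED_K = 12
DEFAULT_L_MIN = 50
DEFAULT_L_MAX = 200
DEFAULT_ID_MIN = 0.70
DEFAULT_SEP_MAX = 10_000
DEFAULT_BIAS_THRESHOLD = 0.80
DEFAULT_IMH_MIN_LEN = 10
DEFAULT_TG_TOL = 50
DEFAULT_RT_MAX_DIST = 5_000

# Ungapped extension scores. Log-likelihood-ratio motivated: inside a repeat
# pair columns match with p~0.8, in AT-rich background with p~0.27, giving
# log(0.8/0.27) : log(0.2/0.73) ~ +1 : -1.2. The max-score extent is then the
# maximum-likelihood repeat boundary.
MATCH_SCORE = 1.0
MISMATCH_SCORE = -1.2
XDROP = 15.0


@dataclass(frozen=True)
class AlignedColumn:
    position_a: int
    position_b: int
    base_a: str
    base_b: str
    match: bool


@dataclass(frozen=True)
class RepeatPair:
    """A gap-free aligned pair of near-identical genomic segments.

    Intervals are 0-based half-open on the forward strand; ``interval_a`` is
    the leftmost copy. ``inverted`` marks a pair whose second copy matched on
    the reverse strand (interval_b still given in forward coordinates).
    """

    genome_id: str
    interval_a: tuple[int, int]
    interval_b: tuple[int, int]
    alignment: tuple[AlignedColumn, ...]
    inverted: bool = False

    @property
    def length(self) -> int:
        return len(self.alignment)

    @property
    def n_matches(self) -> int:
        return sum(c.match for c in self.alignment)

    @property
    def identity(self) -> float:
        return self.n_matches / self.length

    @property
    def mismatched_columns(self) -> tuple[AlignedColumn, ...]:
        return tuple(c for c in self.alignment if not c.match)

    @property
    def separation(self) -> int:
        return self.interval_b[0] - self.interval_a[1]


@dataclass(frozen=True)
class OrientedRepeatPair:
    """A repeat pair with TR/VR roles assigned by adenine bias.

    ``adenine_bias`` is the fraction of mismatched columns whose TR-copy base
    is adenine. ``ambiguous`` is set when neither copy (or both) reaches the
    bias threshold; no orientation is asserted for ambiguous pairs.
    """

    pair: RepeatPair
    tr_interval: Optional[tuple[int, int]]
    vr_interval: Optional[tuple[int, int]]
    adenine_bias: float
    ambiguous: bool

    @property
    def genome_id(self) -> str:
        return self.pair.genome_id

    def tr_is_a(self) -> Optional[bool]:
        if self.ambiguous:
            return None
        return self.tr_interval == self.pair.interval_a


@dataclass(frozen=True)
class ImhAnnotation:
    """IMH / IMH* intervals: the exact-match 3'-terminal run of VR and TR."""

    imh_interval: tuple[int, int]
    imh_star_interval: tuple[int, int]
    length: int
    identical: bool


@dataclass(frozen=True)
class DgrCassette:
    genome_id: str
    target_gene: Optional[OrfRecord]
    target_full_length: bool
    vr: Optional[tuple[int, int]]
    tr: Optional[tuple[int, int]]
    imh: Optional[ImhAnnotation]
    rt: Optional[OrfRecord]
    rt_full_length: bool
    architecture: str
    cassette_class: str  # complete | incomplete | absent
    score: float
    oriented: Optional[OrientedRepeatPair] = None


# ---------------------------------------------------------------------------
# repeat-pair discovery
# ---------------------------------------------------------------------------

def _extend_ungapped(seq_a: str, seq_b: str, i: int, j: int, k: int,
                     limit_left: int = 10**9, limit_right: int = 10**9):
    """X-drop ungapped extension of a seed match seq_a[i:i+k] == seq_b[j:j+k].

    Returns (off_left, off_right): the max-score extent is
    a[i-off_left : i+k+off_right] vs the same offsets on b.
    """
    # right
    best = cur = 0.0
    best_r = 0
    t = 0
    max_r = min(len(seq_a) - (i + k), len(seq_b) - (j + k), limit_right)
    while t < max_r:
        cur += MATCH_SCORE if seq_a[i + k + t] == seq_b[j + k + t] else MISMATCH_SCORE
        t += 1
        if cur > best:
            best, best_r = cur, t
        elif best - cur > XDROP:
            break
    # left
    best = cur = 0.0
    best_l = 0
    t = 0
    max_l = min(i, j, limit_left)
    while t < max_l:
        cur += MATCH_SCORE if seq_a[i - 1 - t] == seq_b[j - 1 - t] else MISMATCH_SCORE
        t += 1
        if cur > best:
            best, best_l = cur, t
        elif best - cur > XDROP:
            break
    return best_l, best_r


def _polish_extent(seq: str, a0: int, a1: int, diag: int,
                   run_len: int = 3, edge_window: int = 12) -> tuple[int, int]:
    """Trim boundary overshoot from an ungapped extent.

    A gap-free repeat pair at ~80% identity almost never contains a run of
    ``run_len`` consecutive mismatch columns, whereas an extension that
    overshot into unrelated flanking sequence usually does. Any such run
    within ``edge_window`` columns of either end is cut off together with
    everything outside it; residual terminal mismatch columns are stripped.
    """
    def is_match(p: int) -> bool:
        return seq[p] == seq[p + diag]

    changed = True
    while changed and a1 - a0 > 0:
        changed = False
        limit = min(a0 + edge_window, a1 - run_len + 1)
        for i in range(a0, limit):
            if all(not is_match(p) for p in range(i, i + run_len)):
                a0 = i + run_len
                changed = True
                break
        limit = max(a1 - edge_window, a0 + run_len - 1)
        for i in range(a1 - 1, limit - 1, -1):
            if all(not is_match(p) for p in range(i - run_len + 1, i + 1)):
                a1 = i - run_len
                changed = True
                break
        while a1 > a0 and not is_match(a0):
            a0 += 1
            changed = True
        while a1 > a0 and not is_match(a1 - 1):
            a1 -= 1
            changed = True
    return a0, a1


def _columns(genome_id: str, seq: str, a0: int, b0: int, length: int) -> tuple[AlignedColumn, ...]:
    return tuple(
        AlignedColumn(a0 + t, b0 + t, seq[a0 + t], seq[b0 + t], seq[a0 + t] == seq[b0 + t])
        for t in range(length)
    )


def find_repeat_pairs(
    genome: GenomeRecord,
    seed_k: int = DEFAULT_SEED_K,
    l_min: int = DEFAULT_L_MIN,
    l_max: int = DEFAULT_L_MAX,
    id_min: float = DEFAULT_ID_MIN,
    sep_max: int = DEFAULT_SEP_MAX,
) -> list[RepeatPair]:
    """Find near-identical direct repeat pairs by k-mer seeding and gap-free
    X-drop extension.

    Every reported pair satisfies: aligned length in [l_min, l_max], identity
    >= id_min, non-overlapping intervals separated by <= sep_max. Pairs are
    deduplicated by extent and by containment (highest identity*length kept),
    and returned ordered by (leftmost coordinate, -score).
    """
    seq = genome.sequence
    n = len(seq)
    if n < 2 * l_min:
        return []
    index: dict[str, list[int]] = {}
    for i in range(n - seed_k + 1):
        kmer = seq[i : i + seed_k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)

    seen_diag_pos: set[tuple[int, int]] = set()  # (diagonal, representative a-start)
    extents: dict[tuple[int, int, int, int], None] = {}
    for kmer, positions in index.items():
        if len(positions) < 2:
            continue
        for ai in range(len(positions) - 1):
            for bi in range(ai + 1, len(positions)):
                i, j = positions[ai], positions[bi]
                if j - i > sep_max + l_max:
                    continue
                diag = j - i
                off_l, off_r = _extend_ungapped(seq, seq, i, j, seed_k)
                a0, a1 = i - off_l, i + seed_k + off_r
                key = (diag, a0)
                if key in seen_diag_pos:
                    continue
                seen_diag_pos.add(key)
                a0, a1 = _polish_extent(seq, a0, a1, diag)
                b0, b1 = a0 + diag, a1 + diag
                length = a1 - a0
                if length < l_min:
                    continue
                if seq[a0:a0 + 5] == "NNNNN" or seq[a1 - 5:a1] == "NNNNN":
                    continue
                if not (l_min <= length <= l_max):
                    continue
                if a1 > b0:  # copies overlap
                    continue
                if b0 - a1 > sep_max:
                    continue
                matches = sum(1 for t in range(length) if seq[a0 + t] == seq[b0 + t])
                if matches / length < id_min:
                    continue
                extents[(a0, a1, b0, b1)] = None

    pairs = [
        RepeatPair(genome.id, (a0, a1), (b0, b1), _columns(genome.id, seq, a0, b0, a1 - a0))
        for (a0, a1, b0, b1) in extents
    ]
    pairs.sort(key=lambda p: (-(p.identity * p.length), p.interval_a[0], p.interval_b[0]))
    kept: list[RepeatPair] = []
    for p in pairs:
        contained = any(
            p.interval_a[0] >= q.interval_a[0] and p.interval_a[1] <= q.interval_a[1]
            and p.interval_b[0] >= q.interval_b[0] and p.interval_b[1] <= q.interval_b[1]
            for q in kept
        )
        if not contained:
            kept.append(p)
    kept.sort(key=lambda p: (p.interval_a[0], -(p.identity * p.length), p.interval_b[0]))
    return kept


# ---------------------------------------------------------------------------
# orientation, IMH
# ---------------------------------------------------------------------------

def assign_tr_vr(pair: RepeatPair, bias_threshold: float = DEFAULT_BIAS_THRESHOLD) -> OrientedRepeatPair:
    """Assign TR/VR roles: the TR is the copy carrying adenine at mismatched
    columns (the A-to-N signature). If both or neither copy reaches
    ``bias_threshold``, or the pair has no mismatches, the orientation is
    flagged ambiguous.
    """
    mism = pair.mismatched_columns
    if not mism:
        return OrientedRepeatPair(pair, None, None, 0.0, ambiguous=True)
    frac_a = sum(1 for c in mism if c.base_a == "A") / len(mism)
    frac_b = sum(1 for c in mism if c.base_b == "A") / len(mism)
    a_q = frac_a >= bias_threshold
    b_q = frac_b >= bias_threshold
    if a_q == b_q:
        return OrientedRepeatPair(pair, None, None, max(frac_a, frac_b), ambiguous=True)
    if a_q:
        return OrientedRepeatPair(pair, pair.interval_a, pair.interval_b, frac_a, ambiguous=False)
    return OrientedRepeatPair(pair, pair.interval_b, pair.interval_a, frac_b, ambiguous=False)


def detect_imh(oriented: OrientedRepeatPair, min_len: int = DEFAULT_IMH_MIN_LEN) -> Optional[ImhAnnotation]:
    """IMH = the maximal run of exactly matching aligned columns at the 3' end
    of the repeats (IMH on the VR, IMH* on the TR). Annotated only when the
    run reaches ``min_len``.
    """
    if oriented.ambiguous:
        raise ValueError("cannot annotate IMH on an ambiguous pair")
    cols = oriented.pair.alignment
    run = 0
    for c in reversed(cols):
        if c.match:
            run += 1
        else:
            break
    if run < min_len:
        return None
    vr0, vr1 = oriented.vr_interval
    tr0, tr1 = oriented.tr_interval
    imh = (vr1 - run, vr1)
    imh_star = (tr1 - run, tr1)
    # exact-match columns imply identity, but re-derive the flag from bases
    identical = all(c.base_a == c.base_b for c in cols[len(cols) - run :])
    return ImhAnnotation(imh, imh_star, run, identical)


# ---------------------------------------------------------------------------
# RT identification
# ---------------------------------------------------------------------------

# RT catalytic core: x-x-D-D with an aromatic/aliphatic first position,
# e.g. the canonical YxDD / YMDD of reverse transcriptases.
RT_MOTIF = re.compile(r"[YLFVIM].DD")
RT_MIN_AA = 150
RT_MAX_AA = 900


def detect_rt(
    orfs: Sequence[OrfRecord],
    mode: str = "motif",
    refs: Optional[dict[str, str]] = None,
    score_min: float = 60.0,
) -> list[OrfRecord]:
    """Flag ORFs encoding a putative reverse transcriptase.

    motif mode: ORFs of 150-900 aa whose translation contains the RT
    catalytic pattern x-x-D-D (first position in {Y,L,F,V,I,M}).
    reference mode: ORFs whose BLOSUM62 local-alignment score against any
    supplied reference protein exceeds ``score_min``.
    """
    if mode == "motif":
        return [
            replace(o, label="RT")
            for o in orfs
            if RT_MIN_AA <= o.aa_length <= RT_MAX_AA and RT_MOTIF.search(o.protein)
        ]
    if mode == "reference":
        if not refs:
            raise ValueError("reference mode requires a non-empty reference panel")
        from ._align import local_protein_score

        out = []
        for o in orfs:
            if any(local_protein_score(o.protein, ref) > score_min for ref in refs.values()):
                out.append(replace(o, label="RT"))
        return out
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# cassette assembly and classification
# ---------------------------------------------------------------------------

def classify_architecture(
    target_gene_present: bool,
    target_full_length: bool,
    vr_present: bool,
    imh_present: bool,
    tr_present: bool,
    imh_star_present: bool,
    rt_present: bool,
    rt_full_length: bool,
    order: Optional[Sequence[tuple[str, int]]] = None,
) -> tuple[str, str]:
    """Classify a cassette and render its architecture string.

    complete  <=> full-length target gene + VR + IMH + TR + IMH* + full-length RT
    absent    <=> no DGR element present at all
    otherwise incomplete. The architecture string concatenates the present
    elements 5'->3'; ``order`` optionally supplies (element, genomic start)
    pairs to order them, otherwise the canonical order is used. Truncated
    genes render lower-case with a prime (tg', rt').
    """
    present: dict[str, str] = {}
    if target_gene_present:
        tg = "TG" if target_full_length else "tg'"
        present["TG"] = tg + ("-VR(IMH)" if vr_present and imh_present else "-VR" if vr_present else "")
    elif vr_present:
        present["TG"] = "VR(IMH)" if imh_present else "VR"
    if tr_present:
        present["TR"] = "TR(IMH*)" if imh_star_present else "TR"
    if rt_present:
        present["RT"] = "RT" if rt_full_length else "rt'"

    if not present:
        return "absent", ""
    if (
        target_gene_present and target_full_length and vr_present and imh_present
        and tr_present and imh_star_present and rt_present and rt_full_length
    ):
        label = "complete"
    else:
        label = "incomplete"
    canonical = ["TG", "TR", "RT"]
    if order:
        rank = {e: s for e, s in order}
        canonical.sort(key=lambda e: rank.get(e, 10**9))
    arch = "-".join(present[e] for e in canonical if e in present)
    return label, arch


# Orientation-aware boundary scores: once the TR copy is known, a mismatch
# at a TR-adenine column is expected under A-to-N mutagenesis (log-odds vs
# background near 0), while a non-adenine mismatch is strong evidence the
# column lies outside the repeat.
REFINE_MATCH = 1.0
REFINE_A_MISMATCH = -0.2
REFINE_OTHER_MISMATCH = -2.0


def refine_boundaries(
    genome: GenomeRecord,
    op: OrientedRepeatPair,
    margin: int = 25,
    l_min: int = DEFAULT_L_MIN,
) -> OrientedRepeatPair:
    """Re-estimate repeat boundaries knowing which copy is the TR.

    Columns in a window around the detected extent are scored match +1,
    TR-adenine mismatch -0.2, other mismatch -2, and the maximum-sum
    contiguous segment becomes the new extent. This keeps 5' stretches of
    substituted adenines inside the repeat (a plain identity-based extension
    trims them) while rejecting overshoot into unrelated flanking sequence.
    """
    if op.ambiguous:
        return op
    seq = genome.sequence
    vr0, vr1 = op.vr_interval
    tr0, tr1 = op.tr_interval
    diag = tr0 - vr0  # signed; columns pair seq[v] with seq[v + diag]
    gap = abs(op.pair.interval_b[0] - op.pair.interval_a[1])
    m = max(0, min(margin, (gap - 1) // 2))
    lo = max(0, vr0 - m, -diag)
    hi = min(len(seq), vr1 + m, len(seq) - diag)

    def score(v: int) -> float:
        a, b = seq[v], seq[v + diag]
        if a == b:
            return REFINE_MATCH
        return REFINE_A_MISMATCH if b == "A" else REFINE_OTHER_MISMATCH

    best_sum = cur = 0.0
    best = (vr0, vr1)
    cur_start = lo
    for v in range(lo, hi):
        s = score(v)
        if cur <= 0:
            cur, cur_start = s, v
        else:
            cur += s
        if cur > best_sum:
            best_sum, best = cur, (cur_start, v + 1)
    nv0, nv1 = best
    # anchor the 3' boundary on the last long exact-match run: the repeats
    # end in the exact IMH/IMH* suffix, so columns past it are overshoot
    suffix_run = 6
    j = nv1
    while j - suffix_run >= nv0 and not all(
        seq[v] == seq[v + diag] for v in range(j - suffix_run, j)
    ):
        j -= 1
    if j - suffix_run >= nv0 and nv1 - j <= 20:
        nv1 = j
    while nv1 > nv0 and seq[nv0] != seq[nv0 + diag]:
        nv0 += 1
    if nv1 - nv0 < l_min:
        return op
    nt0, nt1 = nv0 + diag, nv1 + diag
    first0 = min(nv0, nt0)
    length = nv1 - nv0
    cols = _columns(genome.id, seq, first0, first0 + abs(diag), length)
    pair = RepeatPair(genome.id, (first0, first0 + length),
                      (first0 + abs(diag), first0 + abs(diag) + length), cols)
    mism = pair.mismatched_columns
    if mism:
        tr_left = nt0 < nv0
        bias = sum(1 for c in mism if (c.base_a if tr_left else c.base_b) == "A") / len(mism)
    else:
        bias = op.adenine_bias
    return OrientedRepeatPair(pair, (nt0, nt1), (nv0, nv1), bias, False)


def orient_with_refinement(
    genome: GenomeRecord,
    pair: RepeatPair,
    bias_threshold: float = DEFAULT_BIAS_THRESHOLD,
) -> OrientedRepeatPair:
    """Orient a pair, resolving borderline cases by boundary refinement.

    A raw extent whose adenine-dense 5' prefix was trimmed can sit just below
    the bias threshold. When the plain rule is ambiguous, both TR hypotheses
    are refined and the bias rule is re-applied on the refined alignment; the
    orientation is accepted only if exactly one hypothesis becomes (and
    stays) unambiguous.
    """
    op = assign_tr_vr(pair, bias_threshold)
    if not op.ambiguous:
        return refine_boundaries(genome, op)
    if not pair.mismatched_columns:
        return op
    winners = []
    for tr_iv, vr_iv in ((pair.interval_a, pair.interval_b),
                         (pair.interval_b, pair.interval_a)):
        hyp = OrientedRepeatPair(pair, tr_iv, vr_iv, 0.0, ambiguous=False)
        ref = refine_boundaries(genome, hyp)
        op2 = assign_tr_vr(ref.pair, bias_threshold)
        if not op2.ambiguous and op2.tr_interval == ref.tr_interval:
            winners.append(op2)
    if len(winners) == 1:
        return winners[0]
    if len(winners) == 2 and winners[0].tr_interval == winners[1].tr_interval:
        return max(winners, key=lambda w: w.adenine_bias)
    # sign test on which copy carries A at mismatched columns: decisive
    # asymmetry (one-sided binomial p < alpha under H0 p=0.5) orients the
    # pair even when the bias fraction sits below the threshold
    alpha = 0.01
    mism = pair.mismatched_columns
    n_a = sum(1 for c in mism if c.base_a == "A")
    n_b = sum(1 for c in mism if c.base_b == "A")
    n = n_a + n_b
    if n:
        k = max(n_a, n_b)
        p_tail = sum(comb(n, i) for i in range(k, n + 1)) / 2 ** n
        if p_tail < alpha and n_a != n_b:
            if n_a > n_b:
                hyp = OrientedRepeatPair(pair, pair.interval_a, pair.interval_b,
                                         n_a / len(mism), ambiguous=False)
            else:
                hyp = OrientedRepeatPair(pair, pair.interval_b, pair.interval_a,
                                         n_b / len(mism), ambiguous=False)
            return refine_boundaries(genome, hyp)
    return op


def _snap_to_gene(genome: GenomeRecord, op: OrientedRepeatPair, target: OrfRecord) -> OrientedRepeatPair:
    """Snap a VR/TR pair to the target gene's codon grid.

    The VR sits in-frame at the gene's 3' end, so its start is moved outward
    to the nearest codon boundary and its end to the gene's stop codon when
    within 3 nt; the TR moves by the same offsets (the alignment is
    gap-free). The oriented pair is rebuilt from the adjusted intervals.
    """
    vr0, vr1 = op.vr_interval
    tr0, tr1 = op.tr_interval
    shift = (vr0 - target.start) % 3
    if shift and vr0 - shift >= 0 and tr0 - shift >= 0:
        vr0 -= shift
        tr0 -= shift
    stop_pos = target.end - 3
    delta = stop_pos - vr1
    if delta != 0 and abs(delta) <= 3:
        n = genome.length
        if vr1 + delta <= n and tr1 + delta <= n:
            vr1 += delta
            tr1 += delta
    if (vr0, vr1) == op.vr_interval and (tr0, tr1) == op.tr_interval:
        return op
    first = min(vr0, tr0)
    diag = abs(tr0 - vr0)
    length = vr1 - vr0
    cols = _columns(genome.id, genome.sequence, first, first + diag, length)
    pair = RepeatPair(genome.id, (first, first + length),
                      (first + diag, first + diag + length), cols)
    if vr0 < tr0:
        return OrientedRepeatPair(pair, (tr0, tr1), (vr0, vr1), op.adenine_bias, False)
    return OrientedRepeatPair(pair, (vr0, vr1), (tr0, tr1), op.adenine_bias, False)


def assemble_cassette(
    genome: GenomeRecord,
    orfs: Sequence[OrfRecord],
    oriented_pairs: Sequence[OrientedRepeatPair],
    rts: Sequence[OrfRecord],
    imh_min_len: int = DEFAULT_IMH_MIN_LEN,
    tg_tol: int = DEFAULT_TG_TOL,
    rt_max_dist: int = DEFAULT_RT_MAX_DIST,
) -> list[DgrCassette]:
    """Assemble candidate cassettes around oriented repeat pairs.

    For each unambiguous pair: the target gene is the forward-strand ORF whose
    span contains the VR and whose stop lies within ``tg_tol`` nt of the VR
    3' end; the RT is the nearest RT-labelled ORF within ``rt_max_dist`` nt of
    the TR. Cassettes are scored identity * adenine_bias * (1 if IMH else 0.5)
    and returned best-first (ties by leftmost coordinate).
    """
    cassettes: list[DgrCassette] = []
    for op in oriented_pairs:
        if op.ambiguous:
            continue
        op = refine_boundaries(genome, op)
        vr0, vr1 = op.vr_interval
        tr0, tr1 = op.tr_interval

        target = None
        for o in orfs:
            if o.strand != "+":
                continue
            if o.start <= vr0 and vr1 <= o.end and abs((o.end - 3) - vr1) <= tg_tol:
                if target is None or o.nt_length > target.nt_length:
                    target = o
        if target is not None:
            op = _snap_to_gene(genome, op, target)
            vr0, vr1 = op.vr_interval
            tr0, tr1 = op.tr_interval
        imh = detect_imh(op, min_len=imh_min_len)
        rt = None
        best_d = rt_max_dist + 1
        for o in rts:
            d = max(o.start - tr1, tr0 - o.end, 0)
            if d < best_d:
                best_d, rt = d, o
        label, arch = classify_architecture(
            target_gene_present=target is not None,
            target_full_length=target is not None,
            vr_present=True,
            imh_present=imh is not None,
            tr_present=True,
            imh_star_present=imh is not None,
            rt_present=rt is not None,
            rt_full_length=rt is not None,
            order=[("TG", vr0), ("TR", tr0), ("RT", rt.start if rt else 10**9)],
        )
        score = op.pair.identity * op.adenine_bias * (1.0 if imh else 0.5)
        cassettes.append(
            DgrCassette(
                genome_id=genome.id,
                target_gene=target,
                target_full_length=target is not None,
                vr=(vr0, vr1),
                tr=(tr0, tr1),
                imh=imh,
                rt=rt,
                rt_full_length=rt is not None,
                architecture=arch,
                cassette_class=label,
                score=score,
                oriented=op,
            )
        )
    cassettes.sort(key=lambda c: (-c.score, c.vr[0] if c.vr else 10**9))
    return cassettes


def vr_tr_sequences(genome: GenomeRecord, cassette: DgrCassette) -> tuple[str, str, int]:
    """Extract the gap-free aligned VR and TR sequences of a cassette for
    mutagenesis analysis, with the VR's frame offset in its target gene.

    When a forward-strand target gene is assigned, the VR start (and the TR
    start, by the same shift — the alignment is gap-free) is snapped outward
    to the gene's codon boundary, so codon arithmetic downstream is exact.
    """
    if cassette.vr is None or cassette.tr is None:
        raise ValueError("cassette lacks a VR/TR pair")
    vr0, vr1 = cassette.vr
    tr0, tr1 = cassette.tr
    frame_offset = 0
    tg = cassette.target_gene
    if tg is not None and tg.strand == "+":
        shift = (vr0 - tg.start) % 3
        if shift and vr0 - shift >= 0 and tr0 - shift >= 0:
            vr0 -= shift
            tr0 -= shift
    return genome.sequence[vr0:vr1], genome.sequence[tr0:tr1], frame_offset


def detect_cassettes(
    genome: GenomeRecord,
    orf_min_len: int = 150,
    rt_mode: str = "motif",
    rt_refs: Optional[dict[str, str]] = None,
    **kwargs,
) -> list[DgrCassette]:
    """Convenience end-to-end detection on one genome: ORF calling,
    repeat-pair discovery, orientation, RT identification, assembly."""
    from .seq_io import find_orfs

    finder_keys = {"seed_k", "l_min", "l_max", "id_min", "sep_max"}
    finder_kwargs = {k: v for k, v in kwargs.items() if k in finder_keys}
    asm_kwargs = {k: v for k, v in kwargs.items() if k not in finder_keys}
    orfs = find_orfs(genome, min_len=orf_min_len)
    pairs = find_repeat_pairs(genome, **finder_kwargs)
    oriented = [orient_with_refinement(genome, p) for p in pairs]
    rts = detect_rt(orfs, mode=rt_mode, refs=rt_refs)
    return assemble_cassette(genome, orfs, oriented, rts, **asm_kwargs)
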
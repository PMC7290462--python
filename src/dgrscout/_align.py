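"""Protein local-alignment helpers (BLOSUM62 via Biopython)."""

from __future__ import annotations

from functools import lru_cache


@lru_cache(maxsize=1)
def _aligner():
    from Bio.Align import PairwiseAligner, substitution_matrices

    aln = PairwiseAligner()
    aln.mode = "local"
    aln.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aln.open_gap_score = -11
    aln.extend_gap_score = -1
    return aln


def _sanitize(prot: str) -> str:
    # BLOSUM62 lacks rows for some ambiguity codes; map them to X which it has
    allowed = set("ARNDCQEGHILKMFPSTWYVBZX*")
    return "".join(c if c in allowed else "X" for c in prot)


def local_protein_score(query: str, target: str) -> float:
    """Smith-Waterman score (BLOSUM62, gap open -11 / extend -1)."""
    if not query or not target:
        return 0.0
    return float(_aligner().score(_sanitize(query), _sanitize(target)))


def local_protein_alignment(query: str, target: str):
    """Best local alignment; returns (score, query_span, target_span) with
    0-based half-open spans of the aligned region."""
    if not query or not target:
        return 0.0, (0, 0), (0, 0)
    alns = _aligner().align(_sanitize(query), _sanitize(target))
    best = alns[0]
    q = best.aligned[0]
    t = best.aligned[1]
    q_span = (int(q[0][0]), int(q[-1][1]))
    t_span = (int(t[0][0]), int(t[-1][1]))
    return float(best.score), q_span, t_span
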
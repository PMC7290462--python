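"""A-to-N mutagenesis statistics, theoretical diversity, and sequence logos.

A DGR's reverse transcriptase substitutes positions that are adenine in the
template repeat (TR), so a TR with A adenines can theoretically write
4^A distinct DNA sequences into the variable repeat (VR). Because codons
diversify independently, the number of distinct protein sequences is the
product over codons of the number of distinct translation outcomes reachable
by substituting that codon's adenines.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .seq_io import translate

BASES = "ACGT"
AA20 = "ACDEFGHIKLMNPQRSTVWY"
MAX_INFO_BITS = math.log2(20)


@dataclass(frozen=True)
class MutagenesisReport:
    """Per-pair A-to-N statistics of a gap-free VR/TR alignment."""

    n_codons: int
    n_adenines_tr: int
    n_aton_variable: int
    n_non_aton: int
    variable_positions: tuple[tuple[int, str, str], ...]  # (offset, tr_base, vr_base)

    @property
    def n_mismatches(self) -> int:
        return self.n_aton_variable + self.n_non_aton


@dataclass(frozen=True)
class DiversitySummary:
    n_adenines: int
    dna_variants: int
    dna_order_of_magnitude: int
    protein_variants: int
    protein_order_of_magnitude: int
    stop_handling: str


@dataclass(frozen=True)
class PositionLogo:
    """Per-column amino-acid frequencies and information content (bits)."""

    alignment_depth: int
    columns: tuple[dict[str, float], ...]
    information_content: tuple[float, ...]


def compare_vr_tr(vr: str, tr: str, frame_offset: int = 0) -> MutagenesisReport:
    """Classify every VR/TR mismatch as A-to-N (TR base is adenine) or not.

    The pair must be the aligned gap-free (equal-length) repeat sequences;
    ``frame_offset`` is the number of bases before the first complete codon.
    """
    if len(vr) != len(tr):
        raise ValueError(f"VR ({len(vr)}) and TR ({len(tr)}) lengths differ; supply the gap-free aligned pair")
    if frame_offset not in (0, 1, 2):
        raise ValueError("frame_offset must be 0, 1 or 2")
    vr, tr = vr.upper(), tr.upper()
    variable = []
    n_aton = n_non = 0
    for i, (tb, vb) in enumerate(zip(tr, vr)):
        if tb != vb:
            variable.append((i, tb, vb))
            if tb == "A":
                n_aton += 1
            else:
                n_non += 1
    return MutagenesisReport(
        n_codons=(len(tr) - frame_offset) // 3,
        n_adenines_tr=tr.count("A"),
        n_aton_variable=n_aton,
        n_non_aton=n_non,
        variable_positions=tuple(variable),
    )


def _codon_outcomes(codon: str, stop_handling: str, code: int = 11) -> int:
    """Number of distinct translation outcomes over all substitutions of the
    codon's adenines (each A independently replaced by any base)."""
    a_idx = [i for i, b in enumerate(codon) if b == "A"]
    outs = set()
    for combo in itertools.product(BASES, repeat=len(a_idx)):
        var = list(codon)
        for i, b in zip(a_idx, combo):
            var[i] = b
        outs.add(translate("".join(var), code))
    if stop_handling == "exclude":
        outs.discard("*")
    return len(outs)


def _oom(x: int) -> int:
    return round(math.log10(x)) if x > 0 else 0


def diversity(tr: str, frame_offset: int = 0, stop_handling: str = "exclude") -> DiversitySummary:
    """Exact theoretical diversity generated by A-to-N mutagenesis of a TR.

    ``dna_variants`` = 4^(adenine count), exact big-integer arithmetic.
    ``protein_variants`` multiplies per-codon distinct-outcome counts (codons
    are independent). With ``stop_handling='exclude'`` (default), variant
    codons translating to stop are removed from each codon's outcome set, so
    the product counts exactly the stop-free protein variants.
    Orders of magnitude are round(log10(value)).
    """
    if not tr:
        raise ValueError("empty sequence")
    if stop_handling not in ("exclude", "include"):
        raise ValueError("stop_handling must be 'exclude' or 'include'")
    if len(tr) - frame_offset < 3:
        raise ValueError("need at least one complete codon")
    tr = tr.upper()
    n_a = tr.count("A")
    dna = 4 ** n_a
    prot = 1
    for i in range(frame_offset, len(tr) - 2, 3):
        prot *= _codon_outcomes(tr[i : i + 3], stop_handling)
    return DiversitySummary(n_a, dna, _oom(dna), prot, _oom(prot), stop_handling)


def diversity_bruteforce(tr: str, frame_offset: int = 0, stop_handling: str = "exclude",
                         max_adenines: int = 10) -> DiversitySummary:
    """Independent oracle for :func:`diversity`: explicitly enumerate all 4^A
    DNA variants, translate each, and count distinct sequences. Bounded to
    small adenine counts by construction."""
    if not tr:
        raise ValueError("empty sequence")
    tr = tr.upper()
    a_idx = [i for i, b in enumerate(tr) if b == "A"]
    if len(a_idx) > max_adenines:
        raise ValueError(f"{len(a_idx)} adenines exceeds enumeration bound {max_adenines}")
    n_codons_end = frame_offset + 3 * ((len(tr) - frame_offset) // 3)
    dna_set, prot_set = set(), set()
    for combo in itertools.product(BASES, repeat=len(a_idx)):
        var = list(tr)
        for i, b in zip(a_idx, combo):
            var[i] = b
        s = "".join(var)
        dna_set.add(s)
        p = translate(s[frame_offset:n_codons_end])
        if stop_handling == "exclude" and "*" in p:
            continue
        prot_set.add(p)
    dna, prot = len(dna_set), len(prot_set)
    return DiversitySummary(len(a_idx), dna, _oom(dna), prot, _oom(prot), stop_handling)


def build_logo(aligned_aa: Sequence[str], small_sample_correction: bool = False) -> PositionLogo:
    """Per-column amino-acid frequencies and information content of a gap-free
    protein alignment (gap '-' permitted; gaps are excluded from counts).

    Information content R = log2(20) - H, with H the column Shannon entropy in
    bits over the counted symbols. The optional small-sample correction
    subtracts the standard e_n = 19 / (2 * ln 2 * n) term (off by default,
    matching common sequence-logo practice for moderate depths).
    """
    if not aligned_aa:
        raise ValueError("empty alignment")
    width = len(aligned_aa[0])
    if any(len(s) != width for s in aligned_aa):
        raise ValueError("sequences must be equal length")
    depth = len(aligned_aa)
    columns: list[dict[str, float]] = []
    info: list[float] = []
    for j in range(width):
        counts: dict[str, int] = {}
        for s in aligned_aa:
            c = s[j].upper()
            if c == "-":
                continue
            if c not in AA20:
                raise ValueError(f"unexpected symbol {c!r} in column {j}")
            counts[c] = counts.get(c, 0) + 1
        n = sum(counts.values())
        if n == 0:
            columns.append({})
            info.append(0.0)
            continue
        freqs = {aa: k / n for aa, k in sorted(counts.items())}
        h = -sum(f * math.log2(f) for f in freqs.values())
        r = MAX_INFO_BITS - h
        if small_sample_correction:
            r -= 19.0 / (2.0 * math.log(2.0) * n)
        info.append(max(0.0, min(r, MAX_INFO_BITS)))
        columns.append(freqs)
    return PositionLogo(depth, tuple(columns), tuple(info))


def logo_to_tsv(logo: PositionLogo, path) -> None:
    """Write a position x residue frequency matrix with an information-content
    column."""
    with open(path, "w") as fh:
        fh.write("# position\t" + "\t".join(AA20) + "\tinformation_bits\n")
        for j, (col, r) in enumerate(zip(logo.columns, logo.information_content), 1):
            row = "\t".join(f"{col.get(aa, 0.0):.6g}" for aa in AA20)
            fh.write(f"{j}\t{row}\t{r:.6g}\n")


def render_logo(logo: PositionLogo, path) -> None:
    """Render a simple stacked-letter logo with matplotlib (optional extra)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(4, 0.3 * len(logo.columns)), 2.5))
    for j, (col, r) in enumerate(zip(logo.columns, logo.information_content)):
        y = 0.0
        for aa, f in sorted(col.items(), key=lambda kv: kv[1]):
            h = f * r
            ax.text(j + 0.5, y + h / 2, aa, ha="center", va="center",
                    fontsize=6 + 10 * f, family="monospace")
            y += h
    ax.set_xlim(0, len(logo.columns))
    ax.set_ylim(0, MAX_INFO_BITS)
    ax.set_xlabel("position")
    ax.set_ylabel("bits")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
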
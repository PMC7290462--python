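"""Synthetic genomes with planted DGR cassettes and machine-readable truth.

The generator emulates the statistical structure the detection pipeline
assumes: an AT-rich ~100 kb phage-like genome carrying, in genomic order, a
tail-needle-protein (TNP) anchor gene, a tail-collar-fiber-protein-like
(T-CFP) target gene whose 3' end is the variable repeat (VR), an intergenic
template repeat (TR) sharing an exact 3'-terminal IMH/IMH* with the VR, a
reverse-transcriptase (RT) gene carrying the x-x-D-D catalytic motif, a
hypothetical-protein (HP) gene, and an integration-host-factor (IHF) anchor —
plus truncation/deletion variants of that cassette and element-free loci.

All anchor/target/RT coding sequences come from a deterministic synthetic
reference panel (fixed internal seed), so the cohort is homogeneous the way
a phage genus is: anchors identical across genomes, VRs diversified
per genome. Every output is a pure function of (spec, seed).

Two properties are built into the simulation so that planted coordinates are
well-defined ground truth: each planted ORF is framed by an upstream in-frame
stop codon (the maximal-ORF caller then reports exactly the planted span),
and the three bases flanking each side of the TR are forced to differ from
the bases flanking the VR (the repeat boundary is therefore sharp).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .seq_io import GenomeRecord, translate
from .mutagenesis import diversity

BASES = "ACGT"
NON_STOP_CODONS = tuple(
    a + b + c
    for a in BASES for b in BASES for c in BASES
    if a + b + c not in ("TAA", "TAG", "TGA")
)

CLASS_COMPLETE = "complete"
CLASS_ABSENT = "absent"
VARIANT_TG_TRUNCATED = "incomplete-tg-truncated"
VARIANT_TR_DELETED = "incomplete-tr-deleted"
VARIANT_RT_TRUNCATED = "incomplete-rt-truncated"
INCOMPLETE_VARIANTS = (VARIANT_TG_TRUNCATED, VARIANT_TR_DELETED, VARIANT_RT_TRUNCATED)
ALL_CLASSES = (CLASS_COMPLETE, CLASS_ABSENT) + INCOMPLETE_VARIANTS

_PANEL_SEED = 900913  # fixed: the synthetic reference panel is part of the package
DEFAULT_GENOME_LEN = 98_458
DEFAULT_GC = 0.35

# panel protein lengths (aa, excluding stop)
_TNP_AA = 300
_IHF_AA = 100
_HP_AA = 150
_TCFP_AA = 486
_RT_AA = 350
_TRUNC_FRACTION = 0.40  # truncated variants keep this fraction of the gene


@dataclass(frozen=True)
class CassetteSpec:
    """Parameters of one planted cassette.

    ``p_aton`` is the substitution probability per TR adenine outside the IMH
    (each substituted adenine becomes one of {C,G,T} uniformly);
    ``non_aton_rate`` the per-position substitution probability at non-adenine
    positions outside the IMH. ``n_aton``/``n_non_aton``, when given, plant an
    exact number of substitutions instead of Bernoulli draws.
    ``protect_5prime`` excludes the first bases of the repeat from
    substitution (used by the worked-example locus so its boundaries carry no
    sampling noise). ``tr_seq`` overrides TR sampling with a fixed template
    (the cohort generator passes the shared panel TR).
    """

    class_label: str = CLASS_COMPLETE
    tr_codons: int = 35
    adenine_fraction: float = 0.27
    p_aton: float = 0.7
    non_aton_rate: float = 0.02
    imh_len: int = 14
    rt_len_aa: int = _RT_AA
    seed: int = 0
    n_aton: Optional[int] = None
    n_non_aton: Optional[int] = None
    protect_5prime: int = 0
    tr_seq: Optional[str] = None

    def __post_init__(self) -> None:
        for p in (self.adenine_fraction, self.p_aton, self.non_aton_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0,1]")
        if self.tr_codons < 5:
            raise ValueError("tr_codons must be >= 5")
        if self.imh_len >= 3 * self.tr_codons:
            raise ValueError("imh_len must be shorter than the TR")
        if self.class_label not in ALL_CLASSES and self.class_label != "incomplete":
            raise ValueError(f"unknown cassette class {self.class_label!r}")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one emitted genome (0-based half-open intervals)."""

    genome_id: str
    class_label: str
    elements: dict  # name -> (start, end); names: TNP,T-CFP,VR,TR,IMH,IMH*,RT,HP,IHF
    substitutions: tuple[tuple[int, str, str], ...]  # (offset in repeat, tr_base, vr_base)
    spec: CassetteSpec

    def to_json_dict(self) -> dict:
        return {
            "genome_id": self.genome_id,
            "class": self.class_label,
            "elements": {k: list(v) for k, v in self.elements.items()},
            "substitutions": [list(s) for s in self.substitutions],
            "spec": dataclasses.asdict(self.spec),
        }


# ---------------------------------------------------------------------------
# reference panel
# ---------------------------------------------------------------------------

def _random_cds(rng: np.random.Generator, n_aa: int) -> str:
    codons = rng.choice(len(NON_STOP_CODONS), size=n_aa)
    return "".join(NON_STOP_CODONS[i] for i in codons)


def _sample_tr(rng: np.random.Generator, n_codons: int, adenine_fraction: float) -> str:
    """One TR draw with adenine placement biased to codon positions 1-2,
    where substitutions diversify the protein (as in real DGR templates)."""
    f = adenine_fraction * 3.0
    # split the target adenine mass 40/40/20 across codon positions
    p_a = [min(0.95, 0.4 * f), min(0.95, 0.4 * f), min(0.95, 0.2 * f)]
    out = []
    for _ in range(n_codons):
        while True:
            codon = "".join(
                "A" if rng.random() < p_a[k] else "TGC"[rng.integers(3)] for k in range(3)
            )
            if codon not in ("TAA", "TAG", "TGA"):
                break
        out.append(codon)
    return "".join(out)


def _panel_tr(rng: np.random.Generator) -> str:
    """The shared 35-codon panel TR.

    Drawn to carry the summary statistics of the locus the simulation
    emulates: exactly 28 adenines (>= 23 outside the 14-nt IMH), no in-frame
    stops, and a theoretical protein diversity of order 10^16 under the
    stop-excluding convention.
    """
    for _ in range(100_000):
        tr = _sample_tr(rng, 35, 28 / 105)
        if tr.count("A") != 28:
            continue
        if tr[:-14].count("A") < 23:
            continue
        d = diversity(tr, stop_handling="exclude")
        if d.protein_order_of_magnitude != 16:
            continue
        if diversity(tr, stop_handling="include").protein_order_of_magnitude != 16:
            continue
        return tr
    raise RuntimeError("panel TR sampling failed")  # pragma: no cover


_panel_cache: Optional[dict] = None


def reference_panel() -> dict:
    """The deterministic synthetic reference panel.

    Returns a dict with per-label nucleotide CDS (stop included) and protein
    sequences for TNP, IHF, HP, RT and T-CFP, plus the shared panel TR
    (``tr``). The T-CFP reference carries the TR translation as its
    C-terminal 35 codons.
    """
    global _panel_cache
    if _panel_cache is not None:
        return _panel_cache
    rng = np.random.default_rng(_PANEL_SEED)
    tnp = "ATG" + _random_cds(rng, _TNP_AA - 1) + "TAA"
    ihf = "ATG" + _random_cds(rng, _IHF_AA - 1) + "TAA"
    hp = "ATG" + _random_cds(rng, _HP_AA - 1) + "TAA"
    # RT: x-x-D-D catalytic motif (YMDD) planted mid-protein
    rt_aa_pos = 200
    rt = "ATG" + _random_cds(rng, _RT_AA - 1)
    rt = rt[: 3 * rt_aa_pos] + "TATATGGATGAT" + rt[3 * (rt_aa_pos + 4) :]
    rt += "TAA"
    tr = _panel_tr(rng)
    tcfp = "ATG" + _random_cds(rng, _TCFP_AA - 1 - 35) + tr + "TAA"
    panel = {
        "tr": tr,
        "cds": {"TNP": tnp, "IHF": ihf, "HP": hp, "RT": rt, "T-CFP": tcfp},
        "protein": {
            label: translate(cds).rstrip("*")
            for label, cds in
            {"TNP": tnp, "IHF": ihf, "HP": hp, "RT": rt, "T-CFP": tcfp}.items()
        },
    }
    _panel_cache = panel
    return panel


def write_reference_panel(path, labels=("TNP", "IHF", "HP", "RT", "T-CFP")) -> None:
    """Write the synthetic reference proteins as a labelled FASTA panel."""
    panel = reference_panel()
    with open(path, "w") as fh:
        for label in labels:
            fh.write(f">{label} synthetic reference\n{panel['protein'][label]}\n")


# ---------------------------------------------------------------------------
# TR -> VR mutagenesis
# ---------------------------------------------------------------------------

def mutate_tr_to_vr(
    tr: str,
    spec: CassetteSpec,
    rng: Optional[np.random.Generator] = None,
    avoid_stops: bool = True,
) -> tuple[str, tuple[tuple[int, str, str], ...]]:
    """Derive a VR from a TR by adenine-specific substitution.

    Each adenine outside the ``imh_len`` 3'-terminal suffix is substituted
    with probability ``p_aton`` (uniformly to {C,G,T}); each non-adenine
    position outside the suffix with probability ``non_aton_rate``. With
    exact counts (``n_aton``/``n_non_aton``) the positions are sampled
    without replacement instead. The IMH suffix is never touched. When
    ``avoid_stops`` is set, draws creating an in-frame stop codon are
    rejected and redrawn (the VR sits inside a coding gene).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = len(tr)
    mutable = range(spec.protect_5prime, n - spec.imh_len)
    a_pos = [i for i in mutable if tr[i] == "A"]
    non_a_pos = [i for i in mutable if tr[i] != "A"]

    for _ in range(10_000):
        if spec.n_aton is not None:
            if spec.n_aton > len(a_pos):
                raise ValueError("n_aton exceeds eligible adenine positions")
            sub_a = sorted(rng.choice(a_pos, size=spec.n_aton, replace=False)) if spec.n_aton else []
        else:
            sub_a = [i for i in a_pos if rng.random() < spec.p_aton]
        if spec.n_non_aton is not None:
            if spec.n_non_aton > len(non_a_pos):
                raise ValueError("n_non_aton exceeds eligible positions")
            sub_n = sorted(rng.choice(non_a_pos, size=spec.n_non_aton, replace=False)) if spec.n_non_aton else []
        else:
            sub_n = [i for i in non_a_pos if rng.random() < spec.non_aton_rate]
        vr = list(tr)
        log = []
        for i in sorted(list(sub_a) + list(sub_n)):
            old = tr[i]
            choices = [b for b in BASES if b != old]
            new = choices[int(rng.integers(3))]
            vr[i] = new
            log.append((int(i), old, new))
        vr_s = "".join(vr)
        if avoid_stops and any(
            vr_s[i : i + 3] in ("TAA", "TAG", "TGA") for i in range(0, n - 2, 3)
        ):
            continue
        return vr_s, tuple(log)
    raise RuntimeError("could not draw a stop-free VR")  # pragma: no cover


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------

def _background(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n, p=p)


def _truncate_cds(cds: str, fraction: float) -> str:
    """Keep the 5' ``fraction`` of the codons and close with a stop."""
    n_codons = (len(cds) - 3) // 3
    keep = max(1, int(n_codons * fraction))
    return cds[: 3 * keep] + "TAA"


def generate_genome_with_cassette(
    spec: CassetteSpec,
    genome_len: int = DEFAULT_GENOME_LEN,
    gc: float = DEFAULT_GC,
    genome_id: Optional[str] = None,
) -> tuple[GenomeRecord, SyntheticTruth]:
    """Emit one genome with a planted locus of the requested class.

    The locus (TNP ... IHF) is written over i.i.d. background at roughly one
    third of the genome. Truth records the planted intervals, class and the
    exact VR/TR substitution log.
    """
    if genome_len < 20_000:
        raise ValueError("genome_len must be >= 20,000")
    label = spec.class_label
    rng = np.random.default_rng(spec.seed)
    panel = reference_panel()
    arr = _background(rng, genome_len, gc)

    tr = spec.tr_seq
    if tr is None and label not in (CLASS_ABSENT,):
        tr = _sample_tr(rng, spec.tr_codons, spec.adenine_fraction)
    spacer = lambda: int(60 + rng.integers(60))

    # decide element presence per class
    tg_full = label in (CLASS_COMPLETE, VARIANT_TR_DELETED, VARIANT_RT_TRUNCATED)
    tg_trunc = label == VARIANT_TG_TRUNCATED
    tr_present = label in (CLASS_COMPLETE, VARIANT_RT_TRUNCATED)
    rt_full = label in (CLASS_COMPLETE, VARIANT_TR_DELETED)
    rt_trunc = label in (VARIANT_TG_TRUNCATED, VARIANT_RT_TRUNCATED)

    elements: dict[str, tuple[int, int]] = {}
    subs: tuple[tuple[int, str, str], ...] = ()
    parts: list[tuple[Optional[str], str]] = []  # (element name, sequence)

    parts.append(("TNP", panel["cds"]["TNP"]))
    parts.append((None, "x" * spacer()))
    vr = None
    if tg_full:
        vr, subs = mutate_tr_to_vr(tr, spec, rng)
        tcfp_cds = panel["cds"]["T-CFP"][: -(105 + 3)] + vr + "TAA"
        parts.append(("T-CFP", tcfp_cds))
    elif tg_trunc:
        parts.append(("T-CFP", _truncate_cds(panel["cds"]["T-CFP"], _TRUNC_FRACTION)))
    parts.append((None, "x" * spacer()))
    if tr_present:
        parts.append(("TR", tr))
        parts.append((None, "x" * spacer()))
    if rt_full:
        parts.append(("RT", panel["cds"]["RT"]))
    elif rt_trunc:
        parts.append(("RT", _truncate_cds(panel["cds"]["RT"], _TRUNC_FRACTION)))
    parts.append((None, "x" * spacer()))
    parts.append(("HP", panel["cds"]["HP"]))
    parts.append((None, "x" * spacer()))
    parts.append(("IHF", panel["cds"]["IHF"]))

    locus_start = genome_len // 3
    pos = locus_start
    for name, seq_part in parts:
        if name is not None:
            # frame the ORF: in-frame stop immediately upstream of its start
            arr[pos - 3 : pos] = np.frombuffer(b"TAA", dtype="S1")
            arr[pos : pos + len(seq_part)] = np.frombuffer(seq_part.encode(), dtype="S1")
            elements[name] = (pos, pos + len(seq_part))
        pos += len(seq_part)

    if "T-CFP" in elements and tg_full:
        tg0, tg1 = elements["T-CFP"]
        elements["VR"] = (tg1 - 3 - len(tr), tg1 - 3)
        vr0, vr1 = elements["VR"]
        elements["IMH"] = (vr1 - spec.imh_len, vr1)
    if "TR" in elements:
        tr0, tr1 = elements["TR"]
        elements["IMH*"] = (tr1 - spec.imh_len, tr1)
        # sharpen the repeat boundary: TR flanks must mismatch the VR flanks
        if "VR" in elements:
            vr0, vr1 = elements["VR"]
            genome_bytes = arr
            for k in range(1, 4):
                for tpos, vpos in (((tr0 - k), (vr0 - k)), ((tr1 + k - 1), (vr1 + k - 1))):
                    vb = genome_bytes[vpos].decode()
                    choices = [b for b in BASES if b != vb]
                    genome_bytes[tpos] = choices[int(rng.integers(3))].encode()

    gid = genome_id or f"synth_{label.replace('incomplete-', 'inc_')}_{spec.seed}"
    genome = GenomeRecord(id=gid, sequence=arr.tobytes().decode(), source="synthetic")
    truth = SyntheticTruth(gid, label, elements, subs, spec)
    return genome, truth


# ---------------------------------------------------------------------------
# cohorts and the worked-example locus
# ---------------------------------------------------------------------------

def generate_cohort(
    n: int,
    class_mix: dict[str, int],
    base_spec: CassetteSpec = CassetteSpec(),
    seed: int = 0,
    genome_len: int = DEFAULT_GENOME_LEN,
    gc: float = DEFAULT_GC,
) -> tuple[list[GenomeRecord], list[SyntheticTruth]]:
    """Emit ``n`` genomes with the given class mix, deterministically shuffled.

    The generic key ``"incomplete"`` cycles through the three incomplete
    variants. Per-genome seeds are ``seed + index``. All genomes share the
    panel TR (anchors and templates are conserved within a genus; only the
    VRs vary).
    """
    if sum(class_mix.values()) != n:
        raise ValueError(f"class mix sums to {sum(class_mix.values())}, expected {n}")
    labels: list[str] = []
    for cls, count in sorted(class_mix.items()):
        if cls == "incomplete":
            labels.extend(INCOMPLETE_VARIANTS[i % 3] for i in range(count))
        elif cls in ALL_CLASSES:
            labels.extend([cls] * count)
        else:
            raise ValueError(f"unknown class {cls!r}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    labels = [labels[i] for i in order]
    genomes, truths = [], []
    tr_seq = base_spec.tr_seq or reference_panel()["tr"]
    for idx, lbl in enumerate(labels):
        spec = dataclasses.replace(base_spec, class_label=lbl, seed=seed + idx, tr_seq=tr_seq)
        g, t = generate_genome_with_cassette(
            spec, genome_len=genome_len, gc=gc, genome_id=f"cohort{seed}_g{idx:03d}"
        )
        genomes.append(g)
        truths.append(t)
    return genomes, truths


def flagship_spec(seed: int = 11) -> CassetteSpec:
    """Spec of the synthetic worked-example locus.

    A stand-in for a deposited crAss-like phage cassette, constructed to
    carry that locus's published summary statistics: a 35-codon TR with 28
    adenines, exactly 21 A-to-N and 2 non-A-to-N substitutions in the VR, a
    14-nt IMH, a 486-aa target protein and a 98,458 bp genome. Substitutions
    avoid the repeat's first four bases so the planted boundaries are exact.
    """
    return CassetteSpec(
        class_label=CLASS_COMPLETE,
        tr_seq=reference_panel()["tr"],
        n_aton=21,
        n_non_aton=2,
        imh_len=14,
        protect_5prime=4,
        seed=seed,
    )


def generate_flagship(seed: int = 11) -> tuple[GenomeRecord, SyntheticTruth]:
    """The synthetic worked-example genome (see :func:`flagship_spec`)."""
    return generate_genome_with_cassette(
        flagship_spec(seed), genome_len=DEFAULT_GENOME_LEN, gc=DEFAULT_GC,
        genome_id=f"synthetic_standin_s{seed}",
    )


def write_truth_json(truths, path) -> None:
    with open(path, "w") as fh:
        json.dump([t.to_json_dict() for t in truths], fh, indent=1)


def write_truth_bed(truths, path) -> None:
    with open(path, "w") as fh:
        for t in truths:
            for name, (s, e) in sorted(t.elements.items(), key=lambda kv: kv[1]):
                fh.write(f"{t.genome_id}\t{s}\t{e}\t{name}\n")
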
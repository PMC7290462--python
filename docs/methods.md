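# Methods

## The model

A diversity-generating retroelement (DGR) couples a reverse transcriptase
(RT) to a pair of ~100 nt repeats. The template repeat (TR) is the invariant
donor; the variable repeat (VR), sitting in-frame at the 3' end of a target
gene, is overwritten through an error-prone cDNA of the TR in which adenines
are replaced essentially at random (A-to-N mutagenesis). Short elements at
the repeats' 3' ends (IMH on the VR, IMH* on the TR) delimit the diversified
region. The package detects this structure from sequence alone, quantifies
the mutagenesis, and tabulates cassette architectures across genome cohorts.

Working assumptions, reflected throughout:

* the VR/TR alignment is gap-free (retrohoming preserves length);
* mismatched columns carry adenine on the TR side far more often than
  chance — this asymmetry is what orients the pair;
* the repeats end in a shared exact-match suffix; the IMH is therefore
  *defined operationally* as the maximal 3'-terminal run of exactly matching
  columns (its true sequence and length are not independently known), and
  the `identical` flag is recorded but never enforced;
* the target gene lies on the forward strand with the VR at its 3' end.

## Detection pipeline and its numerical choices

**Repeat discovery.** Exact 12-mer seeds are extended without gaps under
X-drop (drop-off 15) with scores match +1.0 / mismatch −1.2. The scores are
log-likelihood motivated: columns match with p ≈ 0.8 inside a repeat pair
and p ≈ 0.27 in AT-rich background, giving log(0.8/0.27) : log(0.2/0.73)
≈ 1 : −1.2, so the max-score extent is the maximum-likelihood boundary.
Extents are then polished: a run of ≥ 3 consecutive mismatch columns within
12 columns of either end marks overshoot into unrelated flanking sequence
(the interior of an ~80%-identity pair almost never contains one) and is cut
off together with everything outside it. Pairs must satisfy length ∈
[50, 200] nt, identity ≥ 0.70, separation ≤ 10 kb, non-overlapping copies;
deduplication is by extent and containment; ordering is by leftmost
coordinate with identity×length as tie-break, making output deterministic.

**Orientation.** The copy whose bases at mismatched columns are adenine at a
fraction ≥ 0.80 becomes the TR; if both or neither copy qualifies the pair
is flagged ambiguous and no orientation is asserted. The 0.80 default
tolerates the occasional non-A-to-N mismatch seen in real pairs (e.g. 21 of
23 mismatches at adenine ≈ 0.91). The pipeline resolves borderline cases in
two stages rather than lowering the threshold: (1) boundaries are refined
under each orientation hypothesis and the rule re-applied — a trimmed
adenine-dense 5' prefix often hides the signal; (2) if still ambiguous, a
sign test on which copy carries adenine at mismatched columns (one-sided
binomial, α = 0.01 under H0 p = 0.5) may orient the pair: 10-vs-1 asymmetry
is decisive evidence even when the bias fraction sits below 0.80. Pairs that
fail both stay ambiguous and are excluded from assembly.

**Orientation-aware boundary refinement.** Once the TR copy is known,
columns in a ±25 nt window are re-scored match +1, TR-adenine mismatch −0.2,
other mismatch −2 (again log-odds: an A-to-N mismatch is *expected* inside
the repeat), and the maximum-sum contiguous segment becomes the extent. This
keeps substituted-adenine stretches at the 5' end inside the repeat, where a
plain identity score trims them. Because real repeats end in the exact
IMH/IMH* suffix, the 3' boundary is then anchored on the last run of 6
consecutive exactly matching columns (searched within 20 columns of the
refined end); repeats lacking such a suffix keep the unanchored boundary.

**Assembly.** The target gene is the forward-strand ORF containing the VR
whose stop lies within 50 nt of the VR 3' end; when one is assigned, the
repeat boundaries are snapped to the gene's codon grid (start outward to the
codon boundary, end to the stop codon when within 3 nt), so downstream codon
arithmetic is exact. The RT is the nearest RT-labelled ORF within 5 kb of
the TR — by the catalytic x-x-D-D motif (first residue in {Y,L,F,V,I,M},
ORF length 150–900 aa) or by BLOSUM62 local alignment against supplied
references (gap open −11 / extend −1, default score floor 60). Cassettes are
scored identity × adenine-bias × (1 if IMH found else 0.5) and tie-broken by
leftmost coordinate.

**Classification.** `complete` requires full-length target gene + VR + IMH +
TR + IMH* + full-length RT; `absent` means no DGR element at all; everything
else is `incomplete`. A gene is called truncated when its ORF is shorter
than 60% of the supplied reference protein. Architecture strings concatenate
the present elements 5'→3' (`TG-VR(IMH)-TR(IMH*)-RT`; truncated genes
lower-case with a prime, e.g. `tg'-VR-rt'`).

**Cohort screen.** Anchors (tail needle protein, integration host factor,
target gene, RT) are located by translated local alignment across six
reading frames: exact 6-aa seeds select diagonal bands, each band is aligned
with BLOSUM62 Smith-Waterman in a window, and the best hit per label is
kept (an exhaustive all-frame alignment is retained as a test oracle). The
~7.5 kb region downstream of the TNP anchor is screened; genomes without the
anchor are scanned whole and flagged `unanchored` rather than dropped. A VR
without its TR is still reported when the full-length target gene's
C-terminal repeat region aligns to the reference target protein (coverage of
≥ half of the reference's last 35 codons) — this mirrors real cohorts where
many genomes keep a VR but have lost the TR, and it requires the reference
panel to carry the genus's template-derived C-terminus. Percentages are
rounded half-up to integer percent; with a 91-genome cohort the classes
15/66/10 therefore print as 16/73/11 (10/91 is 11%, whatever rounding is
used — a published 9% for that fraction cannot be reproduced by arithmetic
and is not forced). Per-genome failures are recorded, not fatal.

## Diversity arithmetic

`dna_variants = 4^A` exactly (arbitrary precision), with A the adenine count
of the TR. `protein_variants` multiplies per-codon counts of distinct
translation outcomes reachable by substituting that codon's adenines —
exact because codons diversify independently. Stop handling defaults to
`exclude` (variant codons translating to stop are removed from each codon's
outcome set, so the product counts exactly the stop-free proteins); both
conventions are computed since published order-of-magnitude figures rarely
state one. Orders of magnitude are `round(log10(x))`, which renders
4^28 = 7.2×10^16 as ~10^17. `diversity_bruteforce` enumerates all 4^A
variants explicitly (bounded at 10 adenines) and is the independent oracle.

Logo columns count the 20 amino acids only (gaps reduce effective depth);
information content is R = log2(20) − H in bits, clamped to [0, log2 20];
the small-sample correction e_n = 19/(2·ln2·n) is available but off by
default, matching common sequence-logo practice.

## The synthetic generator

The generator emulates the statistical structure the detector assumes, not
any particular genome: i.i.d. background at GC 0.35 (crAss-like genomes are
AT-rich), default length 98,458 bp, and a planted locus in genomic order
TNP · T-CFP(VR-IMH) · TR-IMH* · RT · HP · IHF spanning ~5 kb. Default
cassette parameters: 35-codon TR at adenine fraction 0.27 (≈ 28/105),
substitution probability 0.7 per eligible adenine (uniform over {C,G,T}),
0.02 per non-adenine position, 14-nt inviolate IMH, 350-aa RT carrying
x-x-D-D. All coding sequences come from a deterministic synthetic reference
panel (fixed internal seed), so cohorts are homogeneous the way a phage
genus is; cohorts share the panel TR while each genome draws its own VR.
Incomplete variants mirror the observed architecture classes: truncated
target gene + truncated RT without repeats; TR deleted (VR retained); RT
truncated. Truncations keep the 5' 40% of the gene.

Three simulation-only conveniences make planted coordinates exact ground
truth: planted ORFs are framed by an upstream in-frame stop (the maximal-ORF
caller then reports exactly the planted span); the three bases flanking each
side of the TR are forced to differ from the VR's flanks (the repeat
boundary is sharp); VR draws creating an in-frame stop are rejected (the VR
sits inside a coding gene). Real data offer none of these guarantees — nor
i.i.d. background, codon-usage structure, or gapped repeat pairs — so
passing synthetic tests demonstrates correct mechanics and calibrated
boundary recovery under the stated noise model, not field performance.

The worked-example genome (`generate_flagship`) is a synthetic stand-in for
a deposited crAss-like phage cassette, constructed to carry that locus's
published summary statistics: exactly 28 adenines in the 35-codon TR
(≥ 23 outside the IMH), exactly 21 A-to-N and 2 non-A-to-N substitutions, a
486-aa target protein, protein-diversity order of magnitude 16, and a
98,458 bp genome; its substitutions avoid the repeat's first four bases so
the planted boundaries carry no sampling noise. The template satisfying
these constraints is found once by seeded rejection sampling with adenines
biased to codon positions 1–2 (where substitutions diversify the protein,
as in real DGR templates).

## Problem sizes and determinism

Tests and the acceptance script use 50 planted genomes for end-to-end
recovery and a 91-genome cohort (15 complete / 66 incomplete / 10 absent)
for the partition check — cohort sizes chosen to match the study design the
generator emulates. Every output is a pure function of explicit seeds;
repeated runs are byte-identical.

## Known limitations

* Gap-free repeat model: pairs with indels are neither detected nor
  analysed (flagged out of scope upstream).
* Target genes on the reverse strand are not assembled into cassettes
  (repeats themselves are found regardless of strand).
* Reference-free VR calling requires a detected TR; orphan VRs are only
  recognised via a reference target protein.
* The RT motif scan is a coarse filter; distinguishing DGR RTs from other
  RT classes needs reference- or profile-based evidence.
* Detection thresholds are calibrated for repeats of roughly 50–200 nt at
  ≥ 70% identity; shorter or more diverged cassettes fall outside the
  defaults.
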
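# dgrscout

Detection and analysis of **diversity-generating retroelements (DGRs)** in
phage and bacterial genomes, built around the cassette architecture found in
crAss-like gut phages.

A DGR diversifies a target gene (TG) by error-prone reverse transcription: an
RNA copy of a **template repeat (TR)** is reverse-transcribed by the
cassette's own reverse transcriptase (RT) with adenine-specific infidelity,
and the resulting cDNA overwrites the **variable repeat (VR)** at the 3' end
of the target gene (*mutagenic retrohoming*). Substitutions therefore occur
specifically at positions that are adenine in the TR (**A-to-N
mutagenesis**), delimited by short *initiation of mutagenic homing* elements
(IMH at the VR 3' end, IMH* at the TR 3' end). A complete cassette reads
`TG-VR(IMH)-TR(IMH*)-RT` along the genome.

For a TR carrying *A* adenines the mutagenesis can theoretically write

&nbsp;&nbsp;&nbsp;&nbsp;N<sub>DNA</sub> = 4<sup>A</sup>

distinct DNA sequences into the VR; because codons diversify independently,
the number of distinct protein variants is the exact product over codons of
each codon's reachable translation outcomes. With A = 28 adenines in a
35-codon TR this is 4^28 ≈ 10^17 DNA and ~10^16 protein sequences.

## What the package does

* `dgrscout.seq_io` — FASTA/GenBank input, ORF calling (both strands, all
  frames), translation (genetic code 11), GFF3/TSV export. Coordinates are
  0-based half-open on the forward strand throughout.
* `dgrscout.dgr_core` — cassette detection: k-mer seeded, gap-free X-drop
  repeat-pair discovery; TR/VR orientation by the adenine bias of mismatched
  columns; orientation-aware boundary refinement; IMH/IMH* annotation as the
  maximal exact-match 3' suffix; RT identification by catalytic x-x-D-D
  motif or BLOSUM62 local alignment against references; cassette assembly
  and architecture classification (`complete` / `incomplete` / `absent`).
* `dgrscout.mutagenesis` — A-to-N statistics of a VR/TR pair, exact
  big-integer diversity counts (with a brute-force enumeration oracle), and
  sequence-logo position frequencies with information content
  R = log2(20) − H.
* `dgrscout.cohort` — cohort screening between conserved anchor genes (tail
  needle protein, integration host factor): translated local-alignment
  anchor scan, ~7.5 kb locus extraction, per-genome architecture calls and
  prevalence tabulation.
* `dgrscout.synthetic_data` — generator of ~100 kb AT-rich phage-like
  genomes with planted cassettes (and truncation/deletion variants) plus
  machine-readable ground truth, so the whole pipeline is testable offline.
* `dgrscout.cli` — `dgrscout detect | stats | screen | logo | simulate`.

## Worked example

Generate a genome carrying one complete planted cassette and detect it:

```bash
dgrscout simulate --n 1 --cassette-class complete --seed 5 --out sim
dgrscout detect sim/genomes.fasta --out out
```

`out/cassettes.json` then contains (abridged):

```json
{
  "class": "complete",
  "architecture": "TG-VR(IMH)-TR(IMH*)-RT",
  "target_protein_aa": 486,
  "mutagenesis": {"n_codons": 35, "n_adenines_tr": 28,
                  "n_aton_variable": 20, "n_non_aton": 1},
  "diversity": {"dna_order_of_magnitude": 17,
                "protein_order_of_magnitude": 16}
}
```

Reading: the detected cassette is complete; its TR spans 35 codons with 28
adenines, of which 20 were observed substituted in the VR (plus 1 mismatch
not at a TR adenine); 4^28 adenine substitutions could generate ~10^17 DNA
and ~10^16 protein variants of the 486-aa target. Quick statistics on any
aligned VR/TR pair, without detection:

```bash
dgrscout stats --vr ACGTTTGCA --tr AAATTTGCA
```

Real genomes in GenBank format (e.g. a downloaded flat file of a crAss-like
phage) go through the same entry point: `dgrscout detect genome.gb`.

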
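# scdkit

Stop-codon density analysis for noncoding RNA sequences.

Spliced long noncoding RNAs are bound by the same serine/arginine-rich
splicing factors as protein-coding pre-mRNA, through short exonic
splice-enhancer (ESE) motifs concentrated near exon 5′ ends.  Because
ESEs that function inside coding exons cannot introduce in-frame stop
codons, they are themselves depleted of TAA/TAG/TGA — and that
depletion can carry over into noncoding transcripts that reuse the same
motifs, lowering their stop-codon content below what their nucleotide
composition predicts and inflating the lengths of spurious open reading
frames.  `scdkit` provides the full analysis stack for quantifying this
effect: coverage densities, compositionally matched codon-set controls,
dinucleotide-matched motif nulls, shuffle-based sequence nulls,
enrichment statistics, exon-region analysis, pseudo-ORF length null
models, and a synthetic cohort generator for end-to-end validation.
It is aimed at molecular-evolution researchers studying sequence
composition constraints in noncoding RNA.

## The core metric and statistics

For a sequence *S* of length *L* and a query motif set *M*, the
**coverage density** is

    density(S, M) = |{ i : position i lies inside an occurrence of some m ∈ M }| / L

with every position counted once however many occurrences overlap it, so
0 ≤ density ≤ 1.  The **stop-codon density** (SCD) is this metric for
M = {TAA, TAG, TGA}, scanned at every offset (all three frames).

Observed statistics *O* are compared with *n* null simulants (shuffled
sequences or dinucleotide-matched pseudo-motif sets) via

* fold enrichment **FE = (O − E)/E**, E the simulant mean (FE < 0 is
  depletion, FE > 0 enrichment),
* **Z = (O − mean)/sd** with the sample (n−1) standard deviation,
* empirical **p = (m + 1)/(n + 1)**, m the number of simulants at or
  beyond *O* in the tested tail.

Compositional specificity is assessed against the 41,664 unordered sets
of three distinct codons: control groups matched to the stop set's GC
content (2 of 9 bases; 2,879 control sets) or purine content (6 of 9;
6,856), their intersection (473), GC-matched sets free of stop-codon
members (2,121), and GC-matched sets whose members cannot overlap one
another (131).

## Worked example

Generate a synthetic cohort of 200 two-to-four-exon transcripts with
stop-free enhancer motifs planted in a 5′-flank-heavy gradient, then
test the cohort for stop-codon depletion against 200 per-sequence
shuffles:

```bash
$ scdkit simulate --out demo --seed 7
wrote 200 transcripts to demo

$ scdkit scd-fe --fasta demo/spliced.fa --iterations 200 --seed 1 --out demo/fe.tsv
aggregate FE = -0.0302; 121/200 units with FE < 0
```

The aggregate FE of −0.030 means the cohort's pooled SCD sits 3% below
the mean of composition-preserving shuffles (its empirical p, in
`demo/fe.tsv`, is 0.005: no simulant was as depleted), and 121 of 200
genes are individually depleted — the planted stop-free motifs drag
stop-codon content below the compositional expectation, the signature
the pipeline is designed to detect.  Rerunning with
`--seed`/`simulate --config` varied lets you trace how the signature
scales with planting density.  The matched codon-set counts are
available directly:

```bash
$ scdkit codon-sets --summary
all_tricodon_sets	41664
gc_matched	2879
purine_matched	6856
gc_and_purine_matched	473
gc_matched_no_stop_members	2121
gc_matched_non_overlapping	131
```

Other subcommands: `motif-fe` (codon-set FE in a motif list against
dinucleotide-matched pseudo-motif sets), `mask-fe` (SCD of sequence
left after removing motif hits), `region` (5′ flank / core / 3′ flank
analysis of exons > 207 nt), `exon-intron` (paired exonic vs intronic
SCD), `stop-skew` (per-codon FE for TAA, TAG, TGA), `porf` (pseudo-ORF
Z scores and the annotation-threshold excess curve).  Every subcommand
writes a JSON run manifest alongside its output.

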
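# Methods

## The coverage-density metric

All analyses rest on one statistic: the fraction of a sequence's
positions covered by at least one occurrence of a query motif set.
Hits are found at every offset for every motif (overlapping
self-matches included — GGG hits both offsets in GGGG), and the covered
positions are unioned before counting, so the metric is bounded by 0
and 1 and insensitive to double-counting of overlapping motifs.
Pooled densities over a sequence set sum covered positions and lengths
before dividing; this is an aggregate over nucleotides, not a mean of
per-sequence densities, and the two differ when sequence lengths vary.
Both modes are available (`pooled_density` vs per-sequence
`motif_density`); pooled is the default for cohort-level statistics.

Masking (`mask_and_split`) removes every covered position and returns
the uncovered runs as separate parts.  Parts are never concatenated:
joining them could fabricate motif occurrences spanning a removed hit.

## Compositionally matched codon sets

The universe is all C(64, 3) = 41,664 unordered sets of three distinct
codons (stop codons included).  Matching is on total counts over the 9
positions: the stop set {TAA, TAG, TGA} has 2 G/C and 6 purines.
`filter_sets` is the pure filter — its counts over the full universe
are 2,880 (GC = 2), 6,856 (purine = 6), 474 (both), 2,121 (GC = 2, no
stop members) and 132 (GC = 2, no internal overlap) — and satisfies the
expected invariants (GC-partition counts sum to 41,664; the stop set
passes every filter it parameterises).

For FE-ranking comparisons the package uses
`stop_matched_control_sets`, which excludes the reference set itself
from the groups anchored on its GC content (a set cannot serve as its
own control), giving control groups of 2,879 / 473 / 2,121 / 131; the
purine-only group is reported as the raw filter (6,856).  This counting
convention preserves continuity with the established reference values
for these control groups; the one-set difference is immaterial to any
ranking statistic over thousands of controls.

Two codons "can overlap" when a length-1 or length-2 suffix of either
equals the corresponding prefix of the other, so the pair can co-occur
in a window shorter than 6 nt.  A set has internal overlap when any
*ordered pair of distinct members* overlaps; a codon's ability to
overlap itself (e.g. AAA) is not counted, since the non-overlap
restriction models distinct set members colliding — and the stop set
itself is non-overlapping under this definition.

## Null models

**Motif-level** (dinucleotide-matched pseudo-motif sets).  A motif set
is summarised by the counts of all overlapping dinucleotides across its
motifs, plus mononucleotide counts.  Each pseudo-motif concatenates
⌊k/2⌋ dinucleotides drawn independently from those frequencies (one
trailing mononucleotide for odd k).  Draws are independent, not a
Markov chain and not a shuffle: the null preserves expected
dinucleotide usage, not each motif's exact composition.  Pseudo-sets
match the true set in size and length multiset; a draw colliding with a
pseudo-motif already in the same iteration is redrawn (duplicates of
real motifs are allowed; only within-iteration uniqueness is enforced),
and 1,000 failed redraws for one slot raise a saturation error —
reachable only for profiles supporting fewer distinct motifs than the
set size.  Default 10,000 iterations.

**Sequence-level** (mononucleotide shuffles).  Uniform permutations of
each scope unit preserve its base composition exactly.  Scopes: whole
transcript, per exon, per masked part (preserving the part-length
structure — the conservative choice when the unmatched sequence's
composition varies between parts), and pooled extraction (all
sequences concatenated, shuffled once, re-cut into the original
lengths), which equalises composition across the cohort and is used
for ORF-threshold calibration.  Default 1,000 iterations.  One master
seed spawns independent per-iteration child streams
(`numpy.random.SeedSequence`), so iterations are order-independent.

**Statistics.**  FE = (O − E)/E with E the simulant mean (undefined
when E = 0); Z uses the sample (n−1) standard deviation of the
simulants, the convention for a statistic estimated from a null sample
(undefined at zero sd, surfaced as an error or a null Z field rather
than silently dropped); empirical p = (m + 1)/(n + 1) counts ties with
the observed value in m, making it conservative and bounded below by
1/(n + 1).

## Exon regions

Exons longer than 207 nt are partitioned into three disjoint 67-nt
windows: the 5′ flank at 1-based positions 3–69 (terminal dinucleotides
excluded, as they are dominated by splice-site signal), the mirrored 3′
flank, and a core centred on the midpoint.  When L − 67 is odd the core
start is ⌊(L − 67)/2⌋, biasing it one nucleotide 5′-ward —
deterministic and symmetric on average.  Region-level SCD is compared
against shuffles of each region's own sequences (each region simulated
separately); the per-region O/E ratio is observed pooled SCD over mean
shuffled pooled SCD, and a chi-square over region covered-position
counts (expectations rescaled to the observed total) is delegated to
scipy.

In the exon-versus-intron comparison a gene counts as depleted only
when its pooled exonic SCD is *strictly* below its pooled intronic SCD;
ties count as failures.  Intronless transcripts are excluded and
tallied.  The cohort-level test is a one-tailed exact binomial at null
success probability 0.5 (scipy).

## Pseudo-ORFs

A pseudo-ORF starts at any ATG (all three frames, sense strand only —
transcripts are oriented) and runs to the *first* in-frame stop codon;
its length spans ATG through stop inclusive, so lengths are multiples
of 3 and at least 6.  The implementation buckets stop positions by
frame and binary-searches from each ATG; an exhaustive substring
enumeration serves as the test oracle.  Sequences with no completed
pORF are excluded from Z analysis; shuffles with no pORF score 0 so
simulant counts stay constant.

The threshold-excess curve counts, per length threshold, real sequences
with a pORF at or beyond it minus the mean such count over
pooled-extraction nulls, divided by the number of real sequences.  The
5%-crossing threshold is read from a locally weighted regression
(lowess, span 0.75, no robustness reweighting — robustness iterations
would suppress genuine sharp declines as outliers) with linear
interpolation between the bracketing thresholds.

## Family grouping

Paralogous families are connected components of the undirected pairwise
similarity-hit graph (single linkage; equivalent to iterated
seed-and-absorb grouping and independent of hit order and pair
orientation).  A family is represented either by a seeded random member
or by the per-statistic median over members.

## Synthetic cohorts

The generator produces what the analysis assumes: multi-exon transcript
models with i.i.d. background sequence at a configurable GC content,
enhancer motifs planted by *overwriting* background (insertion would
shift the declared exon coordinates) at non-overlapping uniformly drawn
sites until a target coverage per region is reached, and optionally one
stop-free ORF (ATG + non-stop codons + stop) per gene.  Defaults are
the package's reference study conditions: 200 genes, 2–4 exons of
250–500 nt (long enough for the three-region partition), introns of
150–800 nt, GC 0.46 (typical of noncoding transcripts), an 84-motif
stop-free hexamer set (the size of a gold-standard enhancer set), and
planting coverages of 0.30 / 0.10 / 0.05 for 5′ flank / core / 3′
flank — the 5′-heavy spatial gradient the region analysis is designed
to detect.  Planted ORFs used in threshold tests are 351 nt (the
generator requires a multiple of 3).

Every insertion is recorded in a ground-truth object written alongside
the FASTA/BED output, so planted-signal recovery is assertable exactly.

What the generator does *not* emulate: splice-site signal, positional
composition gradients other than the planted motifs, paralogous
sequence similarity, expression structure, or motif degeneracy.
Passing tests therefore demonstrate that the pipeline recovers planted
compositional signals of realistic magnitude from realistic sequence
volumes — not that any particular real dataset shows them.

## Problem sizes and determinism

Calibration and recovery tests run at 50–200 genes and 60–200 null
iterations per comparison — enough for cohort-level Monte-Carlo error
well below the planted effect sizes, chosen so the whole suite runs in
well under a minute of simulation time.  All stochastic tests are
seeded; hypothesis-based property tests are derandomised by its
default profile.  Empirical p-values are discrete (multiples of
1/(n+1)); uniformity checks on them use sample sizes where this
granularity is negligible next to the Kolmogorov–Smirnov critical
value.

## Known limitations

* Coverage density treats all motif hits as equal; there is no
  position-weight or affinity model, and no fuzzy matching.
* Dinucleotide-matched pseudo-motifs control for dinucleotide *usage*,
  not higher-order structure; motif sets defined by strong
  trinucleotide constraints would need a higher-order null.
* Sequence nulls are mononucleotide shuffles by design; a
  dinucleotide-preserving sequence shuffle is out of scope.
* The pooled SCD weights long sequences more than short ones; per-gene
  (pairwise) mode is provided for the complementary view.
* Z scores assume the null ORF-length distribution is summarised
  adequately by mean and sd; for short sequences it is strongly skewed
  and the empirical p is the more trustworthy figure.
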
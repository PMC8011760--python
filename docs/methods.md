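# Methods

This note documents the models and procedures implemented in lincberry,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data generators do and do not
emulate.

## Coordinate model

All internal coordinates are 0-based half-open; 1-based inclusive
coordinates exist only while reading or writing GFF3/GTF. Spliced
transcript sequences are always stored 5'→3' (minus-strand transcripts are
reverse-complemented at extraction), so ORF scans and miRNA scans operate
purely in transcript space. Assembled transcripts without an explicit
strand are rejected rather than guessed, because positional classification
is strand-dependent and a silent guess would corrupt class tallies.

## lncRNA discovery

The identification pipeline applies three independent predicates in order;
because they are independent, the kept set does not depend on the order
(asserted by a permutation test).

1. **Length.** Spliced length strictly greater than `min_length_nt`
   (default 200 nt). "Longer than" is read strictly: a 200-nt transcript
   is dropped, a 201-nt transcript passes.
2. **Positional class.** Decision tree against the reference annotation,
   with priority discard > exonAS > intronAS > INTRONIC when a transcript
   overlaps several genes: (a) any sense-strand overlap with a reference
   exon discards the transcript; (b) antisense overlap touching at least
   one exonic base → exonAS; (c) antisense overlap confined to intronic
   bases → intronAS; (d) sense transcript fully inside a single intron →
   INTRONIC; (e) no gene overlap → LINC. Sense overlap that fits no
   retained class (e.g. a transcript poking out of an intron without
   touching an exon) is conservatively discarded. Overlap is judged on the
   transcript's exonic bases; intron containment on its full span.
3. **Coding potential.** ORFs are scanned in the three forward frames.
   Internal ORFs are ATG-initiated and closed by an in-frame stop; their
   length in amino acids excludes the stop codon. Terminal ORFs cover both
   ends of the molecule: ATG-initiated frames running off the 3' end
   without a stop, and ATG-less frames entering from the 5' end and closed
   by a stop (length counted in full codons before the stop). Frames open
   at both ends (no ATG, no stop) are not reported; on sequences longer
   than ~150 nt such a frame is rare and, where it occurs, the molecule
   offers no start codon to translate from. Codons containing N never
   count as start or stop. A transcript is dropped when any internal ORF
   exceeds `max_internal_orf_aa` (default 100) or any terminal ORF exceeds
   `max_terminal_orf_aa` (default 50), both strict. Nested ATGs inside a
   longer same-frame ORF are not reported separately, so the filter keys
   on the longest reading frame through each region. An optional
   `homology_hook` predicate can drop transcripts with protein-database
   similarity; it defaults to never firing, keeping the pipeline
   database-free.

## Expression

**TMM/CPM.** The reference sample is the one whose upper quartile of
positive counts is closest to the mean upper quartile. For each sample,
M-values are log2 ratios of raw counts against the reference over genes
positive in both, A-values are average log intensities; values inside the
central M-quantile band (trim 0.30 per tail) and A-band (trim 0.05 per
tail) are averaged with inverse-variance weights
`1 / ((N_s−y_s)/(N_s y_s) + (N_r−y_r)/(N_r y_r))`, and the factors are
rescaled to geometric mean 1. M-values are deliberately computed on raw
counts rather than library-size-normalised abundances: the factors then
absorb depth as well as composition, and a column that is an exact scalar
multiple of another recovers that scalar exactly (up to the geometric-mean
rescale) — a property the test suite asserts to 1e-6. CPM is
`count / (library_size × factor) × 1e6`, so CPM columns sum to
`1e6 / factor`.

**Presence filter.** `threshold_k = floor(min_fraction × n_samples)`; a
feature is kept iff strictly more than `threshold_k` samples have strictly
more than `min_reads` reads. Both strict inequalities reproduce the
43-of-72 worked arithmetic at the defaults (10 reads, 60%).

**Variance stabilisation and batches.** Downstream analyses use
`log2(CPM + 1)`. An optional per-batch median-centering on that scale is
provided; no factor-analytic batch removal is attempted, which keeps the
stack dependency-light at the cost of not modelling unknown unwanted
variation.

**Temporal patterns.** Stage means of CPM against a single expressed
threshold (default 1.0 CPM, a conventional cutoff, configurable):
expressed in exactly one stage → stage-specific; in all → constitutive; in
none → silent; otherwise → other.

**Landscape statistics.** Pearson correlation between samples on
log2(CPM+1), with zero-variance samples marked NaN rather than raising;
per-feature length/exon/GC (GC ignores N); two-sided Wilcoxon rank-sum
comparisons without multiplicity correction (the three metrics are
reported side by side); 100-kb bin densities assigning each feature to the
bin containing its start; and signed lincRNA→nearest-gene distances
(negative when the lincRNA lies on the gene's 5' side, measured from the
lincRNA TSS; positive on the 3' side, measured from the gene 3' end;
overlap → 0; gene-free chromosome → undefined).

## Co-expression

Adjacency is the signed-absolute power law `|r|^beta` with beta = 6, the
conventional soft threshold. Topological overlap uses
`TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 − a_ij)` with
connectivities `k` from off-diagonal row sums. Modules come from
average-linkage hierarchical clustering of `1 − TOM` with a **static** cut
— a deterministic, parameter-transparent simplification of dynamic hybrid
tree cutting. Because a power-6 adjacency shrinks moderate correlations
hard, weighted-TOM dissimilarities concentrate near 1 and the default cut
height is 0.9 (calibrated on the planted two-block synthetic design at the
71-sample study scale, where it recovers the blocks with adjusted Rand
≥ 0.9); clusters below `min_module_size` (default 10) are pooled as
"unassigned". The module eigengene is the first right singular vector of
the row-standardised member matrix, unit-norm, sign-fixed so that the mean
correlation with members is non-negative; its explained variance fraction
is reported. Top-k intramodular edges are ranked by weight with
lexicographic tie-breaks. Enrichment is the exact upper-tail
hypergeometric `P(X ≥ k)` per term, flagged at uncorrected p < 0.05 (an
optional Benjamini–Hochberg correction is a caller-side decision; the flag
follows the uncorrected convention of the motivating analyses).

## miRNA target scanning and mimicry

Targets are scored by exact enumeration of banded duplex alignments:
window lengths from L−1 to L+4 (L = miRNA length, 20–24 nt), at most one
bulge — a target bulge of `W−L` nucleotides between any two adjacent miRNA
positions, or a single bulged miRNA nucleotide when `W = L−1`. Penalties:
mismatch 1, G:U wobble 0.5, bulged nucleotide 2. Positional penalties
(mismatch, wobble, bulged miRNA nucleotide) are doubled over the 5' region
— positions 2–13 in scheme A, 2–12 in scheme B. A target bulge lies
*between* miRNA positions and always costs the flat per-nucleotide rate:
doubling it would let the optimiser trade a central eTM bulge for
off-register mismatches at equal or lower cost and mis-place the bulge.
Ties between equal-penalty placements resolve to the 3'-most bulge. A site
is reported only when it passes both schemes' cutoffs (default 4.0, a
common plant-target stringency) with span midpoints within ±3 nt — the
consensus-intersection design. Note that a canonical eTM site (3-nt bulge,
penalty 6) deliberately fails the default cutoff; eTM classification is
meant for sites scanned at a relaxed cutoff or constructed directly from a
known locus.

Duplex ΔG uses a reduced 16-entry nearest-neighbour stacking table keyed
by the miRNA-side dinucleotide, a flat weak value for wobble-containing
stacks, and a fixed destabilising term per mismatched or bulged
nucleotide. Absolute values are not comparable to full thermodynamic
folders; only orderings between duplexes over the same miRNA are
meaningful (e.g. a contiguous site is at least as stable as its
3-nt-bulged counterpart).

Cleavage prediction follows the AGO slicer convention: the scissile bond
lies between the target bases pairing miRNA nucleotides 10 and 11, and is
reported as `(10, b)` where `b` is the 0-based transcript index of the
first base of the 3' fragment. Prediction is withheld when position 10 or
11 is unpaired or separated by a bulge. Classification: a 3-nt target
bulge between positions 10–11 → canonical eTM; a contiguous site whose
RACE tally places the modal bond at an offset other than 10 → noncanonical
mimic; otherwise a cleavable target.

Target-site conservation aligns each homolog globally to the reference
(match +1, mismatch −1, gap −2) and averages per-column identity over the
site window.

## RLM-RACE tallies and the anthocyanin index

A clone's 5' end marks the first base of the 3' cleavage fragment; the
bond is immediately 5' of it. Offsets are reported as the 5'-side miRNA
nucleotide ("10" means "between the 10th and 11th"), valid in
`[1, L−1]`; clone positions pairing no miRNA nucleotide report None. Modal
ties resolve toward the smaller transcript position and set a tie flag.
The synthetic round-trip (generate clones at offset x, tally, recover x)
holds for every x in 8..14 by test.

The anthocyanin index is `(A530 − 0.25 × A657) / M`; negative values are
reported as-is with a warning rather than clipped, since clipping would
hide blank/calibration problems.

## Synthetic data: what it emulates and what it does not

Generators are pure functions of (parameters, seed) and return planted
truth labels alongside the data, so each stage's recovery is assertable.
Default scales keep a full pipeline run in seconds: two 50-kb chromosomes,
ten 1–5-exon genes, planted single-exon transcripts of 250–300 nt, a
3-stage × 3-replicate count design with 200 features. Planted loci are
kept mutually disjoint and each planted sequence is written back into the
genome, so genomic extraction and stored transcript sequences agree.
Noncoding filler sequence is random at GC 0.40 with stop codons salted
into any frame run exceeding 40 codons, guaranteeing no planted transcript
accidentally carries a disqualifying ORF.

Counts are negative-binomial with variance `mu + phi mu^2` (default
dispersion 0.1, a typical bulk RNA-seq scale). Stage-specific features
have mean 400 in their stage and 0.01 elsewhere; constitutive means are
log-normal around 50. Correlated module blocks multiply member means by a
shared per-sample log-normal factor (sd 1.2 on the log2 scale); the
co-expression fixtures use a 71-sample design, matching the sample count
of the study setting this analysis emulates, because module recovery from
pairwise correlations is sample-limited rather than feature-limited.

The generators do **not** emulate read-level artefacts (no FASTQ, no
alignment or assembly errors), multi-isoform loci, polyploid subgenomes,
GC-dependent coverage bias, or annotation errors. Passing tests therefore
demonstrate the correctness of the downstream computations on clean
inputs, not robustness to upstream noise sources — those live in the
aligner/assembler layer this package intentionally consumes rather than
reproduces.

## Problem sizes and numerical notes

The test suite and the acceptance script run the scales above (≤ 4000
features, ≤ 72 samples, ≤ 50-kb chromosomes, 21-nt duplex enumerations),
chosen so that every check is exact or tightly seeded and the whole suite
completes in well under a minute. Floating-point ties in duplex scoring
are compared at 1e-9 after rounding; TMM trimming uses inclusive quantile
bands so that degenerate all-equal M-vectors are kept rather than emptied;
hierarchical clustering consumes a symmetrised, clipped distance matrix to
absorb 1e-16-scale asymmetries.

## Known limitations

- The static tree cut can split or merge modules that a dynamic cut would
  resolve; cut height is the single most influential co-expression
  parameter and should be tuned per dataset.
- ΔG values are ordinal, not thermodynamic.
- TMM factors absorb library depth by construction (raw-count M-values);
  they are not numerically interchangeable with factors from tools that
  normalise M-values by library size before trimming, although the
  resulting CPM matrices agree up to the factor convention.
- Discovery evaluates one transcript model per reference gene; genes with
  several annotated isoforms are represented by their first mRNA.
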
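# Methods

This note documents the models, statistical procedures, parameter
defaults and numerical choices behind the package, and what the
synthetic benchmark does and does not demonstrate.

## Study design being modelled

Two transcriptional subtypes ("luminal", "basal") with a small number
of samples each (default 2 per group, mirroring two cell lines per
subtype; the power benchmarks use 4 per group, because correlation and
permutation tests at 4 total samples are nearly powerless).  All
genomic coordinates are 0-based half-open; loop anchors and contact
matrices live on a fixed bin grid (default 10 kb).

## Synthetic data generator

The generator is a deliberately simple stand-in with planted, recorded
truth; nothing is fit to a real dataset.  Every stage draws from its
own labelled seed stream, so stages are individually reproducible and
the full study directory is byte-identical under a repeated seed.

**Expression.**  Gene baseline means are log10-uniform on [10, 10^4]
counts.  A fraction `de_fraction` (default 0.1) of genes receives a
±`de_log2fc` (default 2.0) group effect, half up in each subtype.
Library sizes are jittered ±20%.  Counts are negative binomial with
variance mu + `nb_dispersion`·mu² (default dispersion 0.1, i.e. ~32%
biological CV — noisy-tissue territory).

**Enhancers and true links.**  Enhancers are 500 bp intervals placed
uniformly outside ±2.5 kb promoter windows and kept mutually disjoint
(like a merged peak catalog).  Each true link pairs an enhancer with a
gene within ±500 kb; its activity is z_g + N(0, `link_noise_sd`·sd(z_g))
where z_g is the gene's log2-CPM profile, so the population
activity–expression correlation is 1/sqrt(1 + link_noise_sd²) for every
link — the default 0.45 gives r ≈ 0.9.  Decoy enhancers get independent
noise with matched marginal variance, so variance ranking cannot
separate them from true enhancers.

**Loops and contacts.**  Planted loops cycle shared → luminal → basal;
present samples get caller probabilities U(0.85, 0.95), absent samples
U(0.05, 0.15).  Contact matrices have expected counts
`contact_scale`·(1+|i−j|)^−α (defaults 100, α = 1); planted dots
multiply the centre pixel by `loop_enrichment` (default 3) and the 3×3
neighbourhood at half strength, only in samples of the loop's group;
the upper triangle is Poisson-sampled and mirrored.  Poisson (not NB)
contact noise keeps the variance bookkeeping simple and is sufficient
for APA behaviour.

**TF sites, co-binding, sequences.**  One factor's sites are placed by
a per-bin mixture with weight `tf_anchor_fold` (default 5) on loop
anchor bins.  Co-binding truth plants sites of factors A and B inside
disjoint enhancer subsets (A-only / B-only / co-bound).  Peak
sequences are i.i.d. uniform ACGT with an 8-bp consensus inserted (on
a random strand) in `motif_fg_rate` of foreground and `motif_bg_rate`
of background peaks (defaults 0.5 / 0.05); decoy PWMs are column
permutations of the planted PWM, redrawn until their consensus string
differs.

**Rearrangement.**  The planted translocation joins the left part of
chromosome 1 to the right part of chromosome 2.  The derivative-locus
matrix is Poisson-sampled directly from the decay law on derivative
coordinates — that matrix *is* the ground truth — and the observed
intra/trans matrices have the corresponding blocks overwritten, so a
correct reconstruction from the separated pieces is bit-exact.

## Statistical procedures

**Differential test.**  Log2-CPM (pseudocount 1), Welch statistic.  In
balanced designs the Welch statistic coincides with the pooled
two-sample statistic, whose exact null reference is t(n−2); we use
that df there and the Satterthwaite approximation only for unbalanced
groups.  (At n = 4 + 4 on normal data, Satterthwaite centres the null
p < 0.05 fraction at ≈ 0.042 while the balanced-exact df centres it at
0.05.)  When the number of label orderings n! is at most 10,000 the
p-value comes instead from the exhaustive permutation distribution of
group labels; the observed labelling is part of the enumeration, so
the smallest attainable two-sided p is 2/C(n, n_A) and p is never 0.
BH controls the FDR; calls require |log2FC| ≥ 1 and q ≤ 0.05 by
default — conventional thresholds, both configurable, since there is
no canonical cutoff for subtype gene calls.

**Enhancer–gene linking.**  With ≤ 8 samples, label permutations
cannot resolve p < 0.01, so significance comes from a pooled empirical
null: correlations of uniformly sampled cross-chromosome
(enhancer, gene) pairs, which cannot be physically linked.
p_emp = (1 + #{null ≥ r}) / (1 + |null|), one-sided — the pipeline
filters for positive coupling (r ≥ 0.5), so anti-correlated pairs are
reported but never pass.  Zero-variance profiles get r = 0 and a
`degenerate` flag rather than NaN, keeping downstream totals stable.
BH q-values over all tested pairs are reported alongside.

**APA.**  Expected counts per interaction distance are the mean of
each diagonal (optionally a caller-supplied vector, used by the
closed-form tests).  Each loop contributes a (2w+1)² observed/expected
window (default w = 10); loops closer than 2w+2 bins to the diagonal
or touching an edge are skipped.  The score divides the centre pixel
by the mean of the lower-left 3×3 corner — the near-diagonal corner,
the usual APA convention.  Because observed/expected cancels any
global scale, APA is invariant under matrix scaling.

**Anchor enrichment.**  Sites are re-placed uniformly within their
chromosome (sites are essentially points at 10 kb resolution, so
length-matched gap shuffling would add complexity without changing the
null).  Fold = observed / mean(null);
p_emp = (1 + #{null ≥ obs}) / (1 + shuffles).  Note the measured fold
of a planted density ratio f is f / (1 + (f−1)·c) where c is the
anchor coverage fraction — with the default ~12% coverage, a planted
5-fold density reads out as ≈ 3.5.

**Motifs.**  Log2-odds scanning of both strands against a uniform
background; a hit is ≥ `score_frac` (default 0.8) of the maximum
attainable score; N bases score 0.  Enrichment is the one-sided Fisher
exact test on "peaks with ≥ 1 hit" counts, BH across motifs, ranked by
ascending p with name tie-breaks.  The odds ratio uses the
Haldane–Anscombe 0.5 correction so it is finite and equals 1 for
identical tables.  This is a transparent substitute for suite tools
(HOMER-style known-motif enrichment): no GC matching, no background
model calibration — backgrounds are an explicit input.

**SV stitching.**  `side` names the retained segment of each partner;
the output runs along the derivative locus with the junction in the
middle.  Pure-source blocks are bit-exact copies; the cross block
comes from the trans matrix with orientation-dependent index reversal,
or, when absent, from the decay expectation of the first partner at
the derivative-coordinate distance.  Maps are raw counts
(normalisation of reconstructed maps is out of scope); copy-number
scaling of the cross block is not modelled.

## Benchmark problem sizes

Chosen so the full suite runs in minutes on one CPU:

- DE power/calibration: 2000 genes, 4 vs 4, seeds 1–5 (power) and a
  single null study (calibration).
- Linking: 200 true links / 2000 decoys, 8 samples, on 2 × 50 Mb with
  150 genes (1.5 genes/Mb).  The density is a design-of-experiment
  choice: a raw p < 0.01 pass threshold admits ~1% of tested
  within-window null pairs, so the expected false-pass count
  (~0.01 × tested pairs) must stay well below the 200 planted links
  for the pass list to be informative.  At the default dense design
  (100 genes/Mb) the same threshold yields a pass list dominated by
  false positives — the worked example in the README shows exactly
  that, and it is the expected behaviour of raw p thresholds at scale.
- Loops/APA/anchors: 2 × 10 Mb at 10 kb (1000 bins per chromosome),
  120–300 loops, 1000 TF sites.
- Motifs: 200 foreground / 2000 background 150-mers, 11 PWMs.

## What passing tests show — and what they do not

Truth recovery on this generator demonstrates that the pipeline's
statistics are calibrated and its bookkeeping (coordinates, bins,
orientations, truth linkage) is correct.  It does not demonstrate
performance on real data: real expression has correlated gene modules
and outliers; real enhancer–gene coupling is nonlinear and
many-to-many; real Hi-C has domain structure, compartments and
coverage biases that distance decay plus Poisson noise do not emulate;
real motif backgrounds are GC- and repeat-structured.  Known further
limitations: the DE module has no dispersion shrinkage, so its power
at 4 + 4 samples tops out around 85% recall for 4-fold effects at
dispersion 0.1 (a known-variance oracle reaches ~97% under the same
conditions); CPM normalisation couples genes through the estimated
library sums, which slightly widens the spread of null-fraction
statistics beyond binomial; and the subtype-assignment rule is a sharp
threshold formalisation of an inherently soft decision.
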
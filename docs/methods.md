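# Methods

This note records the models implemented, the defaults and why, the
numerical conventions, and what the synthetic benchmarks do and do not
establish.

## Consensus ROI inference

Sample regions are treated as noisy estimates of a hypothetical locus
position. A region with midpoint μ_k and half-width σ_k contributes the
unnormalized Gaussian shape φ((x − μ_k)/(ρσ_k)); the width ratio ρ
(default 1) encodes how much of the region's width is positional
uncertainty. Replicates within a condition are independent estimates of
the same loci, so their per-replicate densities (the sum over that
replicate's regions in the group) are multiplied; different conditions
may have genuinely different loci, so condition products are summed. A
sample with no region in a group contributes a uniform 1/Δ factor over
the group span Δ — absence of evidence, not evidence of absence.

Numerical conventions:

* **Grid.** Integer base positions across the group span, padded by
  3·max(ρσ_k) per side so edge maxima are not clipped; 1 bp matches
  coordinate precision (a finer step is available and shifts μ̂ by at
  most 1 bp, which is tested). Midpoints of odd-length regions are kept
  fractional.
* **Stability.** The replicate product is evaluated as exp(Σ log ·) with
  a 1e−300 per-factor floor. The rescale applied before exponentiation is
  a single global constant: a per-condition rescale would re-weight the
  condition sum and move its maxima (this is easy to get wrong and is
  covered by a brute-force comparison test).
* **Maxima.** A local maximum is a grid point strictly above both
  neighbors; plateaus yield their midpoint. Candidates are ranked by the
  joint value and truncated to M+1, where M is the median region count
  per sample *including* design samples with zero regions in the group
  (the definition does not exclude them), floored so at least one ROI
  survives. A completely flat joint function degenerates to the span
  midpoint.
* **Widths and overlaps.** σ̂ is the inverse-distance weighted mean of
  the contributing σ_k (weights 1/(|μ̂ − μ_k| + 1)); it always lies
  between the extreme sample half-widths. Overlapping ROIs in a group are
  shrunk symmetrically about their (fixed) centers until disjoint;
  coincident centers cannot be separated this way, so the lower-ranked
  one is dropped, as is any ROI whose half-width is driven to zero.
* Coordinates are 0-based half-open throughout; "overlap" means a
  positive-length intersection, so abutting intervals do not group.
  Strand is ignored (ROIs mark bidirectional initiation zones).
* Per-sample quality weighting is not implemented; all samples count
  equally.

A note on a tempting invariant: duplicating a replicate does *not* in
general leave the joint argmax fixed — squaring one factor of a
heterogeneous product re-weights its precision-weighted mean. The
property holds only when the duplicated factor is the condition's sole
density, which is what the test asserts.

## Ranking

The enrichment statistic consumes only an ordering: most significant
positive fold-change first, then zero-LFC records, then negatives with p
descending (or pure fold-change ordering on request); ties break on ROI
id so the ranking is a pure function of the records. DESeq2-style tables
are ingested directly (column names remappable, p = 0 clamped to the
smallest positive float, NA rows dropped). When only raw counts exist, a
clearly labeled fallback is provided — library-size-normalized means,
LFC = log2((mean_B + 0.5)/(mean_A + 0.5)), Welch t-test on log counts
when both conditions have ≥2 replicates — adequate for ordering
simulations, not a negative-binomial model.

## Motif scanning

Motifs are base-frequency matrices smoothed as (f + 0.1·π)/1.1 against
the zero-order background π (by default the average base composition of
all ROI windows; motif GC content g is the mean smoothed C+G and is used
only relatively, across motifs). Scores are log2 likelihood ratios
quantized at 1/1000 bit; the same integer matrix drives both the exact
p-value→score dynamic programming (per-position distributions convolved
by shift-add) and the scanner, so thresholding is exact by construction.
The stated operating point, match p ≤ 1e−6, is interpreted as a scan
p-value in the usual motif-scanner sense; a raw-score threshold mode
exists. Both strands are scanned; a hit's coordinate is the center of its
matched span; ties break toward the window center, then the + strand. N
bases score 0 (the background expectation). Only the best hit per 3 kb
window is kept.

## Enrichment statistic

d_i is the center-to-center distance to the best hit, null when no hit
lies within 1.5 kb (inclusive). The decay length d̄ is the mean non-null
d_i over rank indices ⌈N/4⌉..⌊3N/4⌋ inclusive — rank-index quartiles, on
the assumption that mid-list ROIs are unperturbed background; if that
window has no hits, d̄ falls back to 1500 bp (weights then barely decay,
which is conservative). Weights are w_i = exp(−d_i/d̄), 0 for null.

The score is E = (2/N) Σ_i (e(i) − u(i)) with e the normalized running
sum of weights and u(i) = (i+1)/N the running sum of uniform weights.
Writing the background as a running sum (rather than the index fraction
i/N) is the one place a choice had to be made among near-identical
conventions that differ at O(1/N): this one makes E exactly zero for
uniform weights, exactly antisymmetric under rank reversal, and bounded
by (N−1)/N in magnitude — so the documented range [−1, 1] is a theorem
rather than an approximation. E is invariant to positive rescaling of the
weights, and moving weight mass toward lower ranks can only increase it
(both tested, the bound exhaustively at small N).

Significance: 1000 random permutations of the rank order (shuffling the
weight vector — O(N) per permutation via the linear form
E = 2/(NW)·Σ w_k (N−k) − (N+1)/N), a normal fit (E0, σ_E), Z_TF =
(E_TF − E0)/σ_E, two-sided p, Bonferroni across the motif panel. A motif
with ≤1 weighted ROI carries no enrichment information and reports p = 1.
All permutation streams spawn from a single seed, so results are
reproducible and independent of motif order. Two-sided p-values are used
because both activators and repressors (E of either sign) are of
interest.

## GC correction — and when not to use it

Across a motif panel, E-scores are regressed on motif GC content by
ordinary least squares (the textbook slope Σ(g−ḡ)(E−Ē)/Σ(g−ḡ)²), and the
fitted value is subtracted: E_TF = E − (b̂ + m̂g). The correction can be
turned off; it is on by default in the pipeline.

Its validity depends on panel size. The fitted line is estimated from the
panel's own E-scores, so its pointwise noise scales like the E-score
noise divided by √(panel size). With a database-scale panel (hundreds of
motifs) that noise is small. With a small panel — e.g. the 20-motif
benchmark harness, where 19 motifs have only chance-level hit counts and
hence very noisy E — the fit noise *exceeds* the permutation-null spread
of a dense-hit motif, and corrected z-scores for exactly the motifs of
interest become anti-conservative (we measured corrected |z| > 4 on null
data whose raw |z| was < 1.5). The benchmark harness therefore runs with
the correction off, for both its signal and null arms; the full pipeline
keeps the published default. When every motif shares one GC value the
slope is undefined and the correction is skipped with a warning.

## Motif displacement baselines

MD-Score: fraction of best hits within 150 bp of ROI centers among hits
within 1500 bp (radii inclusive; equal radii force 1; no hits → null).
It ignores the ranking entirely — the contrast with the rank-weighted
statistic is itself a test. The differential variant partitions ROIs by
user-supplied p/LFC thresholds (the appropriate cutoffs are empirical and
dataset-dependent, so none are hard-coded) and differences the two
scores; a two-proportion z-test is available but off by default.

## Synthetic data: what it emulates, what it does not

* **Replicate locus model.** Region midpoints jitter binomially,
  μ_i ~ μ + B(100, 0.5) − 50 (variance 25); half-widths are
  σ_i ~ Poisson(100) (mean = variance = 100), zero draws redrawn (their
  probability at λ=100 is negligible; the guard matters for small-λ
  experiments). Simulations place loci on a fixed-origin synthetic
  chromosome.
* **Sequence model.** First-order Markov chains; the default transition
  matrix is mildly GC-rich with depleted CpG, a qualitative stand-in for
  regulatory-region composition (a positional profile of real initiation
  regions is data-derived and not reproduced here). Motif embedding
  replaces bases in place, preserving length: top-ranked fraction at
  Normal(0, 150 bp) offsets from the window center, a background fraction
  of the remainder at uniform offsets; a truth table records every edit.
  The benchmark panel is deterministic: one p53-like consensus motif
  (two RRRCATGYYY half-sites) plus random motifs spanning GC 0.25–0.75.
* **Not emulated:** mappability, repeats, chromatin-driven positional
  base composition, read-level noise, overdispersed counts. Passing
  benchmarks show the statistics behave as designed under their stated
  models, not that real-data performance is reproduced.

## Benchmark problem sizes

Chosen so the whole suite runs comfortably on one CPU: locus-model
moments at 10,000 draws; replicate-scaling at 1,000 simulations per
replicate count 1–10, drawn nested (the k-replicate estimate uses the
first k of 10 draws — common random numbers, so monotone comparisons are
not noise-dominated); two-locus resolution at 500 simulations per
separation; signal recovery at 2,000 ROIs × 20 motifs × 10 seeds with a
matched no-signal control; null calibration over 200 datasets of 100
ROIs with 1,000 permutations each. The enrichment-score bound is checked
exhaustively for all 0/1 weight vectors to N = 12 and on 10⁵ random
vectors at N = 1000.

## Known limitations

Closely spaced loci merge into one ROI (lowering ρ sharpens resolution at
the cost of fragmentation); the fallback differential statistic is not a
substitute for a proper count model; Bonferroni is conservative for large
correlated motif panels; paralogous TFs are distinguishable only insofar
as their motifs differ; the GC correction requires a large panel (above).
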
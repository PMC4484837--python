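# Methods

This note documents the statistical procedures `normrank` implements, the
numerical conventions it fixes, what the synthetic-data generator does and
does not emulate, and the design choices made where the design was genuinely
open.

## Scaling factors and the divisor convention

All five methods estimate relative sequencing depth; they differ in which
statistic of the count distribution they trust.

* **TMM.** For sample *j* against a reference *r* (by default the sample
  whose upper quartile of library-size-scaled counts is closest to the mean
  of those quartiles), each gene positive in both samples contributes a log
  ratio `M_g = log2((K_gj/N_j)/(K_gr/N_r))` and an average abundance
  `A_g = (log2(K_gj/N_j) + log2(K_gr/N_r))/2`. Genes in the upper or lower
  30% of the M distribution or the upper/lower 5% of the A distribution are
  trimmed (two-sided, per tail, by average rank so tied boundary values drop
  together); the surviving log ratios are averaged with inverse-variance
  weights `1/v_g`, `v_g = (N_j−K_gj)/(N_j K_gj) + (N_r−K_gr)/(N_r K_gr)`
  (the delta-method variance of `M_g`). Under the assumption that most genes
  are not differentially expressed, `d_j = 2^{weighted mean}` stays near 1.
  A cross-check test reproduces edgeR's `calcNormFactors(method="TMM")` to
  8 significant digits.
* **UQ.** After removing genes that are zero in every library,
  `d_j = UQ_j / N_j` with `UQ_j` the 75th percentile of the sample's counts.
* **DES (median-of-ratios).** `d_j = median_g K_gj / (Π_v K_gv)^{1/m}` over
  genes positive in all samples (any zero makes the geometric-mean
  pseudoreference 0). DESeq2's `estimateSizeFactorsForMatrix` cross-checks
  this to ~1e-4 (it takes the median in log space, which differs only when
  the median interpolates between two genes).
* **EBS (quantile).** `d_j = 10^{log10 Q_j − mean_v log10 Q_v}`, `Q_j` the
  sample's upper quartile; the exponents sum to zero so the factors have
  geometric mean 1 by construction.
* **PS.** With total-count depths `d^TC_j = N_j/Σ_v N_v` and per-gene totals
  `S_g`, the Poisson goodness-of-fit statistic is
  `GOF_g = Σ_j (K_gj − d^TC_j S_g)²/(d^TC_j S_g)`. Genes between the 25th
  and 75th percentile of the GOF distribution form the putatively
  non-differential set over which the depth share
  `d^PS_j = Σ_g K_gj / Σ_g S_g` is computed. GOF is a nonnegative,
  chi-square-like, unbounded statistic, so a *literal* value window
  (0.25, 0.75) is empty on any realistically dispersed matrix; the
  interquartile reading is the default and the literal one remains available
  behind a flag. The estimator is a single pass, not the iterated version.
* **RD.** All factors 1 — the unnormalized benchmark every comparison
  includes.

Every method also exposes a count-scale **divisor** `s_j`, the quantity by
which counts are divided to normalize: for TMM the effective library size
`N_j·d_j` (the TMM factor corrects the library size, it is not itself a
count scale), for UQ the upper quartile itself (equivalently `N_j·d^UQ_j`),
for DES/EBS native factors, for PS `m·d^PS_j` (the shares sum to 1 across
the m samples). Divisors are rescaled to geometric mean 1 so all methods
live on one scale in plots, in bias/variance, and against the simulator's
truth. Upper quartiles are always the 75th percentile with linear
interpolation on sorted values; quartile dialects differ between tools, so
the rule is fixed package-wide.

## Housekeeping selection and the bias/variance criterion

Stability is scored on **raw** counts — the control set must not depend on
the normalization under evaluation — as `MSE_g = Σ_j (K_gj − K̄_g)²/m`,
min-max normalized, with the lowest `floor(0.01·G)` genes selected (ties at
the boundary broken by input gene order; the floor reproduces 124/131/127
selected genes at G = 12,410/13,131/12,749). Whether one reports the MSE or
its square root is immaterial: selection is invariant under any strictly
increasing transform, and both values appear in the output table.

Bias (RMSE of log2 ratios to the gene's own mean; the true log ratio of a
constant gene is 0) and variance (unbiased sample variance of those ratios)
are evaluated on **normalized** counts — evaluating on raw counts would make
all methods identical; RD by definition uses the raw counts. Control genes
with a zero count in any sample have undefined log ratios and are excluded
per method with a warning (no pseudocount is added; the exclusion count is
reported). Method-level bias/variance are unweighted means over surviving
control genes.

## The exact test

The test conditions on each gene's total: counts are divided by the
divisors, per-group sums (S1, S2) are rounded to integers, and under the
null of equal expression each group sum is NB with mean `n_k·μ` and
dispersion `φ/n_k` (the sum of n_k i.i.d. NB variates). The two-sided
p-value is the total conditional probability of splits no more likely than
the observed one (with a 1e-10 log-domain tolerance so ties count as ties);
at φ = 0 the conditional law is exactly binomial, verified against an
independent binomial-tail oracle. Totals above a cap (default 2000) are
proportionally rescaled before enumeration, bounding the work per gene at
the cost of resolution no test at these sample sizes can use. The common
dispersion is a pooled moment estimate: within-group `(s² − m̂)` residuals
and `m̂²` scales accumulated over genes and groups with their degrees of
freedom, ratio floored at 0 (Poisson fallback when no group has
replication). Fold changes are `log2` ratios of divisor-normalized group
means with a 0.5 pseudocount on each mean; multiplicity is
Benjamini–Hochberg; DEGs are genes with adjusted p below α (default 0.05).

A full quantile-adjusted conditional-ML re-implementation of edgeR's test is
deliberately out of scope; the contract that matters — the scaling factors
enter the test through the effective library sizes — is preserved, and the
test's calibration is verified by simulation (null false-positive rate
0.03–0.07 at α = 0.05; power > 0.8 for 4-fold effects at φ = 0.1, n = 5+5).

## Classification, overlap and rank aggregation

The classifier benchmark feeds `log2(normalized count + 1)` of the
`floor(0.75·m)` genes with smallest adjusted p-values (30/12/20 genes for
41/16/27 samples) to five classifiers: Gaussian naive Bayes, a single
8-unit-hidden-layer perceptron (inputs standardized — gradient training does
not converge reliably on raw count scales), 5-nearest-neighbours (k clamped
to the training fold on tiny designs), an RBF SVM at library defaults, and a
500-tree random forest; the forest and perceptron take the workflow seed.
Leave-one-out cross-validation runs m rounds; a fold whose training set
lacks a class counts as an error and is logged. The 95% interval on the
mean error is a t-interval with 4 df across the five classifier error
percentages.

Common-DEG percentages `P_ij = 100·D_ij/D_i` are symmetrized by pair
averaging; a method's score is its mean symmetrized percentage over
partners. Methods are also clustered by Ward linkage (scipy's
squared-distance-updating variant) on Euclidean distances between the rank
vectors they assign to the DEGs common to all methods (ranks by adjusted p
ascending, ties by gene order).

The final rank is the unweighted mean of tie-averaged per-criterion ranks
(bias, variance, prediction error: lower better; sensitivity, specificity,
common-DEG score: higher better). A criterion missing any method is dropped
with a warning rather than ranked on partial evidence; omitting the control
panels therefore removes sensitivity/specificity from the mean and leaves
the other criteria untouched.

## The synthetic-data generator

Counts are drawn from the package's own model: gene baselines `λ_g` are
log-normal, per-sample size factors log-normal with σ = 0.4 (≈2–3× spread,
geometric mean 1 — library-size variation is the basic between-sample
difference the normalizations must remove), a configurable fraction of genes
(default 10%) gets a ±`log2fc` effect in group 2 (50/50 up/down by default),
and NB sampling uses the gamma–Poisson mixture (φ = 0 is Poisson). Three
presets emulate two-group designs of 41, 16 and 27 samples with ~12–13k
genes and low-, high- and middle-skewed abundance; the 27-sample
clinical-style preset skews its effects 70/30 upward.

Two structural choices matter and are deliberate:

* **Generated matrices emulate *filtered* data.** Baseline means are
  truncated below (default 50, matching a clinical-style design whose
  post-filter minimum mean abundance is ≈50; the low/high-abundance presets
  lower the floor to 0.02/1). An absolute-MSE stability criterion on raw
  counts is dominated by the `λ²·var(size factor)` term, so without a floor
  the lowest-MSE genes are simply the lowest-expressed genes.
* **Designated housekeeping genes occupy the low-abundance stable niche.**
  Their levels are uniform on [15, 30), just below the ordinary floor, with
  a tenth of the common dispersion — mirroring real filtered data, where
  analytically stable genes concentrate at low-to-medium read counts. Under
  these conditions the 1% selection recovers 86–96% true housekeeping genes
  across seeds at G = 5,000, m = 10.

What the generator does **not** emulate: gene–gene correlation, GC/length
effects, batch structure, outlier samples, or compositional distortion from
a few ultra-abundant transcripts. Passing tests therefore demonstrate that
each method recovers truth under its own generative assumptions — clean
library-size variation — not that any method is robust to the failure modes
real data add on top.

## Problem sizes and numerical conventions

Simulation-backed checks run at G = 5,000, m = 10 (size-factor recovery,
within 5% for every method; bias/variance ordering, RD strictly worst),
G = 2,000, m = 10 (test calibration), and the full 12,749 × 27 preset for
the end-to-end determinism check — sizes chosen so each check carries sound
statistics while the whole suite stays desk-scale. All randomness flows
from one integer seed per run; reruns with the same configuration are
byte-identical in every table. Ties anywhere (ranks, p-values, boundary
trims) break by stable input order. Figures are pure views of computed
results; deleting every plot cannot change a number in the report.

## Known limitations

* The common dispersion is a single pooled moment estimate; no tagwise or
  trended shrinkage, no multi-factor designs.
* The exact test's integer rounding of normalized group sums discards
  sub-count information; at very low totals the conditional support is
  coarse and p-values are conservative.
* The PS estimator is the printed single pass, not the iterative published
  estimator.
* Real control panels (validated positive/negative genes) are external
  inputs; the built-in panels are drawn from simulation truth and exist for
  benchmarking the machinery, not as biology.
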
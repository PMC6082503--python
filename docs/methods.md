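# Methods

This note records the models implemented, the parameters that matter, what
the synthetic data does and does not emulate, and the numerical and design
choices made where the procedure left room.

## Ground truth and training target

A subject's binary CAD label is positive iff any lesion satisfies the
protocol rule: stenosis ≥ 70% for lesions without flow-wire assessment, or
FFR ≤ 0.80 where FFR was measured.  FFR takes precedence over the visual
estimate in flow-wired vessels, in both directions — a 75% lesion with
FFR 0.85 is negative.

The continuous training target is a worst-case-lesion modified Gensini
score.  Severity bands map percent stenosis to {0,1,2,4,8,16,32} at band
edges {25,50,75,90,99,100} (edges lower-closed, so 75% scores 4); location
multipliers are LM 5, proximal LAD/LCx 2.5, mid LAD 1.5, distal
LAD/RCA/OM/PDA 1, other branches 0.5.  Only the lesion with the maximal
severity × location product contributes.  With collaterals present the raw
product is multiplied by 0.25 **before** the log transform — we read "the
worst-case score" as the raw product, since applying a multiplicative
factor after a logarithm would not be a dampening of the score's scale.
The transform is the natural log with offset 1, `G = ln(1 + raw)`, chosen
so a clean angiogram maps exactly to 0 and ordering is preserved; the
procedure specifies "a logarithm" without base or offset.  Both tables can
be overridden from JSON to express other Gensini dialects.

## Elastic net

The loss is minimized exactly as written — a raw weighted sum of squared
residuals plus `λ(½(1−α)‖W‖₂² + α‖W‖₁)` with an unpenalized intercept —
with **no 1/(2n) normalization**.  Consequences: λ lives on the scale of a
sum of squares, the ridge limit solves `(XᵀX + ½λI)W = Xᵀy`, and any
cross-check against a library that normalizes (e.g. scikit-learn, whose
penalty is `α_sk(l1‖W‖₁ + ½(1−l1)‖W‖₂²)` on a mean loss) must set
`α_sk = λ/(2n)`, `l1 = α`.  The tests do exactly this.

Optimization is cyclic coordinate descent with covariance (Gram-matrix)
updates, fixed ascending coordinate order for determinism, and the exact
intercept recovered from the weighted means.  Features are standardized to
zero mean and unit variance on the training split by default (the shared λ
is otherwise meaningless across heterogeneous feature scales; whether the
original study standardized is unknowable from its description), and
coefficients are mapped back to the original scale.  Zero-variance columns
are pinned to zero with a warning.  Convergence is declared when the
largest per-sweep coefficient change falls below `tol` (library default
1e-8, cap 10⁴ sweeps); non-convergence raises an error carrying the last
objective value.  Inside the GA the pipeline uses `tol = 1e-5` with a
1000-sweep cap — hyperparameter search needs ranking accuracy, not
machine-precision coefficients — and a genome whose fit exhausts that
budget (which happens for essentially unpenalized λ ≈ 10⁻⁴ on the p > n
correlated design) is scored as unfit (−∞) rather than aborting the
evolution.

Sample weights enter the loss as `u_i`; upweighting sets `u_i = factor`
where the Gensini target is at or above the genome's threshold, else 1.
We read the procedure's "upweighting based on a threshold" as targeting
the high-severity subjects: they are the safety-critical ones, and with
factor range [1, 10] the GA can always neutralize the mechanism by
driving the factor to 1, so the directional choice costs nothing.

## Correlation-based feature reduction

Pearson correlations are computed on training rows only (verification
blindness), and a greedy ascending-index scan drops any feature whose |r|
with an already-kept feature exceeds the threshold; of a correlated pair
the smaller index survives.  This rule is deterministic and independent of
scan implementation details.  Zero-variance columns have undefined
correlation: they are flagged, never dropped.  The appended demographic
columns (age, sex, heart rate) bypass the filter.

## Genetic algorithm

Genome = (α ∈ [0,1], log₁₀λ ∈ [−4,2], upweight factor ∈ [1,10], Gensini
weighting threshold spanning the observed target range, correlation
threshold ∈ [0.80,1]).  Fixed operators: per-gene mutation probability
0.33 (half Gaussian perturbations with σ = 10% of the gene range, half
uniform re-draws, clipped to range), single-point crossover at one of the
four internal cut points applied to half of each generation's offspring,
and termination after 10 consecutive generations without strict
improvement of the best fitness.  Choices the procedure leaves open, set
here for small-budget robustness: rank-weighted parent selection,
elitism 2, library-default population 50, and a safety cap on generations
(200 by default; the desk-scale pipeline runs population 30 / cap 30).
Evaluations are cached by genome, and the whole evolution is a pure
function of (data, config, seed).

The fitness thresholds defining the five nested noise subsets are the
60/70/80/90th percentiles of the training-split noise volumes — the
procedure names four thresholds but never their values; percentiles of the
observed distribution keep every subset populated by construction.  The
same four cutoffs are applied to the validation split, giving the 5 + 5
subset AUCs in the fitness sum.  AUC is the Mann–Whitney statistic (ties
counted ½), so fitness is invariant under any strictly monotone transform
of the model output.  A subset containing a single class makes fitness
undefined and is reported as an error naming the subset.

## Threshold selection and verification statistics

The decision threshold is chosen on validation ROC operating points only:
among points with sensitivity ≥ the floor (default 0.90), the one with
maximal specificity, ties broken toward higher sensitivity and then the
lower threshold; scores exactly at the threshold are called positive.
Note the floor is always attainable in principle (calling everyone
positive has sensitivity 1), so the fallback branch (return the
maximal-sensitivity point with a warning) can only trigger for floors
above 1.  The threshold is frozen in the model JSON together with the
kept-column indices, the coefficients and a hash of the feature file, and
verification refuses a model whose hash does not match the cohort being
scored.

Verification metrics use the standard confusion-matrix formulas;
ratios with zero denominators are reported as absent, never as 0.
Confidence intervals are bias-corrected and accelerated (BCa) bootstrap
intervals from subject-level resampling (default 2000 resamples,
jackknife acceleration, ties in the bias correction counted half).
Resamples on which a metric is undefined (e.g. no positives drawn) are
skipped and counted; more than 50% degenerate resamples is an error.  A
zero-variance statistic yields the degenerate interval (v, v) — this is
why empirical coverage should be assessed away from the boundary: at true
sensitivity 0.92 with 25 positives, 12% of replicates are all-correct and
collapse to (1, 1), capping attainable coverage below 0.90 for *any*
resampling interval; at 0.80 the measured coverage is ≈ 0.95.

Cohort comparisons (development vs verification) use a two-sided
pooled-variance Student t-test computable from (mean, sd, n) summaries for
continuous variables and a Pearson chi-square without continuity
correction on the 2×2 counts for categorical ones.  This reconstruction
reproduces the published age comparison (61.5 ± 10.7, n = 512 vs
59.0 ± 9.8, n = 94 → p = 0.0354, displayed as 0.04) from its printed
summaries; which test produced the original table is not stated, and the
categorical rows are not exactly recoverable from printed percentages.

## Synthetic cohort

The generator reproduces the *conditions* of the study — sizes
(339/173/94), ~31% prevalence, demographic moments (age N(61.5, 10.7²)
truncated to [21, 95], 60.2% male, BMI N(31.3, 7²) truncated at 15), a
per-acquisition noise scalar — and a feature matrix with the geometry the
pipeline assumes, not the physics of any signal:

* **Angiograms.**  Diseased subjects (zero-inflated) carry 1 + Poisson(0.8)
  lesions, each critical (stenosis U[70,100]) with probability 0.5 or
  sub-critical (U[20,65]); segments are drawn with realistic frequencies
  (left main rare at 3%).  Lesions in the borderline window [40,70) get an
  FFR with probability 0.5, its mean falling linearly in stenosis
  (1.05 − 0.005·s, sd 0.04), so FFR-positive-but-visually-moderate cases
  exist.  Collaterals appear with probability 0.2 given any ≥ 90% lesion.
  The lesion-free probability is solved **analytically** from the target
  prevalence and the per-lesion positivity rate implied by these
  distributions (a closed form via the normal CDF), so prevalence
  calibration involves no empirical tuning; at the defaults the realized
  prevalence is 0.31 ± 0.02 across seeds.  All lesion-distribution
  choices are stipulations — the study reports no angiographic
  distributions.
* **Features.**  405 features in 40 equicorrelated blocks via a shared
  latent factor (within-block correlation 0.95, so pairs above the 0.907
  filter threshold always exist, while cross-block pairs are null).  Ten
  informative features (the first member of each of the first ten blocks)
  carry `signal_strength ×` the cohort-standardized Gensini score.  The
  entire structured-noise term of subject *i* is scaled by
  `1 + noise_volume_i × noise_scale` (noise volume ~ LogNormal(0, 0.5),
  noise_scale 0.5): noisy acquisitions are genuinely less informative —
  which is what the noise-subset fitness weighting exploits — while
  within-block correlations remain exactly 0.95.
* **Splits.**  Random, stratified by CAD label with largest-remainder
  quotas, hitting (339, 173, 94) exactly and matching train/validation
  prevalence to within one subject.

What the generator does **not** emulate: raw phase-signal physics, ECG
morphology, the real features' marginal distributions or their true
correlation with disease, informative missingness, or site effects.
Passing the end-to-end recovery test therefore demonstrates that the
pipeline is correct and leak-free (the planted signal is recovered to
within 0.05 of the oracle AUC, blindly, on held-out subjects), not that
any particular clinical performance is attainable on real signals.

## Problem sizes and determinism

The analysis scripts and the acceptance run use the full cohort
(606 × 405) with the GA at population 30 for at most 30 generations —
about 400–900 elastic-net fits, a few minutes on one CPU — which is
sufficient for the fitness to plateau near its ceiling on the synthetic
cohort.  Structural tests run on a miniature cohort (160 × 40, GA 6 × 3).
One master seed drives everything: per-stage seeds (cohort, GA, bootstrap)
are spawned from it via `numpy.random.SeedSequence`, file manifests carry
SHA-256 hashes, and reruns are byte-identical.

## Known limitations

* The original study's verification metrics are properties of real,
  unavailable signals; nothing here reproduces them, by design.
* The GA's selection scheme, population size and perturbation width are
  reconstructions; only the mutation probability, crossover scheme and
  stopping rule are fixed by the procedure.
* The upweighting direction (above vs below the Gensini threshold) is a
  documented choice, not a documented fact.
* BCa intervals for proportions at small n are discrete and collapse at
  the boundary (see above); they are reported as computed, without
  continuity corrections.
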
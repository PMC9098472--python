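# Methods

## The generative model

The simulator works at the protein-quantitation level — the matrix a DIA
software suite would export after protein summarization — and makes no
attempt to model peptides, spectra or FDR control. On the log2 scale the
complete (pre-censoring) intensity of protein *g* in sample *s* is

    x_gs = b_g + δ_g(c_s) + u_gs + ε_gs

with

* `b_g ~ N(base_mean, base_sd²)` a per-protein baseline
  (defaults 20 and 2: a realistic log2 dynamic range for LC-MS/MS protein
  intensities);
* `δ_g(c)` the condition shift: 0 for human proteins everywhere; for spike
  proteins 0 in condition 1:25, `spike_delta` (default 1.11) in 1:12 and
  `delta_1to6` (default log2(25/6) ≈ 2.06) in 1:6; spike proteins are
  structurally absent from `humanOnly` samples;
* `u_gs ~ N(0, σ²_species)` the biological (inter-patient) effect,
  independent per protein × sample, with `sigma_patient_human = 1.0` much
  larger than `sigma_patient_spike = 0.25` — the human background comes
  from heterogeneous individuals while the spike is one batch, so its
  between-sample variance is mostly technical;
* `ε_gs ~ N(0, tech_sd²)` technical noise (default 0.25).

`spike_delta` defaults to the benchmark's calibrated constant 1.11 even
though the pipetted ratio arithmetic gives log2(25/12) ≈ 1.06; the constant
is configuration, not derived, and both the generator and the ground truth
use the same value, so the discrepancy never enters any score.

### Missingness

Each sample draws a detection-threshold location
`T_s ~ N(detect_mu, detect_sd²)` and each cell is censored with probability
`logistic((T_s − x_gs) · detect_slope)`, then additionally with the uniform
rate `mcar_rate`. `detect_slope = ∞` degenerates to a hard threshold (a
fair coin exactly at the threshold). The mechanism is monotone — lowering a
cell's intensity never decreases its missingness probability — and, with
the defaults (`detect_mu 17`, `detect_sd 0.5`, `slope 1`, `mcar 0.01`),
produces ≈ 10% MNAR missingness on top of the structural 25% absence of
spike proteins, and reproduces the two hallmark correlations of real
acquisitions: protein mean intensity vs. missingness is negative, and
sample mean vs. sample missingness is positive when thresholds vary
between samples but negative when they are constant (censoring removes the
low tail from the sample mean).

Optionally, `fp_rate` injects spurious spike-protein quantitations into
humanOnly samples (values just above the detection threshold), emulating
false-positive identifications; the default is 0.

### Workflow ensembles

`simulate_workflow_ensemble` emulates several acquisition/software
pipelines over one shared simulation: each member applies an independent
protein dropout (retention drawn uniformly from `[1 − spread, 1]`), and
members beyond the first re-draw their detection thresholds and censoring.
Member 1 always reuses the base realization so that a zero-spread ensemble
of one equals `simulate_benchmark` output exactly. All members share the
sample annotation; their differing protein sets drive the `Combined`
(union) and `Intersection` (> 80% membership) reference lists.

## Preprocessing

Pipeline order is sparsity reduction → normalization → test. A protein
passes SR66/SR90 iff its observed fraction is ≥ 0.66 / 0.90 (a
`strict` switch changes ≥ to >). Removed proteins are recorded and re-enter
the evaluation with p = 1.

Normalizations act on observed values only and never change the
missingness pattern:

* **median** — each sample is shifted additively so its observed median
  equals the grand median of the pre-normalization sample medians (the
  absolute scale is preserved for the Gamma GLM's back-transformation);
* **QN** — each observed value at mid-rank quantile level
  `(r − 0.5)/m_s` (average ranks for ties) is replaced by the reference
  quantile at that level, where the reference is the across-sample mean of
  the per-sample empirical quantile functions (linear interpolation);
  with equal observed counts and no ties this reduces to classic
  order-statistic averaging;
* **TRQN** — QN whose reference and rank map are built from the top `q`
  fraction of each sample's observed values only (default q = 0.5); values
  below the per-sample (1 − q)-quantile are shifted by the offset the
  mapping applies at the cut, which keeps the per-sample transform
  continuous and monotone. This is a reconstruction from the method's
  motivation (an MNAR-contaminated lower tail should not drive the
  reference); with q = 1 and complete data it equals QN exactly.

## Statistical tests

All tests are two-sided, use observed values only (no imputation), and
share one minimum-data rule: fewer than two observed values in either
group gives status `insufficient_data`, whose p-value is coerced to 1 at
evaluation time. The estimated log2FC is the difference of observed-value
group means, undefined if either group is entirely missing. Degenerate
inputs (zero variance in both groups) give p = 1 at equal means and p = 0
otherwise.

* **t_equal / t_welch** — textbook pooled / Satterthwaite t, vectorised
  across proteins; verified per-protein against scipy in the test suite.
* **wilcoxon** — rank-sum test; exact enumeration of the U null
  distribution (dynamic programming) when both groups have ≤ 8
  observations and there are no ties, otherwise the normal approximation
  with tie and continuity corrections, matching scipy's conventions.
* **glm_gamma** — Gamma-family log-link GLM on 2^x. For a two-group
  design the IRLS fixed point has fitted means equal to the group sample
  means, so the converged coefficient is `ln(ȳ₂/ȳ₁)` in closed form; the
  dispersion is the Pearson estimate and the Wald statistic is referred to
  a t distribution with n₁ + n₂ − 2 df. The closed form is verified
  against statsmodels' iterative fit to 1e-10 in the tests.
* **limma-style moderated t** — gene variances are shrunk toward an
  inverse-chi-square prior fitted by method of moments on the log scale
  (digamma/trigamma matching; the trigamma inverse by Newton iteration).
  When the spread of log variances does not exceed its expected sampling
  spread the prior df is infinite and the location is the geometric-mean
  based value. Moderated t uses `s̃² = (d₀v₀ + d_g s_g²)/(d₀ + d_g)` with
  d₀ + d_g reference df. The fit is cross-checked against
  `limma::squeezeVar` via Rscript.
* **SAM** — `d_g = (x̄₂ − x̄₁)/(s_g + s₀)` with the Tusher pooled standard
  error; s₀ is chosen from the percentiles 0, 5, …, 100 of the gene-wise
  standard errors to minimize the coefficient of variation of the median
  absolute deviation of d across ~100 standard-error bins. p-values follow
  the pooled-permutation convention — the fraction, over all permutations
  and all genes, of |d*| ≥ |d_g| — with equality counted at a 1e-9
  relative tolerance so the observed labeling counts itself. All
  C(n, n₂) label assignments are enumerated exactly whenever they fit the
  250-permutation budget (e.g. all 20 at 3 vs 3).
* **ROTS** — statistic family `|x̄₂ − x̄₁|/(α₁ + α₂ s)`; candidates are
  (0, 1), (1, 0) and (a, 1) for a on an 8-point geometric grid between the
  1st and 99th percentiles of s. For each candidate and top-list size
  k ≤ 500, reproducibility is the mean top-k overlap between paired
  group-preserving bootstrap resamples (computed in O(G) per pair via the
  max-rank identity), standardized against permuted-label resamples; the
  maximizing (α, k) is selected and p-values come from its pooled
  permutation null. B = 100 resamplings by default; exact numeric
  agreement with the reference R implementation is not claimed.

Permutation and bootstrap streams are derived from
`(seed, bootstrap id, method index)` via `numpy.random.SeedSequence`, so
each method is independently reproducible and re-running any subset of the
grid gives bit-identical results.

## Evaluation

Positives are the spike proteins of the chosen reference list, negatives
its human proteins. Proteins present in the outcome with a missing result
count as p = 1; reference proteins entirely absent from the outcome are
modeled as *never called* — they cap the maximum reachable TPR (this, not
a p = 1 entry, reproduces the workflow-dependent TPR ceiling of the
`Combined` list). The ROC sweeps the distinct p-values in ascending order;
tied proteins advance TP and FP jointly in one vertex (vertex collapsing;
the trapezoidal area is unaffected by the tie convention). The scaled pAUC
is the trapezoidal area restricted to FPR ∈ [0, 0.1] — with linear
interpolation at the boundary and flat extension beyond the terminal
vertex — rescaled by 100/0.1; it matches pROC's partial `auc`
(specificity ≥ 0.9, uncorrected) to 1e-10 in the tests. Sensitivity uses
the strict convention p < α with all reference spike proteins in the
denominator. RMSE is computed over reference proteins with a defined
estimate; the excluded count is reported alongside.

The `Intersection` membership floor is `⌊0.8·W⌋ + 1` (strictly more than
the threshold fraction), which gives 14 of 17 workflows at the default
threshold.

## Bootstrap design and data characteristics

Group sizes span 3…23 with 100 replicates each (2100 bootstrap datasets);
each (size, replicate) cell derives its seed from the base seed so the
design is reproducible end-to-end and individual cells can be recomputed in
isolation. Draws are with replacement within each of the two compared
conditions (default 1:25 vs 1:12); duplicated samples are materialized as
duplicated columns — standard bootstrap semantics, no collapsing. Per
bootstrap, the data characteristics are the pooled skewness and excess
kurtosis (bias-uncorrected moment estimators), the per-group median
protein variance and their ratio, and the missing-cell fraction.

## Problem sizes used by the shipped runs

The test suite exercises the directional benchmark at 1000 human + 200
spike proteins, group sizes {3, 10, 23} with 20 bootstrap replicates each,
sparsity levels NoSR/SR66/SR90 and tests SAM/Wilcoxon/GLMgamma; the
acceptance script runs the same layout with 10 replicates and adds the
moderated t. Null calibration uses 2000 proteins at 10 samples per group;
the null model draws raw-scale intensities from a Gamma distribution
(shape 20, i.e. log2-SD ≈ 0.33), so that every test's distributional
assumption — near-normal log2 values for the t-family and Gamma raw values
for the GLM — is approximately met and the check measures calibration
rather than robustness to misspecification. (Under a log-normal null with
log2-SD 1 the Gamma GLM Wald test intrinsically rejects at ≈ 6.7%; that is
a property of the model pair, not of the implementation, which matches
statsmodels to machine precision.)

## What the generator does and does not emulate

It does emulate: the two-species design and its exact arithmetic, a large
human-to-spike variance gap, MNAR censoring with sample-dependent
thresholds and both of its observable correlation signatures, structural
absence of spikes in a quarter of the samples, optional false-positive
spike identifications, and workflow-to-workflow protein-set variation.

It does not emulate: per-protein variance heterogeneity within a species
(each species has one biological SD), heavy-tailed or outlier-prone
patient effects, a shared per-patient latent factor (patient effects are
protein × sample independent; a latent factor is a possible extension),
intensity-dependent technical variance, or anything below the protein
level.

Two consequences matter when reading results on synthetic data. First,
because within-species variance is constant, the empirical per-protein
standard error carries species information (all spike proteins occupy the
low-SE stratum); a variance-stabilizing offset such as SAM's s₀ then
compresses exactly the signal-bearing axis, and the Tusher selection
criterion — whose purpose is to flatten the spread of d across SE bins —
legitimately drives s₀ to the top of its grid at small n. On data like
this, plain t ranking is optimal and SAM cannot beat it; the real-data
advantage of permutation tests rests on variance heterogeneity and heavy
tails that this generator deliberately omits. Second, passing directional
checks here demonstrates the machinery (filters bite, power grows with n,
rankings behave), not that any test ordering transfers to real
acquisitions.

## Numerical choices

* Tolerances: QN/TRQN assertions at 1e-12; pAUC oracle agreement at 1e-10;
  Gamma GLM IRLS equivalence at 1e-10; trigamma-inverse Newton stops at a
  1e-10 relative step.
* Ties: average ranks in QN and in the rank-sum test; ROC vertex
  collapsing for tied p-values; SAM/ROTS pooled-null counting includes
  equality within 1e-9 relative tolerance.
* Degenerate inputs: zero-variance proteins give p ∈ {0, 1} by the
  equal/unequal-means convention; samples with no observed values are an
  error in normalization; empty post-filter protein sets propagate as
  `preprocessing_empty` rows rather than exceptions.
* The corrupted-sample rule of real datasets is generalized to an
  `exclude` column in the annotation file rather than a hard-coded sample
  id.
* All randomness flows through `numpy.random.SeedSequence` spawning with
  purpose keys (baselines, patient effects, thresholds, censoring,
  dropout, permutations), so changing one component's draw does not
  perturb the others.
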
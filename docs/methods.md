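# Methods

## Study design being modelled

A stratified cross-sectional cohort of 24 CNT/F manufacturing workers,
12 per exposure group. Group membership is defined on personal
breathing-zone inhalable elemental carbon (EC): High > 0.5 µg/m³, Low
below the 0.13 µg/m³ exposure limit of quantification. Three exposure
metrics are carried per worker — inhalable EC, respirable EC (µg/m³)
and CNT/F structure count (structures/cm³) — together with binned
demographics (age, education, exposure duration), health-history flags,
and five serum cumulative inflammatory potential (SCIP) covariates
(log fold-change induction of IL6, CCL2, TNFα, VCAM, ICAM in endothelial
cells). The serum peptidome is a peptide × worker intensity matrix from
label-free ion-mobility LC-MS with intensity-dependent missingness.

## Synthetic cohort generator

Exposure metrics are lognormal. Given a published arithmetic group mean
m and standard error SE (n = 12), the underlying normal parameters are
moment-matched as σ² = ln(1 + s²/m²), µ = ln m − σ²/2 with s = SE·√12,
so the lognormal reproduces the arithmetic mean and variance exactly.
Group-defining bounds on inhalable EC are enforced by per-worker
rejection sampling; the raw moment-matched distribution is exposed
separately (`sample_metric`) so the matching formulas remain testable
without truncation bias. Binned covariates are discretized clipped
normals and flags are Bernoulli draws at the published group
frequencies; metrics are drawn independently within worker.

## Synthetic peptidome generator

Latent log2 intensities are built per feature class:

- **null** — per-peptide baseline ~ N(18, 3²) log2 units plus technical
  noise; no structure.
- **responsive** (859 by default) — baseline + β·(x − x̄) + ε, where x is
  the worker's composite exposure (log∑Exp = Σ log₁₀ of the three
  metrics). Group-mean effects |β·Δx| are drawn from 1–4 log2 units with
  random sign, as in a real volcano plot; the random sign also keeps
  sample-median normalization unbiased. The noise variance is solved
  from Var(β·x)·(1 − r²)/r² so the expected coefficient of determination
  against x equals `target_r2` (default 0.85).
- **top-discriminant** (41 by default) — Low-group level placed just
  above the intensity LOQ (detected but effectively at the
  quantification floor, noise tail left-censored) with a High-group
  shift of 10–13 log2 units (3–4 orders of magnitude), plus technical
  noise only. These are deliberately step-like: the biomarker panel the
  pipeline must recover.
- **nuisance** (60 by default) — linear in a non-exposure covariate
  (SCIP IL6 or age bin), exercising the correlation-intersection logic
  that rejects covariate-driven false biomarkers.

Per-worker depth offsets ~ N(0, 0.3²) log2 units are added to every
cell; median centering is expected to remove them. Missingness is
left-censored: cells at or above the LOQ (2¹⁴ by default) are always
observed; below it, detection is logistic in the log2 distance from the
LOQ, so a masked cell always hides a sub-LOQ latent value. A
missing-completely-at-random mode (`mcar_rate`, `censor=False`) supports
null-calibration experiments.

`noise_sd` — the technical noise floor — is the one genuinely free
parameter: within-group technical variance is not published. It
defaults to 0.15 log2 units (≈ 11 % CV), the replicate-level precision
of strong label-free MS signals. Within-group *biological* variation of
responsive peptides is not a separate dial: it emerges from the
within-group spread of the composite exposure through β plus the
r²-calibrated residual.

What the generator does **not** emulate: correlated missingness beyond
intensity dependence, batch/run-order drift, heavy-tailed or
peptide-dependent noise, correlations among the three exposure metrics
within worker, and any real biological pathway structure. Passing
recovery tests therefore demonstrates the pipeline's correctness under
its own model assumptions, not performance on real serum data.

## Alignment

The published workflow names a proprietary clustering tool without an
algorithm, so a deterministic substitute is defined: events sorted by
descending intensity seed clusters greedily; an event joins the cluster
whose running intensity-weighted centroid lies within all three
tolerances (± 2 min RT, ± 4 drift bins inclusive, ± 6 ppm of the
centroid mass), ties broken by smallest mass difference. On instances
whose clusters are separated by more than twice each tolerance this
provably coincides with exhaustive single-linkage components, which is
the oracle used in tests. The matrix LOQ defaults to the smallest
clustered intensity and is overridable.

## Preprocessing

Order: detection filter → median centering → LOQ imputation → log2 /
fold standardization. The published description does not fix whether
centering preceded imputation; centering first means imputed cells sit
exactly at the LOQ on the centered scale, which keeps the censoring
floor common across samples. Median centering is multiplicative — each
column is scaled so its observed median equals the geometric mean of
column medians — equivalent to an additive shift in log space and
positivity-preserving for the log2 transform. Detection filtering
defaults to the both-groups rule (fraction ≥ threshold in each group),
with an either-group switch, because the published wording alternates
between "per group" and "of workers". Standardization subtracts the
Low-group mean per peptide after log2, so the Low mean is exactly zero
and the operation is idempotent.

Known artifact: when a large planted (or real) responsive fraction
shifts predominantly one way, column medians absorb part of the signal
and the univariate screen inflates slightly on null features. Type-I
calibration is therefore assessed on a null-only configuration; in
signal-dense runs the inflation is absorbed downstream by the R²
correlation filter.

## Statistics

- Student's *t*: pooled variance (not Welch), df = n₁+n₂−2, two-sided.
  Zero pooled variance returns p = 1 (equal means) or p = 0 (unequal)
  with a degeneracy flag.
- Benjamini–Hochberg: step-up, order-preserving, with family size m
  allowed to exceed the number of supplied p-values so that the k
  smallest members of a larger test family can be adjusted (the absent
  larger p-values cannot lower any step-up minimum).
- Kruskal–Wallis: tie-corrected H, χ² p on k−1 df; an all-identical
  sample short-circuits to H = 0.
- One-sample z: one-sided upper tail by default (a vote count can only
  be meaningfully *larger* than random); two-sided optional. This
  one-sided convention reproduces the published q = 0.0029 for Z = 3.84
  at rank 5 of a 237-test family.
- Power: noncentral-t power of the two-sided pooled t-test;
  noncentrality (δ/σ)·√(n/2). The α and variance behind any particular
  published power figure are exposed as parameters, not hard-coded; a
  helper supplies the median per-peptide pooled SD of a matrix.

## Model building

- The composite exposure is the equal-weight sum of log₁₀ metrics; a
  weighted variant exists because the published construction states only
  a single combined axis. Metrics must be strictly positive.
- The model space is 5 base exposure terms × covariate subsets of size
  ≤ 2 from a 9-covariate pool = 230 models (`data/models.yaml`). The
  originally reported count (237) is not reconstructible from its
  description; the space is configurable and the count is logged.
- AICc uses k = coefficients + intercept + variance parameter and
  AIC = n ln(RSS/n) + 2k, the Gaussian-likelihood AIC up to the
  model-independent constant n(ln 2π + 1); tests verify agreement with
  the explicit likelihood computation after removing that constant. An
  RSS at rounding level (≤ machine-ε × ‖y‖²) is flagged degenerate with
  AICc = −∞.
- Voting: with δ = 0 each peptide casts one vote for its minimum-AICc
  model; an exact tie splits the vote equally among tied models, which
  keeps counts summing to the peptide total, makes the tabulation
  invariant to peptide ordering, and sends the all-models-identical
  edge case to uniform counts with z = 0. With δ > 0 a peptide votes
  fully for every model within δ AICc units of its minimum (published
  per-model counts overlap, so an overlap mode is required). The z
  null is the empirical mean/SD of counts across all models — the
  simplest reading of "significance from random".
- Correlation tiers use adjusted R² at 0.4 (moderate) and 0.7 (strong);
  the refinement set is the intersection of strong sets across all
  selected model variants (default: the composite alone, + IL6,
  + IL6 + age), the conservative reading that guards against
  orthogonal covariates inflating R².

## Discriminant model

- PLS-DA: single centered {0,1} response, features autoscaled,
  zero-variance features dropped with a warning. NIPALS with deflation,
  tolerance 1e-10, ≤ 500 iterations per component (a single response
  converges immediately; the loop is kept for generality). Two
  components by default — enough for a 2-D scores plot — configurable.
  Component extraction stops early if the residual response or score
  variance vanishes.
- VIP as defined above; Σ VIP² = p is asserted on every fit in tests.
- Cross-validation refits everything inside each fold, including the
  autoscaling constants — the published text does not state this, but
  computing scaling on the full data would leak held-out information
  into Q². Q² = 1 − PRESS/TSS with TSS about training-fold means;
  accuracy assigns the nearest coded class; the class probability is
  the continuous prediction linearly rescaled between the coded values
  and clipped to [0, 1] — chosen for determinism and monotonicity.
- Monte-Carlo leave-n-out holds out a stratified quarter of the cohort
  (6 of 24) per repeat, 50 repeats by default; leave-one-out is also
  implemented since both schemes are named in the source description.
  Setting the holdout to half the cohort reproduces the split-half
  validation design (build on 12 random workers, classify the other 12,
  50 resamplings).
- PCA is centered (not scaled) SVD on the full reproducible matrix;
  explained fractions are eigenvalue shares and sum to one.

## Problem sizes and determinism

All randomness descends from one root seed via `numpy SeedSequence`
splitting, so stages are independently reproducible and identical seeds
give bit-identical outputs. The default synthetic scale (12,000
features × 24 workers) runs the full pipeline in under a second per
seed; acceptance evaluation uses 10 cohorts for the cross-validation
targets and 20 for vote-recovery and VIP-recall checks, sizes at which
the stochastic acceptance margins are stable.

## Known limitations

- The alignment algorithm is a declared substitute for an unpublished
  proprietary tool; only its tolerance semantics are shared.
- Median centering assumes a mostly-stable peptidome; strongly
  asymmetric responses bias it (see Preprocessing).
- The AICc model space approximates, not reproduces, the original 237
  models.
- Q²/accuracy acceptance values are properties of the synthetic
  analogue at its planted effect sizes, not re-derivations of the
  original cohort's numbers, which require the protected data.
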
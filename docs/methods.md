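# Methods

`combatkit` harmonizes continuous feature tables (the motivating case is
radiomic features extracted from multi-site CT cohorts) across categorical
*batch effects* — non-biological acquisition factors such as contrast
enhancement, reconstruction-kernel resolution class, or scanner
manufacturer — while protecting the signal of clinical covariates. This
note records the models, the estimator conventions, the numerical choices,
and what the synthetic benchmark does and does not demonstrate.

## The location/scale harmonization model

For feature g, sample j in batch i:

    Y_ijg = alpha_g + X_j beta_g + gamma_ig + delta_ig * eps_ijg,
    eps_ijg ~ N(0, sigma_g^2)

`alpha_g` is the grand intercept, `X` the protected-covariate design,
`gamma_ig` an additive and `delta_ig` a multiplicative batch effect.
Fitting follows the standard empirical-Bayes recipe:

1. **Least squares.** Y is regressed feature-wise on batch indicators plus
   covariates. One-hot batch coding with the grand mean defined as the
   sample-size-weighted mean of the level intercepts enforces the
   identifiability constraint `sum_i n_i gamma_hat_ig = 0` exactly.
2. **Standardization.** `Z = (Y - alpha_hat - X beta_hat) / sigma_hat`,
   where `sigma_hat^2` is the mean squared residual over **all n samples**
   (denominator n). Per-batch raw estimates are the batch means of Z
   (`gamma_hat`) and the batch variances with denominator `n_i - 1`
   (`delta2_hat`).
3. **Empirical-Bayes shrinkage** (`eb=True`, the default). Per batch, a
   normal prior on location and an inverse-gamma prior on squared scale are
   estimated across features by the method of moments; the conditional
   posterior means are iterated until the maximum absolute relative change
   falls below 1e-4 (cap 1000 iterations, error on non-convergence).
   Shrinkage pulls every `gamma*`/`delta2*` toward the batch-level prior,
   stabilizing estimates when batches are small relative to the feature
   count.
4. **Adjustment.** `Y* = sigma_hat/delta* (Z - gamma*) + alpha_hat + X beta_hat`:
   the batch contribution is removed, the covariate contribution restored.

These conventions — including the deliberately mismatched variance
denominators in step 2 — reproduce the Bioconductor `sva::ComBat`
parametric path; the test suite pins element-wise agreement to 1e-6 on a
frozen 20x5 fixture harmonized once with sva (`tests/data/`). Two
consequences worth knowing:

* **Harmonization is only *nearly* idempotent.** Because the pooled
  variance uses denominator n while batch variances use `n_i - 1`, a second
  pass rescales residuals by `sqrt((n - I)/n)` (~0.5% at n=200, I=2
  batches) even without EB; with EB, the intentional under-correction of
  shrinkage leaves slightly more. A second pass never re-introduces a
  location effect (the residual batch-mean gap is exactly zero).
* **EB needs at least two non-constant features**, since the hyperpriors
  are moments across features; with a single feature, refit with
  `eb=False`.

Degenerate inputs: constant features are passed through unharmonized with a
logged warning (never a division by zero); missing values are rejected at
load time with no imputation; a covariate aliased with the batch indicators
is reported by name via a pivoted-QR rank check; batch levels are ordered
alphabetically so parameter indexing is reproducible.

## KS percent-significant metric

Residual detectability of a batch effect is the percentage of features —
**out of the original feature count**, even after dropping — whose
distributions differ across batch levels by a two-sample two-sided
Kolmogorov–Smirnov test at strict p < alpha (default 0.05, no
multiple-testing correction; the KS test is preferred over rank tests
because feature distributions are often multimodal). The exact p-value is
used when the combined sample size is <= 1000, the asymptotic one above.
With more than two levels the feature's p-value is the minimum over all
pairwise comparisons — a feature is as significant as its most discordant
pair — and each level must hold at least 3 samples.

## Nested ComBat and NestedD

Given a list of batch effects, each iteration harmonizes the current matrix
separately by every remaining effect (clinical covariates protected;
already-harmonized effects **not** protected), scores each candidate by the
total KS-significant feature count, and keeps the minimizer. Scoring sums
counts over **all original** batch effects by default so that the
per-iteration criterion matches the final metric; `score_scope="remaining"`
restricts it to unharmonized effects. Ties break by input-column order, so
the procedure is fully deterministic. The dropping variant (NestedD)
removes, after each selection, every feature still significant for any
original batch effect (`drop_scope="any"`; `"selected-effect"` narrows it),
which mainly prunes features whose bimodal shape violates the Gaussian
model. The final report always uses the original feature count as
denominator, so dropping can only lower, never inflate, the percentage.

## GMM scan grouping

When bimodality stems from an unrecorded variable, a surrogate batch label
is estimated from the data: each feature is z-scored (so log-likelihoods —
and hence AICs, 2k − 2 ln L with k = 5 — are comparable across features;
hard assignments are unaffected by the affine rescaling) and fitted with a
two-component univariate Gaussian mixture (EM, k-means initialization, 10
restarts, tol 1e-6, max 500 iterations, fixed seed). Components are ordered
by mean so labels are invariant to EM permutation. Models assigning fewer
than 25% of scans to either cluster by hard assignment are filtered out
(fitted mixing weights are also reported for audit); non-converged fits are
excluded. One surviving model is selected by AIC and its assignments become
the binary grouping used as a ComBat batch effect, optionally followed by
ComBat on each known batch effect.

The AIC direction is configurable. `aic="max"` follows the originally
published recipe verbatim; with k fixed at 5 for every candidate, however,
the highest AIC is simply the *worst* likelihood, so the default logs a
warning and `aic="min"` (conventional best-model selection) is what
actually recovers a planted bimodal feature — the recovery tests and the
acceptance script use `"min"`.

## Synthetic benchmark

The generator produces `Y = sum_e loc_e[label] + (prod_e scale_e[label]) * eps
+ hidden_shift + covariate_effect` with `eps ~ N(0, noise_sd^2)` — i.e. the
batch scale acts on the noise exactly as the harmonization model assumes.
Baselines are standardized so effect sizes read in SD units. Per batch
effect: level proportions are apportioned exactly (largest remainder),
per-level location shifts are drawn N(0, location_sd^2) and
weighted-centered (making the true gamma identifiable), scale factors are
uniform on `scale_range`. A hidden binary variable adds a `separation`-SD
mean shift to a chosen fraction of features and appears only in the ground
truth, never in the metadata. Default desk-scale conditions mirror a
multi-site lung-CT cohort: 85 samples x 100 features, three two-level batch
effects with realistic level imbalance, one protected binary covariate with
a 1 SD effect.

What the benchmark shows: parameter recovery (fitted location shifts within
2 SE of truth for >=90% of cells), near-complete batch-effect removal
(pre ~88%, post ~0% significant at n=200, location SD 1.5, scale 0.7–1.4),
KS type-I calibration on null data, greedy-selection correctness, latent
grouping recovery (6 SD separation, 60/40 split: source feature found and
>=95% label agreement in every tested seed). What it does not show: real
radiomic features are heavily correlated, non-Gaussian within batch, and
their batch effects need not be additive/multiplicative on the noise term
alone — passing here demonstrates correctness of the estimators under the
model's own assumptions, not field performance.

Two measurement definitions deserve emphasis:

* **Covariate preservation** is judged on the covariate's *effect size* —
  the mean case-minus-control contrast over truly affected features —
  which changes by <10% (typically <6%) after harmonization. Individual
  per-feature contrasts move more, because in any finite sample the batch
  term is partially aliased with the covariate (imbalance ~ n^-1/2) and
  removing it legitimately shifts each contrast toward its true value.
* **NestedD vs Nested** is compared where residual significance survives
  plain Nested at all: small cohorts (n=60) with wide scale ranges, where
  EB shrinkage leaves detectable scale differences. There NestedD's final
  count (original-feature denominator) is never larger and is strictly
  smaller in aggregate.

## Problem sizes

Simulated checks use 60–200 samples and 11–200 features, 8–20 replicate
seeds per property — the scale of the motivating cohorts — and complete in
a few minutes end to end. All randomness flows from explicit integer seeds;
every pipeline is byte-for-byte reproducible under a fixed seed.

## Known limitations

* Parametric EB only (normal/inverse-gamma priors); no non-parametric,
  longitudinal, or GAM variants.
* Mixtures are limited to two components and one global grouping from a
  single feature; per-feature groupings are out of scope.
* The KS multi-level rule (minimum pairwise p, no multiplicity correction)
  is deliberately conservative and will over-flag with many levels.
* No missing-data support by design: tables must be complete.
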
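# Methods

## The measurement model

All three pipelines target the same estimand: the per-ROI standardized
case-control difference in a dataset pooled over sites. The working model
for ROI `r`, site `i`, subject `j` is

    y_rij = alpha_r + X_ij . beta_r + gamma_ri + delta_ri * eps_rij,
    eps_rij ~ N(0, sigma_r^2)

where `X` holds diagnosis (0/1), age (years, unscaled) and sex (0/1) plus
any further covariates (e.g. ICV), `gamma_ri` is the additive and
`delta_ri` the multiplicative (residual-SD scaling) site effect. The key
empirical-Bayes assumption is that within a site the `gamma_ri` across
ROIs are draws from `N(gamma_bar_i, tau_i^2)` and the `delta_ri^2` draws
from `InvGamma(a_i, b_i)`: site effects differ per ROI but share a
site-level distribution, so each per-ROI estimate can borrow strength
from all others.

## ComBat fitting (what `combat_fit` computes)

1. **Zero-variance screen.** ROIs whose *observed* cells have zero range
   are flagged and excluded from fitting; they pass through application
   unchanged, with a warning, so output columns are stable.
2. **Temporary imputation.** For fitting only, each missing cell is
   replaced by the fitted value of an OLS of that site/ROI's observed
   cells on [intercept, diagnosis, covariates]. A rank-deficient local
   design (e.g. single-sex site) falls back to the site/ROI mean; fewer
   than (#design columns + 1) observed cells is an error naming the
   site/ROI pair. Imputations never leave the fit: application works
   cell-wise on observed cells and missing stays missing.
3. **Standardization.** Pooled least squares with one indicator per site
   plus the covariates; the grand intercept `alpha_r` is the
   site-size-weighted mean of the site intercepts (the weighted
   sum-to-zero identifiability constraint), `sigma_r^2` the mean squared
   residual (divisor n). Data are standardized to
   `z = (y - alpha - X beta) / sigma`.
4. **Empirical Bayes.** Per-site means/variances of `z` are the raw
   estimates; hyperparameters come from method of moments across ROIs;
   the shrunken `gamma*` (posterior mean under the normal prior) and
   `delta*^2` (posterior mode under the inverse-gamma prior) are solved
   by the standard fixed-point iteration, tolerance 1e-4 on the maximum
   relative change, 1000-iteration cap.
5. **Application.** `y* = alpha + X beta + (z - gamma*)/delta* * sigma`,
   i.e. covariate effects — including diagnosis, which is passed to the
   fit precisely so the disease signal is estimated and protected rather
   than absorbed into site effects — are put back.

On complete data steps 3–5 reproduce the canonical sva/neuroimaging
ComBat; the test suite pins agreement with a frozen `sva::ComBat` run to
1e-6. The fit/apply split means a model trained on one cohort can
transform another (any site present at apply time must have been fitted;
anything else is an error rather than a silent refit).

When several measurement types are harmonized, the default is a single
ComBat over all ROIs (they share scanner-level causes); `harmonize_groups`
runs one fit/apply per type instead. On synthetic data the two options
give Hedges' g within ±0.02 of each other, mirroring the near-identical
results expected when the types are related.

## Effect sizes and inference

* **Hedges' g**: `g = J * coef / sd_resid` with
  `J = 1 - 3/(4 df - 1)`, `df = n1 + n2 - 2 - #covariates`, and
  `var_g = J^2 [(n1+n2)/(n1 n2) + d^2/(2(n1+n2))]`. The standardizer is
  the model residual SD in every pipeline — for ME-Mega the *within-site*
  residual SD, not sqrt(residual + site variance), so g is comparable
  with ComBat-Mega where site variance has been removed.
* **RE-Meta** pools per-site g with weights `1/(var_i + tau^2)`; tau^2 by
  REML (fixed-point iteration to the restricted-likelihood stationary
  point; DerSimonian-Laird available), two-sided normal p on the pooled
  estimate. Sites contributing fewer than 2 subjects per diagnosis group
  to an ROI are dropped from that ROI's pooling only (g variance is
  undefined there); such sites still feed harmonization and mega models.
* **ME-Mega** fits a random-site-intercept model per ROI by REML
  (statsmodels MixedLM). Satterthwaite degrees of freedom are not
  available there, so p-values use a t reference with df = n − p − 1;
  boundary fits (site variance 0) are kept, coinciding with pooled OLS.
* **ComBat-Mega** is plain OLS per ROI on harmonized data, t p-values.
* **Holm** step-down adjustment over the full ROI family of a run
  (thickness + area + volume jointly).
* CIs are `g ± 1.96 sqrt(var_g)` throughout.

## Method comparison machinery

* **Permutation scheme** (Draper-Stoneman): diagnosis labels are shuffled
  within each site; measurements, covariates and design stay fixed, and
  the identical permuted dataset feeds every pipeline, so method
  differences cannot be confounded by permutation differences. ComBat is
  refit on every permutation (its fit sees the labels).
* **Significance comparison**: per permutation, both pipelines are rerun
  and only the ROI-median of `logit(p_A) - logit(p_B)` is kept
  (`logit(p) = ln(p/(1-p))`, clipped at 1e-15 so underflowed p stay
  finite). Using the median avoids per-ROI multiplicity. The one-sided
  probability uses +1 smoothing, `(1 + #{null <= observed})/(n_perm + 1)`,
  whose floor is the permutation granularity. A self-comparison is
  degenerate by construction (all differences tie at zero).
* **Subset power**: ROIs taken as true positives are those with Holm
  p < 0.001 under *all* pipelines on the full data; each replicate
  samples sites without replacement, reruns the pipelines, and scores
  detection at Holm p < 0.05; per-ROI powers are compared by Wilcoxon
  signed-rank (zero differences dropped; a fully tied comparison is
  reported as NaN rather than a p-value).
* **Empirical FWER**: proportion of permutations with any Holm p < 0.05;
  shares its permutation stream with the significance comparison for the
  same master seed.
* **Variance-ratio diagnostic**: per ROI, covariate-adjusted pooled
  within-site residual variance over covariate-adjusted total residual
  variance (site ignored). Ratios near 1 mean site explains nothing; the
  gain from harmonization concentrates in low-ratio ROIs. The
  covariate-adjusted definition is an interpretation choice; the raw
  variant differs only through covariate imbalance across sites.

All randomness derives from one master seed through fixed
`numpy.random.SeedSequence` spawn keys (namespace, counter), so nested
loops are bit-reproducible and independent of execution order.

## Synthetic data

The generator draws directly from the measurement model above: per-site
mean additive effect from `N(0, gamma_spread^2)` with per-ROI scatter
`gamma_tau` (both in residual-SD units), `delta^2` from an inverse-gamma
normalized to unit mean (shape must exceed 2 so moments exist), diagnosis
effects specified on the Hedges'-g scale (`beta_dx = g * sd`), per-site
mean ages, Bernoulli sex, per-site case fractions, and MCAR missingness.
The `enigma_like_preset` mimics a large schizophrenia consortium dataset:
33 sites of log-uniform size (30–400, rescaled to ~6000 total, floor 12
so per-site imputation stays estimable), 48% cases, 156 ROIs, per-ROI g
uniform on [-0.45, 0.28], 5% missing cells.

What the generator does *not* emulate: spatial correlation between
neighboring ROIs (columns are independent given site effects), site-by-
covariate confounds (e.g. older samples at noisier sites), non-normal
residuals, and MNAR missingness. Consequently passing tests demonstrate
correctness of the estimators under the assumed model, not robustness to
those violations; in particular, independent ROIs make the Holm FWER sit
near its nominal ceiling (~0.049 at 40 ROIs) whereas strongly correlated
real ROIs push it well below.

## Problem sizes and numerical choices

Simulation-based tests use desk-scale problem sizes chosen to keep the
full suite in the tens of minutes while leaving the tested phenomena
clearly resolved: FWER at 20 sites x 100 subjects x 40 ROIs with 200
permutations; parameter recovery at 10 sites x 500 subjects x 50 ROIs;
the power/significance ordering at 20 sites of 15–120 subjects (100
subset replicates, 200 permutations); calibration from 500 independent
null replicates of 10 sites x 30. The heterogeneous-ordering conditions
deliberately use many small sites with unbalanced case fractions
(U(0.15, 0.85)) and strong additive/multiplicative site effects — the
regime where site-aggregated meta-analysis demonstrably loses power to
mega-analytic pooling.

Numerical details worth knowing: EB iteration tolerance 1e-4 (relative),
REML tau^2 fixed point to 1e-10; pooled variance uses divisor n to match
canonical ComBat; rank checks use exact matrix rank and reject rather
than silently dropping columns; covariates are never centered or scaled
internally, so harmonized output stays on the input measurement scale.

## Known limitations

* Raw p-values of RE-Meta are mildly conservative under exact
  homogeneity (tau^2 truncation at zero), visible only at very high
  replication counts; all familywise error statements hold a fortiori.
* Only the parametric (normal / inverse-gamma) ComBat priors are
  implemented; no nonparametric, longitudinal, or covariance-preserving
  variants.
* Subjects with missing covariates are rejected at load, not imputed.
* The CLI's `--grouping per-type` infers types from ROI-name prefixes
  (`thick_`/`area_`/`vol_`); arbitrary groupings are available through
  the Python API (`harmonize_groups`).
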
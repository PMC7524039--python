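# harmon

Multi-site harmonization and case-control comparison of ROI-level brain
morphometry tables.

Pooling subject-level FreeSurfer measurements (cortical thickness and
surface area of Desikan-Killiany parcels, subcortical volumes) across
many scanning sites buys statistical power but imports *site effects*:
each scanner/sequence shifts the measurements additively and scales their
residual spread. `harmon` implements and compares the three standard ways
consortium analyses deal with this:

* **RE-Meta** — per-site linear models `y = α_i + Xβ_i + ε` are reduced
  to per-site Hedges' g, then pooled by random-effects meta-analysis with
  inverse-variance weights `w_i = 1/(var(g_i) + τ²)` (τ² by REML, or
  DerSimonian-Laird);
* **ME-Mega** — a linear mixed-effects mega-analysis of the pooled
  individual data with a random site intercept,
  `y = α + Xβ + γ_i + ε`;
* **ComBat-Mega** — empirical-Bayes harmonization first. ComBat models
  `y_rij = α_r + X_ij β_r + γ_ri + δ_ri ε_rij` per ROI r and site i,
  assumes the additive effects γ and squared multiplicative effects δ²
  share normal / inverse-gamma distributions across ROIs, shrinks the
  per-site estimates toward those priors, and returns
  `y* = α + Xβ + (y − α − Xβ − γ*)/δ*`. Harmonized data are then
  analyzed with plain per-ROI linear models, no site term.

The ComBat implementation separates **fitting** (`combat_fit`, which
tolerates missing cells via temporary per-site/per-ROI covariate
imputations and drops zero-variance ROIs) from **application**
(`combat_apply`, which transforms observed cells only and never imputes),
so parameters can be trained on one dataset and applied to another. On
complete data it matches the reference Bioconductor `sva::ComBat` to
better than 1e-6.

Every pipeline reports per-ROI Hedges' g (small-sample corrected
standardized mean difference), its variance, 95% CI, and raw +
Holm-adjusted p-values. An evaluation layer compares pipelines the way
method studies do: Draper-Stoneman within-site permutation of diagnosis
labels feeding identical permuted data to every pipeline, with the
ROI-median difference in logit-transformed p-values as the test
statistic; small-subset power with Wilcoxon signed-rank comparisons; and
empirical familywise error rates. A seeded synthetic-data module
generates multi-site case-control datasets from the same generative model
with known ground truth.

## Worked example

Simulate a 33-site schizophrenia-like dataset at quarter scale, fit and
inspect the harmonization, and run the harmonized comparison:

```sh
harmon simulate --seed 7 --scale 0.25 --out-dir sim
harmon fit --data sim/measurements.csv --cov sim/covariates.csv --out model.json
harmon compare --data sim/measurements.csv --cov sim/covariates.csv \
    --pipeline combatmega --out results.csv
```

The fit prints the model card (per-site prior hyperparameters: the prior
mean `gamma_bar` and variance `tau2` of the additive effects, the
inverse-gamma `a_prior`/`b_prior` of the squared multiplicative effects):

```
ComBat harmonization model
==========================
sites:            33
ROIs:             156 (156 included, 0 zero-variance excluded)
covariates:       dx, age, sex

site               gamma_bar        tau2     a_prior     b_prior
site00                0.6432      0.1753      4.6093      3.6687
site01               -0.5053      0.1125      5.9022      4.8979
```

and the comparison summarizes the per-ROI results written to
`results.csv` (one row per ROI with g, variance, CI, p, Holm p):

```
ComBat-Mega case-control comparison
========================================
ROIs analyzed:      156
Holm p < 0.05:      75
median |g|:         0.172
median 95% CI width: 0.207
```

Here 75 of 156 ROIs survive Holm correction at the simulated effect sizes
(|g| up to 0.45 at roughly 1500 subjects); the median |g| of 0.172 sits in
the planted range.

From Python, comparing the statistical significance of two pipelines on a
heterogeneous 12-site dataset:

```python
from harmon import SyntheticConfig, generate, compare_significance

cfg = SyntheticConfig(n_sites=12, site_sizes=(15, 120), roi_counts=(12, 0, 0),
                      effect_g=0.3, case_fraction=(0.15, 0.85),
                      gamma_spread=0.6, gamma_tau=0.4, seed=11)
data, cov, truth = generate(cfg)
r = compare_significance(data, cov, "ComBat-Mega", "RE-Meta", n_perm=199, seed=3)
print(r.summary())
```

```
Significance comparison: ComBat-Mega vs RE-Meta
==================================================
observed median logit-p difference: -1.684
null medians (95% central range):   [-0.732, 0.354]
permutations:                       199
one-sided probability (A <= B):     0.005
(negative difference = pipeline A more significant)
```

The observed median of −1.68 lies far below anything produced by label
permutation, so the harmonized pipeline's smaller p-values are not a
chance artifact (permutation probability 0.005, the granularity floor is
1/200).

## Layout

| module              | contents                                                      |
|---------------------|---------------------------------------------------------------|
| `harmon.data`       | `ROIMatrix`, `CovariateTable`, design construction, CSV I/O   |
| `harmon.combat`     | `ComBat` model, `CombatModel` results, fit/apply, grouping    |
| `harmon.pipelines`  | Hedges' g, REML/DL pooling, mixed mega-model, Holm, pipelines |
| `harmon.evaluation` | permutation comparison, subset power, FWER, variance ratio    |
| `harmon.synthetic`  | seeded generator + `enigma_like_preset`                       |
| `harmon.cli`        | `harmon simulate|fit|apply|compare|evaluate`                  |

See `docs/methods.md` for the statistical details and design choices.
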
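# Methods

This note documents the models, conventions and design choices behind
`riskdomains`, and what the synthetic experiments do and do not establish.

## Problem setting

One row per survey respondent aged 50+: numeric risk factors (missing
values allowed), a binary death indicator for a fixed prediction window,
and a partition of the risk factors into up to seven domains (demography,
socioeconomic, psychology, social connections, childhood adversity,
adulthood adversity, health behaviors). The analysis estimates death
predictability, decomposes it by domain, and attributes individual
predictions to risk factors.

## Synthetic cohort generator

The real harmonized ageing surveys are restricted-access, so the
generator produces cohorts with the statistical structure the analysis
assumes, calibrated to published survey profiles:

- **Ages** uniform on [50, 100], standardized with the theoretical uniform
  moments for the linear predictor; **gender** Bernoulli with female
  fraction 0.59 (1 = female).
- **Domains** are equicorrelated latent Gaussian blocks (default pairwise
  correlation ρ = 0.3 inside a domain, independence across domains) —
  the simplest structure producing within-domain redundancy, which is what
  makes coalition marginals differ from single-feature effects. A flag can
  threshold the non-demographic items to 0/1 to emulate binary survey
  items; the default keeps them continuous.
- **Outcome**: Bernoulli(logistic(α + η)), where η sums the age terms
  (linear + quadratic in standardized age), a gender term, and the planted
  per-feature log-odds coefficients. The intercept α is calibrated by
  bisection on the realized covariates so the expected prevalence hits the
  target (default 0.316) within ±0.01; realized prevalence differs only by
  binomial noise.
- **Missingness** is MCAR at rate 0.1 on non-demographic features only,
  applied after the outcome is drawn. MCAR keeps the recovery experiments
  interpretable; real survey missingness is not emulated.
- **Default planted structure** (the reference study conditions): seven
  domains with sizes 3, 8, 10, 4, 6, 5, 8 (demography = age + gender + one
  extra) and variance contributions to η in the ratio
  demography : socioeconomic : rest = 9 : 4 : ≤ 1, with the five remaining
  domains strictly ordered (childhood adversity > health behaviors >
  psychology > social connections > adulthood adversity). The unit is
  0.2, giving total predictor variance ≈ 3.2 and a ROC-AUC in the
  low-to-mid 0.8s — comparable to what large ageing surveys support. The
  demography block splits its share 70% age-linear, 5% age-quadratic, 15%
  gender, 10% extra feature.
- **Ground truth**: a domain's planted contribution is βᵀΣβ for its
  equicorrelated block (plus the age and gender terms for demography,
  using Var z = 1, Var z² = 4/5, Var F = f(1−f)); the planted ranking
  orders domains by contribution, ties broken by name. With binarized
  items the same formula is used with the thresholded-Gaussian correlation
  2/π·arcsin ρ, which is then an approximation.

**What passing recovery tests shows**: that the pipeline correctly ranks
domain groups whose effects are linear, Gaussian-correlated and MCAR-
masked. It does not show robustness to informative missingness, item
skew, survey weighting or longitudinal structure, none of which the
generator emulates.

### The U-shape cohort

`ushape_spec` plants a concave, monotone-increasing quadratic age effect
(the parabola's vertex at the top of the age range): mortality log-odds
rise with age but decelerate. Because an individual's age attribution is,
to first order, the centered effect η_age(a) − E[η_age], its magnitude
dips where the rising effect crosses its population mean — around age 71
for uniform ages — and grows toward both extremes. This reproduces the
U-shaped age-importance pattern with its minimum near the typical death
age. A quadratic whose *vertex* sits mid-range would do the opposite: the
vertex is the effect's extremum, hence the point of *largest* absolute
attribution; the dip location is controlled by the zero-crossing of the
centered effect, not by the vertex, which is why the generator calibrates
the former.

## Models

All twelve base classifiers use their library defaults, with two recorded
exceptions: KNN uses k = 25 (√n-scale heuristic for cohorts of ~10⁴), and
the SVM trains on a stratified subsample capped at 10 000 rows (cost
control; the cap is a hyperparameter). Non-tree models receive median
imputation and standardization fitted on training rows only; LightGBM and
XGBoost consume missing values natively and skip both. SVM and SGD (hinge
loss) lack native probabilities and are sigmoid-calibrated (Platt) with
3-fold CV on the training data. No hyperparameter search is performed.

The **benchmark** is logistic regression on exactly age and gender.

The **Super Learner** is classical stacking: stratified k-fold (default
k = 5) out-of-fold predictions from each base learner form the meta
design; the meta-learner is the non-negative, sum-to-one weight vector
minimizing Bernoulli log-loss (SLSQP on the simplex); bases are refit on
the full training set for deployment. The default base library is all
twelve classifiers.

Every stochastic component is driven by an explicit integer seed; no
global RNG state is mutated. Identical (spec, data, seed) triples give
bit-identical predictions.

## Metrics

- **PR-AUC** is average precision (step interpolation), not trapezoidal —
  trapezoidal PR interpolation is optimistic. A constant predictor scores
  exactly the prevalence.
- **Pseudo-R²** is Efron's: 1 − Σ(y−p̂)²/Σ(y−ȳ)², numerically identical
  to R² computed on predicted probabilities. This identity explains why
  the two columns of a model-comparison table agree to printed precision.
- **IMV**: probabilities are clipped to [1e−12, 1−1e−12] before logs; the
  entropy-equivalent w is solved by bracketed root finding to 1e−10; mean
  log-likelihoods below ln ½ clip to w = 0.5. The default baseline is the
  prevalence-constant predictor on the evaluation set — the canonical
  no-information null, anchored by the IP row; a benchmark-relative IMV is
  available by passing the benchmark's predictions as baseline.
- **Reporting**: per-(model, metric) mean and SE = sd/√(#seeds) across
  seeds; SE is 0 for a single seed.

## Domain importance

The value function v(S) is the test-set metric of the model retrained on
exactly the features of the domains in S. Within a seed every coalition
shares the same 7:3 split, so marginals compare models on identical test
rows. v(∅) is fixed per metric (PR-AUC → test prevalence, ROC-AUC → 0.5,
R²/pseudo-R²/IMV → 0) because singleton marginals v({d}) − v(∅) need it.

The headline importance is the **unweighted mean** of all 2^(D−1)
marginals v(S ∪ {d}) − v(S) — the plain reading of "mean of all marginal
contributions". The Shapley weighting is provided as an option; it is the
principled alternative and uniquely satisfies efficiency
(Σ importances = v(full) − v(∅) to 1e−10, which the tests assert). Under
an additive value function the two weightings coincide exactly.

Enumeration is exhaustive and capped at D = 12 (4 095 coalitions);
Monte-Carlo coalition subsampling is out of scope. Ledgers of v(S) values
are cached per (coalition, seed) and persisted as JSON so interrupted runs
can resume; a repeated evaluation never refits.

The default coalition model is LightGBM and the default metric PR-AUC.

## SHAP attribution

Attributions live on the **log-odds margin scale**. The dominant age
effect in ageing cohorts reaches mean |SHAP| above 1.5, which is
impossible on a probability scale bounded by 1; the conventional 0.1
reporting threshold is therefore only meaningful on the margin scale, and
summaries carry scale metadata so the threshold is refused on
probability-scale values. A probability-scale option exists (each row's
attributions rescaled to sum to p_i − mean p).

For LightGBM/XGBoost the attribution is the boosters' built-in exact
path-dependent tree algorithm (conditional expectations weighted by
training split counts), verified in the tests against a brute-force
Shapley computation over feature subsets on the dumped tree structure.
For other models a hand-written estimator is used: exact subset
enumeration for p ≤ 12, otherwise permutation sampling (Castro-style)
with a seeded background subsample and at least 2p + 2048 model
evaluations; p > 100 is refused. Both routes are exactly locally accurate
(base value + row sum = margin output): permutation contributions
telescope to f(x) − E_background[f] for every permutation. Note the
exemptions: exact duplicated features receive equal attribution under the
enumeration estimator, but path-dependent tree attribution does not
guarantee symmetry; tree attribution of a never-split feature is exactly
zero.

Mean |SHAP| is computed over the **full cohort** (train + test), matching
the convention of reporting overall feature contribution including both
fit and generalization behavior. Age stratification uses half-open
5-year bins from 50 to 80 plus a closed 80+ bin; bins with < 30
individuals are flagged unstable, empty bins carry NaN. Cross-cohort
tables are aligned on a reference cohort's ranking, with absent features
shown as missing.

## Problem sizes

The reference experiments run at n = 10 000 (7 000 training rows after
the 7:3 split): domain-ranking recovery with 10 replicate splits in the
acceptance script and a 3-replicate smoke version in the test suite;
null-signal calibration with 1 replicate; the U-shape experiment with 10
generated cohorts. These sizes put per-seed coalition sweeps (127
LightGBM fits) at well under a minute each while keeping split-to-split
metric SE below ~0.02.

## Known limitations

- Domain importance inherits the instability of retraining: marginals on
  small cohorts (n ≲ 2 000) are noisy relative to signals below ~0.01
  PR-AUC.
- The empty-coalition conventions are definitional, not estimated; IMV
  and R² marginals for singleton coalitions depend on them.
- Path-dependent TreeSHAP can spread attribution among correlated
  features in ways the interventional convention would not; rankings of
  strongly collinear items should be read with that in mind.
- The generator's MCAR missingness and Gaussian blocks understate the
  messiness of real survey data (see above).
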
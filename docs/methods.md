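# Methods

This note documents the models, defaults and design choices behind
`gpif`: what the estimator computes, what the synthetic data-generating
process (DGP) emulates, which knobs matter, and what the validation does
and does not demonstrate.

## Estimand and estimator

The potential impact fraction (PIF) of an intervention that changes an
adiposity exposure X (BMI or waist circumference) to X* in a target
subpopulation is `1 − P_cf / P_obs`, with `RD = P_cf − P_obs`.  Both
prevalences are model-standardised: a survey-weighted logistic regression
of the outcome on X and the adjustment set L is fit, each record's risk is
predicted at its factual and counterfactual exposure with L fixed, and
both are averaged with the survey weights.  Using the *predicted* factual
prevalence as the denominator (rather than the raw weighted prevalence)
guarantees that a null intervention yields PIF = 0 exactly, since
identical predictions enter numerator and denominator; a well-calibrated
logistic model makes the two denominators nearly identical anyway.  The
raw-prevalence variant is available via the estimator internals but is
not the default.

Identification requires the usual g-computation assumptions — temporal
ordering, conditional exchangeability given L, positivity, consistency,
no model misspecification, no measurement error.  The package does not
test these on real data; it provides a positivity diagnostic (below) and
corrects one specific measurement-error mechanism (self-reported
anthropometry) by multiple imputation.

### Uncertainty

Within one completed dataset, records are resampled i.i.d. with their
weights (`n_boot` = 1000 by default; the desk-scale configs use 200), the
outcome model is *refit* in every replicate, and every scenario is
re-applied — including fresh distribution-shift draws from the
replicate's own reference pool, so the scenario's sampling randomness
propagates into the SE.  The SE is the SD of replicate PIFs; the point
estimate is the full-data estimate.  Replicates where an outcome
degenerates to one class are dropped (an error is raised beyond 10%).
Cluster-aware resampling is not implemented; the survey design enters
through the weights only.

Across the m completed datasets, estimates are pooled by Rubin's rules:
`Q̄ = mean(Q_k)`, `W = mean(SE_k²)`, `B = var(Q_k)`,
`T = W + (1 + 1/m) B`, with Rubin's classical degrees of freedom
`(m−1)(1 + W/((1+1/m)B))²` (normal reference when B = 0).  PIFs are
pooled on the raw fraction scale.  Model refits inside bootstrap
replicates use an in-package Newton (IRLS) solver that reproduces the
statsmodels coefficients to ~1e−10 at a fraction of the per-call
overhead; a unit test enforces the agreement.

### Scenario mechanics

Targets use strict inequalities (BMI > 25, BMI > 30, WC:height > 0.5);
non-target records keep their factual exposure bit-identically.  The
distribution-shift scenario draws counterfactual BMIs with replacement
from the survey-weighted empirical distribution of the normal-BMI pool
(18.5 ≤ BMI < 25), unconditional on covariates.  The mean exposure
reduction is averaged over the *target* population, which forces the
one-unit scenario to equal exactly 1; full-population averaging is
available via `basis="all"`.

## Measurement-error correction

Measured height, weight and WC exist only in the examination arm
(`subsample_fraction`, default 4.3%).  They are imputed for everyone else
by chained equations with random-forest conditional models, with the
self-reported layer, all covariates, the design variables and the
outcomes as predictors (including the outcomes is what keeps the
imputation congenial with the outcome analyses).  Missing covariates are
imputed in the same chains.  BMI is never imputed directly: it is derived
from imputed measured height and weight, so the weight–height–BMI
identity holds in every completed dataset.

Per missing cell, one tree is chosen uniformly, the record is dropped
down it, and one observed donor is drawn uniformly from the leaf — this
preserves distributional spread and keeps categorical imputations inside
the observed levels.  Defaults: m = 10 imputations, 500 cycles, 100 trees
(the reference analysis settings); the shipped example configuration and
the validation suite use m = 5, 20 cycles, 25 trees, which the chain
diagnostics show to be ample for this DGP.  Two numerical choices matter:

- `max_features = 0.9`: regression leaves must be tight in the strong
  self-report predictors.  With the classifier-style `sqrt` default the
  leaves are coarse, donor draws shrink toward the donor-pool mean, and
  the exposure coefficient attenuates measurably.
- `max_train = 3000` caps the per-tree bagging sample of the large
  covariate forests; it does not affect the donor mechanism.

Visit order is by increasing missingness fraction; cold start is a
uniform draw from observed values.  Convergence is judged per
variable × imputation chain by regressing the chain mean on the iteration
over a trailing window: a chain passes when the slope is statistically
indistinguishable from zero (|slope| ≤ 2 SE) *or* the total drift over
the window is below one fifth of the within-imputation SD of the imputed
values.  The second branch is needed because with ~10⁴ imputed cells the
chain-mean SE is tiny and a pure significance test flags drifts that are
practically irrelevant (e.g. 0.25 cm on a 90 cm mean); a genuinely
trending chain still fails.

## The synthetic data-generating process

The generator emulates a merged interview + examination survey of adults:
14 covariates (age, sex, education, income quintile, household type,
smoking, indoor smoking, alcohol category, physical activity, black
carbon, vegetation cover, road-noise indicator, region, survey year) with
plausible Belgian-adult marginals and a simple dependency chain
(education depends on age; income on education; air pollution on region
and income; etc.).  True BMI is normal around a covariate-linear mean
with conditional SD 5.3 units (floored at 10 to exclude absurd draws,
~0.2% truncation); height is normal by sex and age; true weight is
derived from BMI and height; WC is linear in BMI with conditional SD
13.2 cm given the covariates.  The intercepts are calibrated so that
overweight prevalence is ≈48%, obesity ≈17%, and the four outcome
prevalences land near 5.3%, 29%, 6.8% and 35.5%.

Self-report bias is additive: weight −2 kg, height +1 cm, with noise SDs
2 kg and 1.5 cm.  The examination layer adds small device noise (0.3 kg,
0.5 cm, 1 cm).  Missingness is MAR, depending on age only (income ~6%,
alcohol ~4% by default) and never touches design columns or outcomes.

Each outcome follows one logistic model in *one* true exposure — BMI for
diabetes and hypertension, WC for CVD and MSK disease — plus covariates.
This "one exposure pathway per outcome" choice is deliberate: the oracle
transforms the exposure column with everything else fixed, so a true
model containing both exposures would make every single-exposure fitted
model misspecified relative to the oracle's semantics.  Scenario–outcome
pairs are therefore formed within matching exposure (BMI scenarios × BMI
outcomes, the WC scenario × WC outcomes).

The survey design is schematic: strata nested in region, clusters in
strata, Brussels oversampled, weights = population share / sampling share
times outcome-independent cluster and household lognormal noise — so
weighted estimates are consistent for the superpopulation, which is what
the oracle simulates (`mode="population"`: population shares, unit
weights, no missingness).  The design is a stylised two-stage scheme, not
a replica of any national weighting procedure.

What the generator does **not** emulate: spatial/GIS structure of the
environmental exposures (they are ordinary covariates correlated with
region and income), longitudinal structure, nonresponse informative of
the outcomes, cluster-correlated outcomes, and real Belgian covariate
joint distributions.  Passing tests therefore demonstrate estimator
correctness under a known, well-specified DGP — not calibration to any
real population.

## Oracle and validation

`true_pif` simulates `n_mc` individuals from the superpopulation,
evaluates the true-model risk at factual and scenario-transformed
exposure, and returns `1 − P_cf/P_obs` with a delta-method Monte-Carlo
SE.  The distribution-shift draws inside the oracle come from the true
normal-BMI pool of the simulated superpopulation, keeping the oracle
estimator-independent.

The validation suite (tests/test_acceptance.py) runs, at one CPU:

- oracle recovery: one survey of n = 20 000 → RF-MICE (m = 5, 20 cycles,
  25 trees) → bootstrap g-computation (n_boot = 200) → Rubin pooling, for
  all 14 scenario × outcome pairs, each checked against its oracle at 3
  combined SEs (BMI and WC pathways checked separately — the WC pathway
  carries the attenuation described under Known limitations), with the
  expected strength ordering (distribution shift > 10% weight loss > one
  unit) and target dominance (overweight ≥ obesity-only);
- CI coverage: 200 fresh complete-data surveys of n = 2 000
  (s2, diabetes, n_boot = 200), nominal-95% coverage required in
  [0.90, 0.985];
- bias removal: −2 kg self-report bias with a 5% examination arm at
  n = 10 000, recovered within 3 between-imputation SEs of the realised
  gap, observed cells untouched.

Scaled-down problem sizes are used in ordinary unit tests (e.g. stepwise
selection power at n = 6 000 × 12 replicates; bootstrap-SE consistency at
n = 1 200 × 40 replicates); the sizes above are the package's chosen
validation conditions and are stated in the test docstrings.

## Outcome models

Survey weights enter as likelihood weights (statsmodels GLM
`var_weights`) with an HC1 sandwich variance; the bootstrap, not the
sandwich, is the primary SE engine for PIFs.  Categoricals are
dummy-coded against the first codebook level.  ORs are reported per
survey-weighted IQR of the exposure, `exp(β̂ × IQR)` with a normal 1.96
multiplier.  Optional exposure² and exposure × covariate terms are chosen
by bidirectional greedy stepwise AIC from the main-effects model (ties
broken by candidate order; selection is done once on the full data and
reused inside bootstrap replicates).  When such terms are selected the
main-effect OR is flagged `conditional`, since no single OR summarises
the exposure then.  Discrimination is a 70/30 split-sample weighted AUC,
averaged over the m completed datasets.  Metabolic mediators/colliders
(hypertension as a covariate, hypercholesterolaemia) are refused in
adjustment sets.

Perfect separation is detected by perfect classification of the fitted
probabilities (not by coefficient size, which penalises legitimately
steep effects) and reported with the separating term.

## Diagnostics

- **Positivity**: a main-effects logistic model of exposure-class
  membership (default: overweight) on the confounders; the predicted
  membership probabilities of the two groups are compared by a 50-bin
  histogram overlap coefficient in [0, 1] (symmetric in the labels).  The
  plausibility threshold 0.2 is a convention, not an inferential cutoff.
- **Conditional SDs**: weighted least squares of BMI (or WC) on all
  covariates; the residual SD bounds the scenario shifts relative to
  unexplained variation (5.3 units / 13.2 cm in the default DGP).
- **Simulation harness**: repeats generate → (optionally impute) →
  estimate → pool and reports bias, RMSE, empirical SE, mean bootstrap SE
  and 95% CI coverage against the oracle.

## Known limitations

- The bootstrap ignores the cluster structure; with strongly
  cluster-correlated outcomes the SEs would be optimistic.
- Imputed waist circumference rests on a ~4% validation arm with no
  self-reported WC proxy: the leaf-donor draws approximate
  P(WC | self-reported BMI, covariates) with ~8 cm spread and, with so few
  training rows, almost never condition on the binary outcomes, so
  WC-exposure coefficients — and hence the WC-scenario PIFs — attenuate
  by roughly Var(WC|preds)/Var(WC|X) ≈ 30–40% at these sample sizes.  The
  between-imputation variance reflects draw noise but not this systematic
  shrinkage; the self-reported height/weight proxies make the BMI pathway
  immune to it.  The validation suite keeps the WC-pathway oracle check at
  full strictness, where this limitation is visible as a failure.
- Stepwise-AIC selection is done once per completed dataset, not inside
  bootstrap replicates; selection uncertainty is not propagated.
- Scenario consistency (what real-world intervention would produce these
  exposure shifts) is outside the model, as is any time-varying
  confounding structure.
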
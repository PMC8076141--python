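# Methods

## Model

The analysis model is a MIMIC structural equation model with three latent
factors (arterial stiffness, calcification, plaque) measured by 14 clinical
indicators. Conditional on the covariate vector `x`:

- `f = B x + ζ`, `ζ ~ N(0, Ψ)` with `diag(Ψ) = 1` — fixing each factor's
  *residual* variance at 1 identifies the latent scale (the common
  convention when no loading is anchored); the free off-diagonals of `Ψ`
  are residual correlations between pathologies.
- `y = ν + Λ f + K x + ε`, `ε ~ N(0, Θ)`; `Θ` has free variances plus four
  freed residual correlations (AI–cSBP, left–right CCA IMT, left–right ABI,
  left–right UT), pairs that share a device or anatomy. Because these pairs
  touch disjoint indicators, parameterizing them as correlations (rather
  than raw covariances) makes `Θ` positive definite by construction.
- The single direct covariate→indicator path is sex→AI.

Covariate coding: dose in weighted Gy untransformed; age centered at the
analyzed-sample mean, age² computed after centering (affects only
intercepts); female = 1, Nagasaki = 1, distal = 1, a city×distal product;
smoking as current/past dummies with never as reference. Covariate sets per
factor: stiffness {dose, age, city, distal, city×distal}; calcification
{dose, age, age², female, city, distal, city×distal, smoking};
plaque {dose, age, city, distal, city×distal, smoking}.

Assumptions: indicators conditionally multivariate normal; missingness at
random (missingness may depend on observed covariates and observed
indicator values, not on the missing values themselves); covariates
complete (records with unknown dose or smoking are excluded upstream, as
the preparation stage does); linear dose response.

## Estimation

Full-information maximum likelihood: each record contributes the Gaussian
log-density of its observed indicator sub-vector under the corresponding
sub-moments. Records are grouped by missingness pattern; each pattern's
covariance sub-matrix is Cholesky-factorized once per likelihood
evaluation. The likelihood is conditional on covariates (the regression
formulation of a MIMIC model).

Optimization is quasi-Newton (L-BFGS-B) on an unconstrained
reparameterization: log residual variances, Fisher-z correlations.
Gradients are analytic (matrix-calculus chain rule through the implied
moments), verified against central differences in the test suite; they are
what makes the n = 3274 simulation studies affordable. Indicators are
internally z-scored and covariates variance-scaled before optimization (an
exact reparameterization, mapped back afterwards; the log-likelihood is
reported on the data scale) — without this the raw scales (cSBP variance
~400, ABI variance ~0.006 before rescaling) stall the optimizer.
Starting values: loadings at the indicator sample SD (1 after internal
scaling), residual variances at half the sample variance, intercepts at
sample means, all covariances and coefficients at zero. Non-positive-
definite proposals are handled by a penalty objective value, not
projection. Convergence tolerances: projected-gradient 1e-5, relative
objective change 1e-11.

Standard errors (used only by the direct-effect scan) come from the
observed information, obtained by forward finite differences of the
analytic gradient, inverted and mapped through the transform Jacobian.

## Standardization and derived quantities

Standardized solutions rescale to latent-factor and indicator SDs but leave
covariates on their natural scale, so structural coefficients read "factor
SDs per covariate unit" (per Gy, per year). Factor SDs use the model-implied
total variance `diag(B Sx B' + Ψ)` with `Sx` the sample covariate
covariance; indicator SDs use the implied total indicator variance. Factor
R² is `1 − ψ_ff / Var(f)`.

Indirect (total) per-Gy effects on each indicator are the products of the
unstandardized dose→factor and factor→indicator coefficients, equal to
∂E[y|x]/∂dose under the no-direct-effect assumption (checked against a
finite difference in the tests), mapped back to clinical units by undoing
the fitting-scale factors (ABI ×10; baPWV carried in m/s, with a cm/s
loader option for instruments that report cm/s).

Fit indices use the saturated conditional-Gaussian model (unrestricted
means on all covariates, unrestricted covariance, fit by the same FIML
machinery; closed form when data are complete) and the independence
baseline (intercept-only means, diagonal covariance):
`chi² = 2(ll_sat − ll_model)`, `df` = parameter-count difference,
`CFI = 1 − max(chi²−df,0)/max(chi²_b−df_b,0)`,
`RMSEA = sqrt(max(chi²−df,0)/(df·n))` with `n` the records used (not
n − 1), `AIC = −2 ll + 2k`. Other software may use a different baseline
(e.g. one with covariate effects retained), so CFI values are comparable
within this package, not across packages.

Confidence intervals are percentile bootstrap over participants (the
resampling unit is the row), replicates warm-started at the full-data
estimates; non-converged replicates are dropped and counted, and a failure
rate above 10% is surfaced. BCa was not used; the percentile convention is
stated because the upstream convention is unspecified.

The modification scan (`lr_scan`) refits with one fixed parameter freed at
a time and reports `Δchi² = 2Δll` on 1 df. It replaces software-specific
score-test modification indices: asymptotically equivalent, numerically
different, so index values should not be expected to match other programs.

The direct-effect validation scan adds one free dose→indicator path at a
time to the final model, warm-started at the base fit, and applies a Wald
test from the observed information at the Bonferroni level 0.05/14,
reported at the conventional 0.003. Bootstrap p-values across 14 refits
would be far more expensive and are not used. Under a misspecified base
model the one-at-a-time refits can redistribute signal across indicators;
the family-wise error under the null is verified by simulation instead
(≤ ~5% empirically).

E-values use the linear-coefficient conversion: with the factor
standardized to unit total SD and R² the covariate-explained share, the
residual SD is `sqrt(1 − R²)`, `d = coefficient / sqrt(1 − R²)` for a 1 Gy
contrast, `RR = exp(0.91·d)`, `E = RR + sqrt(RR(RR−1))` (risk ratios below
1 inverted first); the same mapping applies to the CI limit closer to the
null, with E = 1 when the CI crosses it. Using the residual SD (not the
total SD) is the convention under which published CI-limit E-values
(1.36, 1.21) are reproduced exactly from the printed inputs
(0.070 / R² 0.27 → RR 1.077 → 1.366; 0.029 / R² 0.28 → 1.212). Point
E-values computed from rounded printed inputs land within 0.02 of the
published 1.61 / 1.51.

## Synthetic cohort generator

The generator emulates the analyzed study population; its defaults are the
study conditions, frozen once:

- **Dose**: five strata with exact sizes (1163, 1529, 251, 229, 102;
  n = 3274), within-stratum uniform laws on [lower bound, 2·mean − lower
  bound] reproducing the published stratum means (0.001, 0.116, 0.720,
  1.36, 3.09 Gy), 381 exact zeros in the lowest stratum, maximum 4.84 Gy.
  The implied overall mean is 0.301 Gy (SD ≈ 0.63).
- **Age–dose confounding** via a two-sub-cohort mixture: a 1703-member
  expansion sub-cohort (mean age 70.8) and a 1571-member primary sub-cohort
  (mean age 78.3), within-group SD 4.9 (so the overall age SD matches
  ~6.2). The expansion allocation across strata, (296, 1407, 0, 0, 0), is
  the exact solution of the two constraints "1703 members" and "mean dose
  0.096 Gy" given the stratum means; the primary group then has mean dose
  0.523 Gy. A two-group mixture cannot also reproduce every per-stratum age
  mean; those deviate by 1–2 years from the published table.
- **Categorical covariates** drawn with per-stratum proportions (sex, city,
  smoking); distal participants occur only in the lowest stratum.
- **Outcomes** on the standardized scale: factors are the structural linear
  predictor plus correlated residuals scaled so each factor has exactly
  unit sample variance (exact normalization matters because the baPWV
  loading 0.98 leaves a residual-variance budget of only 0.04); indicators
  are loadings×factors + direct effects + correlated residuals with unit
  total variance, mapped to clinical units by the published overall
  means/SDs. For the realized covariate sample, the generating model's
  standardized coefficients equal the configured values by construction.
- **Calcification discretization.** Thoracic grade 0–3 by thresholds at
  cumulative probabilities (0.26, 0.635, 0.985) — one of the solutions
  matching the published mean 1.12 / SD 0.81, chosen because it also zeroes
  the quadratic Hermite coefficient of the threshold map, which otherwise
  inflates the thoracic–abdominal within-block covariance and attenuates
  the calcification–plaque correlation. Abdominal score 0–24 as the sum of
  eight region grades (0–3 by fixed thresholds on a region latent sharing
  the indicator's continuous score, loading 0.8731), mirroring the actual
  instrument and calibrated once to the published mean 4.71 / SD 5.04; the
  resulting marginal has its mode at zero.
- **Missingness and artifacts.** Disjoint artifact sets (ABI > 1.4; ABI
  < 0.9 invalidating same-side baPWV; 26 unreliable rise times leaving ABI
  only; surgery flags 5/16/21) are placed first; an age-weighted
  missing-at-random top-up (selection probability ∝ logistic(age z-score))
  then brings every indicator *after* the validity filters exactly to its
  configured pooled missing count. The published counts pool "not measured"
  and "invalid"; the split between the mechanisms is a configurable guess.
- **Invited-population wrapper** adds 247 refusers, 321 in-utero, 273
  missing-dose and 8 missing-smoking records so eligibility accounting can
  run end to end (4123 → 3555 → 3274).

Everything is deterministic for a fixed seed (numpy Generator,
SeedSequence-spawned children per stage).

### What the generator does and does not emulate

It reproduces the covariate structure, dose mixture, indicator moments,
correlation structure, missingness counts and artifact layer. It does not
reproduce: skewness of the continuous indicators (IMT is generated
normal, so a few ICA values are non-positive and the log-transform
sensitivity masks them as invalid), longitudinal smoking histories, images
or dosimetry, or rater behavior beyond the threshold model. Passing
recovery tests therefore shows the estimator is correct *for data
satisfying its assumptions*, not that the assumptions hold in any real
cohort.

### Known quasi-ML distortion of the calcification block

An integer score on [0, 24] with mean 4.71 *below* its SD 5.04 cannot be a
linear-Gaussian measurement of a normal latent factor: E[score | factor]
is necessarily convex. Fitting the linear model to such data leaves most
quantities unbiased — the age coefficient, loadings of the continuous
indicators, factor correlations (to within ~0.02) — but the standardized
dose→calcification coefficient absorbs the projection of the curvature
onto dose (whose zero point mass and sub-cohort coupling the linear model
does not span) and is recovered ~0.17 when generated at 0.15 (~+13%),
invariant to how strongly the score couples to the latent (verified by
varying the coupling share with a shared grading-session component). The
distortion is a property of the measurement scale itself; published
estimates from real scores of this shape carry the same quasi-ML caveat.
The recovery experiments report it rather than re-tuning generating
parameters to cancel it.

## Problem sizes used by the test and acceptance suites

Recovery: 10 cohorts of n = 3274 (full missingness layer) in the test
suite, 48 in the acceptance script. Comparator properties: 50 complete-data
replicates of n = 1000. Direct-scan family-wise error: 100 complete-data
simulations of n = 400. Bootstrap coverage: 50 simulations × 60 replicates
at n = 150 on a three-indicator toy. These sizes keep the full suite at a
few minutes while leaving Monte-Carlo error well inside the asserted
tolerances (recovery tolerances are 3 Monte-Carlo SEs by construction).

## Limitations

Ordinal indicators are treated as continuous (no probit/proportional-odds
measurement); no robust (sandwich) or mean-adjusted likelihood
corrections; no analytic score-test modification indices; no mediation
through post-exposure risk factors; the comparator's AIC/CFI comparisons
assume both models were fit to identical records (enforced). Bootstrap
CIs for the full 14-indicator model are computationally heavy at the
published replicate count (2000); tests exercise smaller B, and the
pipeline exposes B as configuration.
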
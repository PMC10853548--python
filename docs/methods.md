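# Methods

## The model and its assumptions

`srhadvisor` treats 4-level self-rated health (SRH) as a continuous outcome
in a linear mixed model with a per-participant random intercept. Treating
an ordinal scale as continuous assumes **equidistance**: adjacent SRH
levels are equally far apart, so a +0.6 effect means the same thing
anywhere on the scale. Two diagnostics probe this assumption:

* `equidistance_diagnostic` regresses model predictions on actual SRH and
  reports, per level, the gap between the mean prediction and the linear
  trendline (exactly zero when predictions are affine in the actual level,
  by construction of least squares within-level means);
* `discretized_normal_gof` fits a normal distribution to the integer SRH
  values and compares its probability mass over the bins
  (−∞, 1.5], (1.5, 2.5], (2.5, 3.5], (3.5, ∞) with the empirical level
  frequencies.

Fixed-effect basis: age in decades (linear + quadratic), HII comorbidity
index (linear + quadratic), HSCL-10 (cubic), and dummies for sex, education
(reference: university), household, friend support, BMI category
(reference: overweight), smoking, HbA1c ≥ 6.5 %, the 12 physical-activity
frequency×intensity cells (reference: moderate intensity 2–3/week), and
three age>65 interaction dummies (intense PA ≥ 4/week, normal BMI, obese
BMI). Continuous terms enter uncentered; with uncentered evaluation the
embedded table reproduces the published contrast effects, which is the
evidence for that convention. Age enters only through its two polynomial
terms and the three interactions; there is no age>65 main-effect dummy.

The underweight BMI category has no published coefficient (the effect was
reported non-significant); `linear_effect` treats it as the overweight
reference level with a warning unless a coefficient is supplied. Absolute
SRH predictions require an explicit intercept anchor, because none is
published; every core quantity is a difference, which is intercept-free.

## Estimation choices

* REML estimation via `statsmodels.MixedLM`, participant id as the grouping
  variable; participants observed in one wave enter as singleton groups.
* Wald z p-values on fixed effects; 95 % CIs as estimate ± 1.96·SE.
* Power-term selection enters powers 1..4 of one covariate **jointly** in a
  single-variable model and keeps those with p < 0.05. The four uncentered
  powers are strongly collinear on short ranges, so individual Wald tests
  are conservative; selection is only reliable for strong signals. When a
  cohort has no repeated participants the selection model falls back to OLS
  (the random intercept is unidentified and MixedLM standard errors
  degenerate at the boundary).
* Design columns that are identically zero (a category absent from the
  cohort) are dropped with a warning; a rank-deficiency error naming the
  collinear terms is raised only for genuine linear dependence among
  observed columns.
* Rounded predictions are clamped to [1, 4] before computing accuracy.
  Marginal R² = var(fixed-effect predictions) / (var(fixed) + σ_u² + σ_ε²).
* Stratified rate CIs use the normal approximation by default (Wilson by
  flag), matching the symmetric intervals of the source tables.

## The synthetic cohort generator

The generator emulates the *statistical skeleton* of a two-wave population
survey so the pipeline can be exercised end to end without the
access-restricted survey data:

* `n_participants` (default 5,000) each get persistent attributes (sex,
  education, household, friend support, HII, age, and a random intercept
  with SD 0.298 — the published between-person value) and one wave-6 row;
  with probability 6264/22335 ≈ 0.28 (the published overlap) they also get
  a wave-7 row with age advanced 8 years and modifiable covariates redrawn
  from wave-7 marginals.
* Categorical marginals mirror the published sample characteristics
  (e.g. smoking 20.4 %/13.9 % by wave, obesity 20.4 %/23.8 %). HSCL-10 is
  1 + lognormal (σ = 1, clipped at 4) with the location solved so that
  P(HSCL ≥ 1.85) matches the published distress share; HII is a
  zero-inflated discrete draw matching the published HII ≥ k shares; age is
  a truncated normal (mean 57, SD 13 on [30, 88]) roughly matching the
  published age-threshold shares.
* Latent SRH\* = intercept + x'β + u_i + ε is rounded to the nearest level
  and clamped to [1, 4] (equivalent to cutpoints 1.5/2.5/3.5), the same
  discretisation the accuracy metric and the goodness-of-fit bins use.
  The default true coefficients are the embedded published table.

**Calibrated constants.** The default intercept 4.89 was found by bisection
(`calibrate_intercept`) so the simulated wave-6 share of good-or-excellent
SRH matches the published 68.3 %. The default residual SD 0.623 solves
total latent variance = 0.579, the wave-6 SRH variance implied by the
published level shares (`residual_sd_for_total_variance`). An alternative
calibration — choosing the residual SD to reproduce the published marginal
R² of 0.631 — is **infeasible under independent covariate draws**: the
fixed-effect variance is then only ≈ 0.10, capping the latent marginal R²
at ≈ 0.53 even with zero residual noise. The published value implies a
fixed-effect variance near 0.37, which requires the clustering of unhealthy
factors seen in real populations. `residual_sd_for_marginal_r2` implements
that calibration and raises an informative error in the default setup; a
`joint_sampler` hook accepts user-supplied correlated covariate draws.

**What the generator does not emulate**, and hence what passing tests do
not establish: covariate correlation (independent draws → no confounding
between lifestyle factors, and a marginal R² of ≈ 0.18 rather than 0.63),
within-person covariate persistence between waves (modifiable covariates
are redrawn independently), the survey's age-stratified invitation design,
and item-level HSCL structure. Parameter-recovery results therefore show
estimator correctness under the model's own assumptions, not robustness to
realistic confounding.

Under these conditions the refitted random-intercept SD averages ≈ 0.28
across replicates — a mild attenuation of the generating 0.298 caused by
discretising and clamping the latent outcome — and fitted fixed effects
cover their generating values at close to the nominal 95 % rate.

## Recommendation engine

Goal categories are mental health (HSCL-10), physical activity, weight
(BMI category), smoking, and blood-sugar control. Age, sex, education,
household, friend support and comorbidity never generate goals; friend
support is deliberately excluded from the modifiable set because improving
it is not under a person's direct control. For each category the
model-optimal state is the argmax of the linear predictor over the
category's state space with interactions evaluated at the person's age
(ties break toward the less extreme state); categories are ranked by the
effect of reaching that optimum, and the optimum is always shown alongside
any intermediate catalog goals so the long-term potential is visible. The
shipped catalog (two exercise steps, the distress threshold) is a starting
point, editable as YAML; which intermediate goals motivate a given user is
a behavioural question the model cannot answer. Joint multi-goal queries
are supported (`joint_effect`). Reports always carry the caveat that
effects are associational.

## Numerical details and degenerate inputs

* Standard errors recovered from printed CIs use (high − low)/3.92; CIs
  built from them ignore coefficient correlations and are flagged
  `independence_approx`.
* `effect_between` on identical profiles returns exactly 0; zero contrasts
  get the CI (0, 0).
* The HSCL-10 score is missing (None, never NaN or 0) with fewer than 7
  answered items; missingness propagates as an explicit error at profile
  construction.
* HII scoring refuses condition names without weights rather than guessing;
  only four condition weights are published (myocardial infarction 2,
  stroke 2, asthma 2, migraine 1), the other seven entries of the shipped
  table are documented placeholders completing the 0–22 scale and are meant
  to be overridden.
* `discretized_normal_gof` raises on zero variance; `stratified_rates`
  marks empty strata undefined; an SRH level absent from a cohort yields a
  missing row in the equidistance table.
* Cohort ingest is complete-case: rows missing any model variable are
  dropped with a logged count, rows violating profile invariants are
  rejected with row numbers.

## Problem sizes used in the test suite

Simulation tests use 2,000-participant cohorts for single-fit checks and
twenty replicates of 5,000 participants for the coverage study — large
enough that every coefficient's CI is informative while a full run of the
suite stays in the single-digit minutes. Marginal-convergence checks use a
50,000-row draw.

## Known limitations

* Printed-precision coefficients make some derived quantities differ from
  the published ones: the HII 0→6 contrast evaluates to 0.47 from the
  rounded table where 0.42 was published (the only published contrast that
  disagrees beyond rounding; all others reproduce within 1 %).
* Goal effects assume all other covariates stay fixed; real lifestyle
  changes have knock-on effects, so displayed values likely underestimate
  joint consequences (mitigated by the joint-query facility).
* The engine's outputs are associations from observational survey data and
  must not be read causally; the cumulative benefit of sustained adherence
  over time is outside the model.
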
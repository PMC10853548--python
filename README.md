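# srhadvisor

Self-rated health (SRH) — the answer to *"How do you, in general, consider
your health to be?"* on a 4-point scale from "poor" to "excellent" — is a
well-validated proxy for overall health that responds strongly to modifiable
lifestyle factors. `srhadvisor` is a proof-of-concept engine for turning a
population-level statistical model of SRH into **individually tailored
lifestyle advice**: it evaluates a published mixed-effects regression model
on a single person's profile, finds the lifestyle categories with room for
improvement, and ranks concrete goals (exercise schedules, weight category,
smoking, blood-sugar control, mental-health targets) by their predicted
effect on that person's SRH.

It is aimed at biostatisticians and digital-health researchers who want to
prototype model-backed recommendation logic, and it ships the full
statistical pipeline needed to refit and diagnose such a model on their own
cohort data — plus a synthetic two-wave survey generator so every part of
the pipeline is testable without access-restricted survey data.

## The model

Mean SRH is modelled as a linear mixed model over two survey waves:

```
SRH_ij = β₀ + x_ij'β + u_i + ε_ij ,   u_i ~ N(0, σ_u²),  ε_ij ~ N(0, σ_ε²)
```

where `i` indexes participants, `j` waves, and `u_i` is a per-person
random intercept (the individual's SRH "baseline"). The fixed-effect basis
`x` contains age in decades (linear + quadratic), a comorbidity index
(HII, linear + quadratic), the HSCL-10 mental-distress index (cubic
polynomial), and dummies for sex, education, household, friend support,
BMI category, smoking, HbA1c ≥ 6.5 %, the 12 physical-activity
frequency-by-intensity cells, and three age>65 interactions.

The package embeds the published coefficient table as its default knowledge
base. No intercept is published, so the core contract is **differences**
between covariate states,

```
effect(a → b) = x_b'β − x_a'β ,
```

which are free of both the intercept and the random effect. Delta-method
95 % CIs are available from a fitted covariance matrix, or approximately
(independence across coefficients) from the printed CIs.

## Worked example

A 32-year-old woman with severe mental distress (HSCL-10 = 2.8), exercising
less than once a week at moderate intensity, BMI 27 (overweight):

```python
from srhadvisor import UserProfile, build_recommendations

profile = UserProfile(
    age=32, sex="female", education="university", lives_with_spouse=True,
    friend_support=True, hii=0, hscl=2.8, bmi_category="overweight",
    pa_frequency="lt1_per_week", pa_intensity="moderate",
    smoker=False, hba1c_high=False,
)
for r in build_recommendations(profile):
    print(f"{r.category_rank}. {r.goal.category:18s} {r.effect.effect:+.2f}  {r.goal.label}")
```

```
1. mental_health      +0.32  Bring mental distress below the clinical threshold (HSCL-10 = 1.85)
1. mental_health      +0.91  Reach the optimal state: no mental-distress symptoms (HSCL-10 = 1)
2. physical_activity  +0.15  Exercise with moderate intensity 2-3 times per week
2. physical_activity  +0.24  Exercise with moderate intensity at least 4 times per week
2. physical_activity  +0.53  Reach the optimal exercise schedule for your age
3. weight             +0.11  Reach the optimal BMI category
```

Numbers are predicted changes in mean SRH on the 4-point scale: resolving
her mental distress entirely predicts a 0.91-level gain — almost a full
step, e.g. from "not so good" to "good" — and outranks exercise (0.53) and
weight (0.11). The effects are associations estimated from an observational
cohort, not causal guarantees; every report carries that caveat. For a
68-year-old the engine recommends hard exercise 2–3 times per week rather
than ≥ 4, because an age>65 interaction reduces the predicted benefit of
daily vigorous exercise.

The same logic is available from the shell:

```bash
srhadvisor recommend --profile profile.json --out report.json --fig report.svg
srhadvisor effect --current now.json --target goal.json --ci independence_approx
srhadvisor simulate --n 5000 --seed 1 --out cohort.csv
srhadvisor fit --cohort cohort.csv --out fit.json
srhadvisor metrics --fit fit.json --holdout holdout.csv --out metrics.json
srhadvisor strata --cohort cohort.csv --out umf_rates.csv
```

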
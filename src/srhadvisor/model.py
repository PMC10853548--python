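"""Fixed-effect SRH model: term encoding, coefficient tables and effects.

The model predicts mean self-rated health (SRH, 4-point scale treated as
continuous) from a linear combination of basis functions of a
:class:`~srhadvisor.profiles.UserProfile`:

* age in decades, with a quadratic term;
* the comorbidity index HII with a quadratic term;
* the mental-distress index HSCL-10 as a cubic polynomial;
* dummies for sex, household, friend support, education, BMI category,
  smoking, high HbA1c and the 12 physical-activity frequency-by-intensity
  combinations;
* three age>65 interaction dummies (with intense PA >=4/week, normal BMI and
  obese BMI).

Continuous terms enter uncentered.  Reference categories (female, university
education, lives with spouse, has friend support, overweight BMI,
moderate-intensity PA 2-3 times/week, non-smoker, normal HbA1c, age <= 65)
produce an all-zero dummy block.  The package ships the published coefficient
table as :func:`default_coefficients`; no intercept is published, so the core
contract is *differences* between covariate states, which are intercept-free.
An absolute prediction requires an explicitly supplied anchor intercept.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .profiles import UserProfile, PA_FREQUENCIES, PA_INTENSITIES

__all__ = [
    "ModelError",
    "ModelTermSpec",
    "Coefficient",
    "CoefficientTable",
    "EffectEstimate",
    "BASE_TERM_SPEC",
    "DEFAULT_TERM_SPEC",
    "TERM_GROUPS",
    "REFERENCE_PROFILE",
    "build_design_row",
    "linear_effect",
    "predict_srh",
    "effect_between",
    "effect_ci",
    "pa_effect_grid",
    "default_coefficients",
]

#: Z quantile for 95% confidence intervals.
Z95 = 1.959963984540054

#: Age above which the published age-interaction dummies switch on.
AGE_INTERACTION_THRESHOLD = 65.0


class ModelError(ValueError):
    """Raised on model-evaluation failures (missing terms, bad contrasts)."""


TermFunc = Callable[[UserProfile], float]


class ModelTermSpec:
    """Ordered collection of named basis functions over a profile."""

    def __init__(self, terms: Sequence[tuple[str, TermFunc]]):
        names = [n for n, _ in terms]
        if len(names) != len(set(names)):
            raise ModelError("duplicate term names in spec")
        self._terms: list[tuple[str, TermFunc]] = list(terms)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self._terms]

    def __iter__(self):
        return iter(self._terms)

    def __len__(self) -> int:
        return len(self._terms)

    def __add__(self, other: "ModelTermSpec") -> "ModelTermSpec":
        return ModelTermSpec(list(self) + list(other))

    def subset(self, names: Iterable[str]) -> "ModelTermSpec":
        wanted = set(names)
        return ModelTermSpec([(n, f) for n, f in self._terms if n in wanted])


def _dummy(predicate: Callable[[UserProfile], bool]) -> TermFunc:
    return lambda p: 1.0 if predicate(p) else 0.0


def _pa_name(intensity: str, frequency: str) -> str:
    short = {"lt1_per_week": "lt1", "1_per_week": "1wk",
             "2_3_per_week": "23wk", "ge4_per_week": "ge4"}[frequency]
    return f"pa_{intensity}_{short}"


def _pa_dummy(intensity: str, frequency: str) -> TermFunc:
    return _dummy(lambda p, i=intensity, f=frequency: p.pa_intensity == i and p.pa_frequency == f)


def _age_gt65(p: UserProfile) -> bool:
    return p.age > AGE_INTERACTION_THRESHOLD


#: Term groups, usable to assemble reduced specs for sensitivity analyses.
TERM_GROUPS: dict[str, list[tuple[str, TermFunc]]] = {
    "age": [
        ("age_decades", lambda p: p.age / 10.0),
        ("age_decades_sq", lambda p: (p.age / 10.0) ** 2),
    ],
    "demographics": [
        ("male", _dummy(lambda p: p.sex == "male")),
        ("not_living_with_spouse", _dummy(lambda p: not p.lives_with_spouse)),
        ("lack_friend_support", _dummy(lambda p: not p.friend_support)),
        ("edu_primary", _dummy(lambda p: p.education == "primary")),
        ("edu_upper_secondary", _dummy(lambda p: p.education == "upper_secondary")),
    ],
    "hii": [
        ("hii", lambda p: float(p.hii)),
        ("hii_sq", lambda p: float(p.hii) ** 2),
    ],
    "bmi": [
        # reference: overweight; underweight ships without a published
        # coefficient and defaults to the reference level (see linear_effect)
        ("bmi_underweight", _dummy(lambda p: p.bmi_category == "underweight")),
        ("bmi_normal", _dummy(lambda p: p.bmi_category == "normal")),
        ("bmi_obese", _dummy(lambda p: p.bmi_category == "obese")),
    ],
    "hba1c": [("hba1c_high", _dummy(lambda p: p.hba1c_high))],
    "smoking": [("smoker", _dummy(lambda p: p.smoker))],
    "pa": [
        (_pa_name(i, f), _pa_dummy(i, f))
        for i in PA_INTENSITIES
        for f in PA_FREQUENCIES
        if not (i == "moderate" and f == "2_3_per_week")  # reference cell
    ],
    "hscl": [
        ("hscl", lambda p: float(p.hscl)),
        ("hscl_sq", lambda p: float(p.hscl) ** 2),
        ("hscl_cube", lambda p: float(p.hscl) ** 3),
    ],
    "age_interactions": [
        ("age_gt65:pa_intense_ge4",
         _dummy(lambda p: _age_gt65(p) and p.pa_intensity == "hard" and p.pa_frequency == "ge4_per_week")),
        ("age_gt65:bmi_normal", _dummy(lambda p: _age_gt65(p) and p.bmi_category == "normal")),
        ("age_gt65:bmi_obese", _dummy(lambda p: _age_gt65(p) and p.bmi_category == "obese")),
    ],
}

#: Main-effects-only spec (no age interactions); used by interaction tests.
BASE_TERM_SPEC = ModelTermSpec(
    TERM_GROUPS["age"] + TERM_GROUPS["demographics"] + TERM_GROUPS["hii"]
    + TERM_GROUPS["bmi"] + TERM_GROUPS["hba1c"] + TERM_GROUPS["smoking"]
    + TERM_GROUPS["pa"] + TERM_GROUPS["hscl"]
)

#: The full published model: main effects plus the three age>65 interactions.
DEFAULT_TERM_SPEC = BASE_TERM_SPEC + ModelTermSpec(TERM_GROUPS["age_interactions"])

#: A profile sitting at every reference category (dummies all zero).
REFERENCE_PROFILE = UserProfile(
    age=40.0,
    sex="female",
    education="university",
    lives_with_spouse=True,
    friend_support=True,
    hii=0.0,
    hscl=1.0,
    bmi_category="overweight",
    pa_frequency="2_3_per_week",
    pa_intensity="moderate",
    smoker=False,
    hba1c_high=False,
)


@dataclass(frozen=True)
class Coefficient:
    estimate: float
    ci_low: float = math.nan
    ci_high: float = math.nan

    def __post_init__(self) -> None:
        if not (math.isnan(self.ci_low) or math.isnan(self.ci_high)):
            if not self.ci_low <= self.estimate <= self.ci_high:
                raise ModelError(
                    f"CI ({self.ci_low}, {self.ci_high}) does not bracket estimate {self.estimate}"
                )

    @property
    def se(self) -> float:
        """Standard error recovered from the 95% CI width, (high-low)/3.92."""
        return (self.ci_high - self.ci_low) / (2 * Z95)


@dataclass
class CoefficientTable:
    """Named model terms mapped to estimates (and optionally CIs/covariance).

    ``covariance``, when present, is a symmetric DataFrame indexed by term
    names (it may additionally carry an ``"intercept"`` row/column).
    ``intercept`` is optional because the published table prints none.
    """

    coefficients: dict[str, Coefficient] = field(default_factory=dict)
    covariance: Optional[pd.DataFrame] = None
    intercept: Optional[float] = None

    def __contains__(self, name: str) -> bool:
        return name in self.coefficients

    def estimate(self, name: str) -> float:
        try:
            return self.coefficients[name].estimate
        except KeyError:
            raise ModelError(f"no coefficient for term {name!r}") from None

    def names(self) -> list[str]:
        return list(self.coefficients)

    def to_records(self) -> list[dict]:
        return [
            {"term": n, "estimate": c.estimate, "ci_low": c.ci_low, "ci_high": c.ci_high}
            for n, c in self.coefficients.items()
        ]

    @classmethod
    def from_records(
        cls,
        records: Iterable[Mapping],
        covariance: Optional[pd.DataFrame] = None,
        intercept: Optional[float] = None,
    ) -> "CoefficientTable":
        coefs = {
            r["term"]: Coefficient(
                float(r["estimate"]),
                float(r.get("ci_low", math.nan)),
                float(r.get("ci_high", math.nan)),
            )
            for r in records
        }
        return cls(coefs, covariance=covariance, intercept=intercept)


# Published fixed-effect estimates with 95% CIs.  Age unit: one decade;
# continuous terms uncentered; reference categories as in the module docstring.
_PUBLISHED_ROWS: list[tuple[str, float, float, float]] = [
    ("age_decades", 0.037, -0.024, 0.097),
    ("age_decades_sq", -0.006, -0.011, -0.00075),
    ("male", -0.096, -0.11, -0.079),
    ("not_living_with_spouse", -0.01775, -0.040, 0.001),
    ("lack_friend_support", -0.12, -0.14, -0.091),
    ("edu_primary", -0.18, -0.2, -0.15),
    ("edu_upper_secondary", -0.11, -0.13, -0.096),
    ("hii", -0.12, -0.14, -0.11),
    ("hii_sq", 0.0069, 0.0029, 0.011),
    ("bmi_normal", 0.11, 0.095, 0.13),
    ("bmi_obese", -0.21, -0.23, -0.18),
    ("hba1c_high", -0.21, -0.24, -0.17),
    ("smoker", -0.12, -0.14, -0.099),
    ("pa_mild_lt1", -0.26, -0.29, -0.23),
    ("pa_mild_1wk", -0.19, -0.22, -0.17),
    ("pa_mild_23wk", -0.22, -0.25, -0.2),
    ("pa_mild_ge4", -0.13, -0.15, -0.1),
    ("pa_moderate_lt1", -0.15, -0.18, -0.11),
    ("pa_moderate_1wk", -0.087, -0.11, -0.06),
    ("pa_moderate_ge4", 0.089, 0.066, 0.11),
    ("pa_hard_lt1", -0.25, -0.44, -0.056),
    ("pa_hard_1wk", -0.06, -0.17, 0.048),
    ("pa_hard_23wk", 0.19, 0.15, 0.24),
    ("pa_hard_ge4", 0.38, 0.3, 0.46),
    ("hscl", -1.9, -2.2, -1.5),
    ("hscl_sq", 0.56, 0.37, 0.75),
    ("hscl_cube", -0.063, -0.095, -0.032),
    ("age_gt65:pa_intense_ge4", -0.24, -0.47, -0.02),
    ("age_gt65:bmi_normal", -0.073, -0.11, -0.04),
    ("age_gt65:bmi_obese", 0.11, 0.074, 0.15),
]

#: Human-readable labels for display, keyed by term name.
TERM_LABELS: dict[str, str] = {
    "age_decades": "Age (decades)",
    "age_decades_sq": "Age^2",
    "male": "Male",
    "not_living_with_spouse": "Not living with spouse",
    "lack_friend_support": "Lack friend support",
    "edu_primary": "Primary/partly secondary education",
    "edu_upper_secondary": "Upper secondary education",
    "hii": "HII",
    "hii_sq": "HII^2",
    "bmi_underweight": "BMI underweight",
    "bmi_normal": "BMI normal",
    "bmi_obese": "BMI obese",
    "hba1c_high": "HbA1c >= 6.5%",
    "smoker": "Current smoker",
    "pa_mild_lt1": "Mild PA < 1/week",
    "pa_mild_1wk": "Mild PA 1/week",
    "pa_mild_23wk": "Mild PA 2-3/week",
    "pa_mild_ge4": "Mild PA >= 4/week",
    "pa_moderate_lt1": "Moderate PA < 1/week",
    "pa_moderate_1wk": "Moderate PA 1/week",
    "pa_moderate_ge4": "Moderate PA >= 4/week",
    "pa_hard_lt1": "Intense PA < 1/week",
    "pa_hard_1wk": "Intense PA 1/week",
    "pa_hard_23wk": "Intense PA 2-3/week",
    "pa_hard_ge4": "Intense PA >= 4/week",
    "hscl": "HSCL",
    "hscl_sq": "HSCL^2",
    "hscl_cube": "HSCL^3",
    "age_gt65:pa_intense_ge4": "Age > 65 : intense PA >= 4/week",
    "age_gt65:bmi_normal": "Age > 65 : BMI normal",
    "age_gt65:bmi_obese": "Age > 65 : BMI obese",
}


def default_coefficients() -> CoefficientTable:
    """The embedded published coefficient table (estimates and 95% CIs).

    No covariance matrix and no intercept are attached: the source prints
    neither, so CIs on contrasts of this table require the independence
    approximation, and absolute predictions require a user-supplied anchor.
    """
    return CoefficientTable.from_records(
        {"term": n, "estimate": e, "ci_low": lo, "ci_high": hi}
        for n, e, lo, hi in _PUBLISHED_ROWS
    )


def build_design_row(
    profile: UserProfile, spec: ModelTermSpec = DEFAULT_TERM_SPEC
) -> dict[str, float]:
    """Evaluate each basis function at the profile, in spec order."""
    return {name: float(func(profile)) for name, func in spec}


def linear_effect(
    profile: UserProfile,
    coeffs: Optional[CoefficientTable] = None,
    spec: ModelTermSpec = DEFAULT_TERM_SPEC,
) -> float:
    """Fixed-effect linear predictor, excluding intercept and random effect.

    Terms with a zero design weight need no coefficient; the underweight BMI
    dummy, for which no coefficient was published, falls back to 0 (the
    overweight reference level) with a warning unless the table provides one.
    """
    if coeffs is None:
        coeffs = default_coefficients()
    row = build_design_row(profile, spec)
    total = 0.0
    for name, x in row.items():
        if x == 0.0:
            continue
        if name not in coeffs:
            if name == "bmi_underweight":
                warnings.warn(
                    "no coefficient for underweight BMI; treating it as the "
                    "overweight reference level (effect 0)",
                    stacklevel=2,
                )
                continue
            raise ModelError(f"design requires coefficient {name!r} which the table lacks")
        total += x * coeffs.estimate(name)
    return total


def predict_srh(
    profile: UserProfile,
    coeffs: Optional[CoefficientTable] = None,
    intercept: Optional[float] = None,
    spec: ModelTermSpec = DEFAULT_TERM_SPEC,
) -> float:
    """Absolute mean-SRH prediction; requires an intercept anchor."""
    if coeffs is None:
        coeffs = default_coefficients()
    anchor = intercept if intercept is not None else coeffs.intercept
    if anchor is None:
        raise ModelError(
            "absolute prediction requires an intercept; the published table has "
            "none, supply one explicitly or use effect_between for differences"
        )
    return float(anchor) + linear_effect(profile, coeffs, spec)


@dataclass
class EffectEstimate:
    """Predicted mean-SRH difference between two covariate states.

    ``effect`` is on the 4-point SRH scale; ``contrast`` holds the
    design-difference weights so the estimate equals ``contrast . estimates``.
    The estimate is associational, not causal.
    """

    effect: float
    contrast: dict[str, float]
    ci: Optional[tuple[float, float]] = None
    ci_method: str = "none"


def effect_between(
    current: UserProfile,
    target: UserProfile,
    coeffs: Optional[CoefficientTable] = None,
    spec: ModelTermSpec = DEFAULT_TERM_SPEC,
    ci_method: Optional[str] = None,
) -> EffectEstimate:
    """Predicted mean change in SRH moving from ``current`` to ``target``.

    All covariates the two profiles share cancel, as do the intercept and the
    person's random effect, so the result is well defined without either.
    Positive values mean the target state predicts better SRH.
    """
    if coeffs is None:
        coeffs = default_coefficients()
    effect = linear_effect(target, coeffs, spec) - linear_effect(current, coeffs, spec)
    row_cur = build_design_row(current, spec)
    row_tgt = build_design_row(target, spec)
    contrast = {
        n: row_tgt[n] - row_cur[n] for n in row_tgt if row_tgt[n] != row_cur[n]
    }
    est = EffectEstimate(effect=effect, contrast=contrast)
    if ci_method is not None:
        est.ci = effect_ci(contrast, coeffs, method=ci_method)
        est.ci_method = ci_method
    return est


def effect_ci(
    contrast: Mapping[str, float],
    coeffs: CoefficientTable,
    method: str = "covariance_delta",
) -> tuple[float, float]:
    """Delta-method 95% CI for a linear contrast of coefficients.

    With ``method="covariance_delta"`` the attached parameter covariance is
    used (variance = c' Sigma c).  With ``method="independence_approx"``
    the covariance is taken diagonal with squared standard errors recovered
    from the printed CIs as ((high-low)/3.92)^2; correlations between
    estimates are ignored, so treat the result as approximate.
    """
    names = [n for n, w in contrast.items() if w != 0.0]
    weights = np.array([contrast[n] for n in names], dtype=float)
    effect = float(sum(w * coeffs.estimate(n) for n, w in zip(names, weights)))
    if not names:
        return (0.0, 0.0)
    if method == "covariance_delta":
        if coeffs.covariance is None:
            raise ModelError(
                "no parameter covariance attached; request "
                'method="independence_approx" to use printed-CI standard errors'
            )
        missing = [n for n in names if n not in coeffs.covariance.index]
        if missing:
            raise ModelError(f"covariance matrix lacks terms: {missing}")
        sigma = coeffs.covariance.loc[names, names].to_numpy(dtype=float)
        var = float(weights @ sigma @ weights)
    elif method == "independence_approx":
        ses = []
        for n in names:
            c = coeffs.coefficients.get(n)
            if c is None or math.isnan(c.se):
                raise ModelError(f"no CI available to recover a standard error for {n!r}")
            ses.append(c.se)
        var = float(np.sum((weights * np.array(ses)) ** 2))
    else:
        raise ModelError(f"unknown ci method {method!r}")
    half = Z95 * math.sqrt(max(var, 0.0))
    return (effect - half, effect + half)


def pa_effect_grid(
    base: UserProfile,
    coeffs: Optional[CoefficientTable] = None,
    spec: ModelTermSpec = DEFAULT_TERM_SPEC,
) -> pd.DataFrame:
    """Effect of each PA frequency-by-intensity cell versus the sedentary cell.

    Rows are frequencies, columns intensities; the reference is the base
    profile set to mild intensity, <1/week ("sedentary").  The base profile's
    age determines whether the age>65 interaction applies.
    """
    sedentary = base.replace(pa_frequency="lt1_per_week", pa_intensity="mild")
    grid = pd.DataFrame(
        index=pd.Index(PA_FREQUENCIES, name="pa_frequency"),
        columns=pd.Index(PA_INTENSITIES, name="pa_intensity"),
        dtype=float,
    )
    for f in PA_FREQUENCIES:
        for i in PA_INTENSITIES:
            cell = base.replace(pa_frequency=f, pa_intensity=i)
            grid.loc[f, i] = effect_between(sedentary, cell, coeffs, spec).effect
    return grid
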
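"""Synthetic two-wave survey cohorts with the structure the SRH model assumes.

The generator emulates the statistical skeleton of a two-wave population
survey: each participant gets covariates drawn from configurable marginals, a
persistent random intercept (their personal SRH baseline), one row in wave 6
and — with a configurable overlap probability — a second row in wave 7 with
modifiable covariates redrawn from the wave-7 marginals and age advanced by
the inter-wave gap.  Latent SRH is

    SRH* = intercept + x'beta + u_i + eps,   u_i ~ N(0, sd_u),  eps ~ N(0, sd_e)

and the observed 4-level SRH is SRH* rounded to the nearest integer and
clamped to [1, 4] (equivalent to cutpoints 1.5/2.5/3.5).

Covariates are drawn independently across variables; real covariates
correlate, so parameter-recovery results here do not establish robustness to
confounded designs.  A ``joint_sampler`` hook accepts a user-supplied
function for correlated draws.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Any, Callable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    CoefficientTable,
    DEFAULT_TERM_SPEC,
    ModelTermSpec,
    default_coefficients,
)

__all__ = [
    "SyntheticSpec",
    "SynthError",
    "default_marginals",
    "default_spec",
    "generate_cohort",
    "calibrate_intercept",
    "residual_sd_for_marginal_r2",
    "DEFAULT_INTERCEPT",
    "DEFAULT_RESIDUAL_SD",
    "DEFAULT_RANDOM_INTERCEPT_SD",
    "INTER_WAVE_YEARS",
]


class SynthError(ValueError):
    """Raised on invalid simulation specifications."""


#: Years between the two survey waves (2007-08 to 2015-16).
INTER_WAVE_YEARS = 8.0

#: Between-person SRH-baseline standard deviation (published fit).
DEFAULT_RANDOM_INTERCEPT_SD = 0.298

#: Latent-scale intercept; calibrated with ``calibrate_intercept`` so that the
#: simulated share of good-or-excellent SRH matches the wave-6 share 0.683.
DEFAULT_INTERCEPT = 4.89

#: Residual SD; solves total latent variance = the published wave-6 SRH
#: variance (0.579, from the printed level shares), computed numerically with
#: ``residual_sd_for_total_variance``.  Under independently drawn covariates
#: the fixed-effect variance is ~0.10, so the published marginal R^2 of 0.631
#: is unattainable on the latent scale (see docs/methods.md); anchoring the
#: total outcome variance instead keeps the simulated SRH scale realistic.
DEFAULT_RESIDUAL_SD = 0.623

#: Published wave-6 SRH variance implied by the printed level shares
#: (5.6 / 26.1 / 53.7 / 14.6 %).
OBSERVED_SRH_VARIANCE = 0.579

#: Share of wave-6-complete participants who also appear in wave 7.
DEFAULT_P_SECOND_WAVE = 6264 / 22335


def default_marginals() -> dict[str, Any]:
    """Per-variable marginal distributions mirroring the published sample
    characteristics; wave-varying entries are keyed by wave."""
    return {
        "female": 0.534,
        "education": {"primary": 0.287, "upper_secondary": 0.335, "university": 0.378},
        "lives_with_spouse": 0.751,
        "friend_support": 0.889,
        # wave-6 age distribution; truncated normal, roughly matching the
        # published age-threshold shares (>=45: 78%, >=65: 31%)
        "age": {"mean": 57.0, "sd": 13.0, "min": 30.0, "max": 88.0},
        # zero-inflated comorbidity index matching the HII>=k shares
        "hii_pmf": {0: 0.645, 1: 0.110, 2: 0.135, 3: 0.072, 4: 0.017, 5: 0.012, 6: 0.009},
        "pa_frequency": {
            6: {"lt1_per_week": 0.223, "1_per_week": 0.199, "2_3_per_week": 0.387, "ge4_per_week": 0.192},
            7: {"lt1_per_week": 0.119, "1_per_week": 0.190, "2_3_per_week": 0.415, "ge4_per_week": 0.277},
        },
        "pa_intensity": {
            6: {"mild": 0.472, "moderate": 0.496, "hard": 0.033},
            7: {"mild": 0.391, "moderate": 0.567, "hard": 0.042},
        },
        "bmi_category": {
            6: {"underweight": 0.006, "normal": 0.347, "overweight": 0.443, "obese": 0.204},
            7: {"underweight": 0.006, "normal": 0.320, "overweight": 0.437, "obese": 0.238},
        },
        "smoker": {6: 0.204, 7: 0.139},
        "hba1c_high": {6: 0.068, 7: 0.059},
        # HSCL-10 = 1 + lognormal, clipped above at 4; sigma fixed, mu solved
        # so that P(HSCL >= 1.85) matches the published distress share
        "hscl": {"sigma": 1.0, "p_distress": {6: 0.084, 7: 0.087}},
    }


@dataclass
class SyntheticSpec:
    """Full description of a synthetic cohort draw."""

    n_participants: int = 5000
    p_second_wave: float = DEFAULT_P_SECOND_WAVE
    marginals: dict[str, Any] = field(default_factory=default_marginals)
    true_coefficients: CoefficientTable = field(default_factory=default_coefficients)
    intercept: float = DEFAULT_INTERCEPT
    random_intercept_sd: float = DEFAULT_RANDOM_INTERCEPT_SD
    residual_sd: float = DEFAULT_RESIDUAL_SD
    seed: int = 0
    term_spec: ModelTermSpec = field(default_factory=lambda: DEFAULT_TERM_SPEC)
    #: optional hook: callable(rng, n, wave) -> DataFrame of covariates,
    #: replacing the independent-marginal draw (for correlated designs)
    joint_sampler: Optional[Callable] = None

    def __post_init__(self) -> None:
        if self.n_participants <= 0:
            raise SynthError("n_participants must be positive")
        if not 0.0 <= self.p_second_wave <= 1.0:
            raise SynthError("p_second_wave must be a probability")
        if self.random_intercept_sd < 0 or self.residual_sd < 0:
            raise SynthError("standard deviations must be non-negative")
        for name in ("education",):
            probs = self.marginals[name]
            if abs(sum(probs.values()) - 1.0) > 1e-6:
                raise SynthError(f"{name} marginal probabilities must sum to 1")
        for name in ("pa_frequency", "pa_intensity", "bmi_category"):
            for wave, probs in self.marginals[name].items():
                total = sum(probs.values())
                if abs(total - 1.0) > 0.01:
                    raise SynthError(f"{name} wave-{wave} probabilities sum to {total}")

    def copy(self) -> "SyntheticSpec":
        new = copy.copy(self)
        new.marginals = copy.deepcopy(self.marginals)
        return new


def default_spec(**overrides: Any) -> SyntheticSpec:
    """The default study conditions (published marginals and variance
    components, true coefficients = the published table)."""
    return SyntheticSpec(**overrides)


def _per_wave(value: Any, wave: int) -> Any:
    if isinstance(value, Mapping) and set(value) <= {6, 7}:
        return value[wave]
    return value


def _draw_categorical(rng: np.random.Generator, probs: Mapping[str, float], n: int) -> np.ndarray:
    cats = list(probs)
    p = np.array([probs[c] for c in cats], dtype=float)
    p = p / p.sum()
    return rng.choice(cats, size=n, p=p)


def _hscl_mu(sigma: float, p_distress: float) -> float:
    # P(1 + exp(N(mu, sigma)) >= 1.85) = p  =>  mu = ln(0.85) - sigma * z(1-p)
    return float(np.log(0.85) - sigma * stats.norm.ppf(1.0 - p_distress))


def _draw_modifiable(
    rng: np.random.Generator, marg: Mapping[str, Any], wave: int, n: int
) -> pd.DataFrame:
    hscl_cfg = marg["hscl"]
    sigma = hscl_cfg["sigma"]
    mu = _hscl_mu(sigma, _per_wave(hscl_cfg["p_distress"], wave))
    hscl = 1.0 + rng.lognormal(mean=mu, sigma=sigma, size=n)
    return pd.DataFrame(
        {
            "bmi_category": _draw_categorical(rng, _per_wave(marg["bmi_category"], wave), n),
            "pa_frequency": _draw_categorical(rng, _per_wave(marg["pa_frequency"], wave), n),
            "pa_intensity": _draw_categorical(rng, _per_wave(marg["pa_intensity"], wave), n),
            "smoker": rng.random(n) < _per_wave(marg["smoker"], wave),
            "hba1c_high": rng.random(n) < _per_wave(marg["hba1c_high"], wave),
            "hscl": np.minimum(hscl, 4.0),
        }
    )


def _design_matrix(df: pd.DataFrame, spec: ModelTermSpec) -> tuple[np.ndarray, list[str]]:
    # local import: fitting depends on this module's CohortTable schema
    from .fitting import design_matrix

    return design_matrix(df, spec, add_intercept=False)


def generate_cohort(spec: SyntheticSpec, seed: Optional[int] = None) -> pd.DataFrame:
    """Draw a synthetic two-wave cohort as a long-format table.

    Columns: participant_id, wave, the :class:`UserProfile` fields, and srh.
    Identical spec and seed give byte-identical output.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.n_participants
    marg = spec.marginals

    # persistent attributes
    a = marg["age"]
    age6 = stats.truncnorm.rvs(
        (a["min"] - a["mean"]) / a["sd"],
        (a["max"] - a["mean"]) / a["sd"],
        loc=a["mean"],
        scale=a["sd"],
        size=n,
        random_state=rng,
    )
    persistent = pd.DataFrame(
        {
            "participant_id": [f"S{i:06d}" for i in range(n)],
            "sex": np.where(rng.random(n) < marg["female"], "female", "male"),
            "education": _draw_categorical(rng, marg["education"], n),
            "lives_with_spouse": rng.random(n) < marg["lives_with_spouse"],
            "friend_support": rng.random(n) < marg["friend_support"],
            "hii": _draw_categorical_int(rng, marg["hii_pmf"], n),
        }
    )
    u = rng.normal(0.0, spec.random_intercept_sd, size=n)
    returns = rng.random(n) < spec.p_second_wave

    frames = []
    for wave, ages, mask in ((6, age6, np.ones(n, bool)), (7, age6 + INTER_WAVE_YEARS, returns)):
        m = int(mask.sum())
        if m == 0:
            continue
        if spec.joint_sampler is not None:
            mod = spec.joint_sampler(rng, m, wave)
        else:
            mod = _draw_modifiable(rng, marg, wave, m)
        df = pd.concat(
            [persistent.loc[mask].reset_index(drop=True), mod.reset_index(drop=True)],
            axis=1,
        )
        df.insert(1, "wave", wave)
        df.insert(2, "age", np.round(ages[mask], 1))
        X, names = _design_matrix(df, spec.term_spec)
        beta = np.array(
            [
                spec.true_coefficients.estimate(nm) if nm in spec.true_coefficients else 0.0
                for nm in names
            ]
        )
        latent = spec.intercept + X @ beta + u[mask] + rng.normal(0.0, spec.residual_sd, size=m)
        df["srh"] = np.clip(np.rint(latent), 1, 4).astype(int)
        frames.append(df)

    out = pd.concat(frames, ignore_index=True)
    return out


def _draw_categorical_int(rng: np.random.Generator, pmf: Mapping[int, float], n: int) -> np.ndarray:
    vals = np.array(list(pmf), dtype=float)
    p = np.array([pmf[int(v)] for v in vals], dtype=float)
    p = p / p.sum()
    return rng.choice(vals, size=n, p=p)


def _good_excellent_share(spec: SyntheticSpec, intercept: float, n: int, seed: int) -> float:
    probe = spec.copy()
    probe.n_participants = n
    probe.intercept = intercept
    df = generate_cohort(probe, seed=seed)
    wave6 = df[df["wave"] == 6]
    return float((wave6["srh"] >= 3).mean())


def calibrate_intercept(
    spec: SyntheticSpec,
    target_good_excellent_rate: float,
    tol: float = 0.01,
    n: int = 20000,
    seed: int = 19937,
    max_iter: int = 60,
) -> float:
    """Bisect the latent intercept until the simulated share of good-or-
    excellent SRH (wave 6) is within ``tol`` of the target.

    The probe simulation reuses one fixed internal seed across evaluations so
    the share is monotone in the intercept.
    """
    if not 0.0 < target_good_excellent_rate < 1.0:
        raise SynthError("target rate must be in (0, 1)")
    lo, hi = -10.0, 15.0
    share_lo = _good_excellent_share(spec, lo, n, seed)
    share_hi = _good_excellent_share(spec, hi, n, seed)
    if not share_lo <= target_good_excellent_rate <= share_hi:
        raise SynthError(
            f"target {target_good_excellent_rate} unattainable: achievable "
            f"range under this spec is [{share_lo:.3f}, {share_hi:.3f}]"
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        share = _good_excellent_share(spec, mid, n, seed)
        if abs(share - target_good_excellent_rate) <= tol:
            return mid
        if share < target_good_excellent_rate:
            lo = mid
        else:
            hi = mid
    raise SynthError("intercept calibration did not converge")


def fixed_effect_variance(spec: SyntheticSpec, n: int = 100000, seed: int = 8191) -> float:
    """Monte-Carlo variance of the fixed-effect predictor x'beta under the
    spec's covariate marginals (wave-6 draw)."""
    probe = spec.copy()
    probe.n_participants = n
    probe.residual_sd = 0.0
    probe.random_intercept_sd = 0.0
    probe.p_second_wave = 0.0
    df = generate_cohort(probe, seed=seed)
    X, names = _design_matrix(df, spec.term_spec)
    beta = np.array(
        [
            spec.true_coefficients.estimate(nm) if nm in spec.true_coefficients else 0.0
            for nm in names
        ]
    )
    return float(np.var(X @ beta))


def theoretical_marginal_r2(spec: SyntheticSpec, n: int = 100000, seed: int = 8191) -> float:
    """The generator's own latent-scale marginal R^2:
    var(x'beta) / (var(x'beta) + sd_u^2 + sd_e^2)."""
    vf = fixed_effect_variance(spec, n=n, seed=seed)
    return vf / (vf + spec.random_intercept_sd**2 + spec.residual_sd**2)


def residual_sd_for_total_variance(
    spec: SyntheticSpec, target_variance: float = OBSERVED_SRH_VARIANCE,
    n: int = 100000, seed: int = 8191,
) -> float:
    """Residual SD such that the total latent variance
    var(x'beta) + sd_u^2 + sd_e^2 equals a target outcome variance."""
    vf = fixed_effect_variance(spec, n=n, seed=seed)
    var_e = target_variance - vf - spec.random_intercept_sd**2
    if var_e < 0:
        raise SynthError(
            f"target variance {target_variance} below the fixed + random "
            f"variance {vf + spec.random_intercept_sd**2:.4f}"
        )
    return float(np.sqrt(var_e))


def residual_sd_for_marginal_r2(
    spec: SyntheticSpec, target_r2: float = 0.631, n: int = 100000, seed: int = 8191
) -> float:
    """Residual SD giving the requested theoretical latent-scale marginal R^2.

    marginal R^2 = var(x'beta) / (var(x'beta) + sd_u^2 + sd_e^2); var(x'beta)
    is estimated by simulating covariates from the spec's marginals.
    """
    probe = spec.copy()
    probe.n_participants = n
    probe.residual_sd = 0.0
    probe.random_intercept_sd = 0.0
    probe.p_second_wave = 0.0
    df = generate_cohort(probe, seed=seed)
    X, names = _design_matrix(df, spec.term_spec)
    beta = np.array(
        [
            spec.true_coefficients.estimate(nm) if nm in spec.true_coefficients else 0.0
            for nm in names
        ]
    )
    var_fixed = float(np.var(X @ beta))
    var_e = var_fixed * (1.0 - target_r2) / target_r2 - spec.random_intercept_sd**2
    if var_e < 0:
        raise SynthError(
            f"target marginal R^2 {target_r2} unattainable: fixed-effect "
            f"variance {var_fixed:.4f} is too small given the random-intercept SD"
        )
    return float(np.sqrt(var_e))
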
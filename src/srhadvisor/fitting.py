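"""Mixed-model fitting, diagnostics, metrics and stratified analyses.

The statistical pipeline behind the embedded coefficient table: a linear
mixed model of 4-level SRH (treated as continuous) with a per-participant
random intercept, power-term selection for continuous covariates,
interaction tests, the equidistance diagnostic for ordinal spacing, a
discretised-normal goodness-of-fit check, held-out prediction metrics, a
nested-model sensitivity sequence, and stratified rate tables.

Estimation uses REML via :class:`statsmodels.regression.mixed_linear_model.MixedLM`;
p-values are Wald z tests on the fixed effects.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .instruments import HSCL_DISTRESS_THRESHOLD
from .model import (
    Coefficient,
    CoefficientTable,
    DEFAULT_TERM_SPEC,
    ModelTermSpec,
    ModelError,
    TERM_GROUPS,
    Z95,
)
from .profiles import UserProfile

__all__ = [
    "FitError",
    "FitResult",
    "MetricsReport",
    "COHORT_COLUMNS",
    "design_matrix",
    "profile_from_row",
    "fit_mixed_model",
    "select_power_terms",
    "test_interaction",
    "equidistance_diagnostic",
    "discretized_normal_gof",
    "prediction_metrics",
    "sensitivity_sequence",
    "stratified_rates",
    "umf_counts",
    "umf_strata",
]


class FitError(ValueError):
    """Raised on invalid fitting inputs (rank deficiency, schema errors)."""


#: Long-format cohort schema: one row per participant per wave.
COHORT_COLUMNS = (
    "participant_id",
    "wave",
    "age",
    "sex",
    "education",
    "lives_with_spouse",
    "friend_support",
    "hii",
    "hscl",
    "bmi_category",
    "pa_frequency",
    "pa_intensity",
    "smoker",
    "hba1c_high",
    "srh",
)


def profile_from_row(row: Mapping) -> UserProfile:
    """Build (and validate) a UserProfile from one cohort row."""
    return UserProfile(
        age=float(row["age"]),
        sex=str(row["sex"]),
        education=str(row["education"]),
        lives_with_spouse=bool(row["lives_with_spouse"]),
        friend_support=bool(row["friend_support"]),
        hii=float(row["hii"]),
        hscl=float(row["hscl"]),
        bmi_category=str(row["bmi_category"]),
        pa_frequency=str(row["pa_frequency"]),
        pa_intensity=str(row["pa_intensity"]),
        smoker=bool(row["smoker"]),
        hba1c_high=bool(row["hba1c_high"]),
    )


def design_matrix(
    cohort: pd.DataFrame,
    spec: ModelTermSpec = DEFAULT_TERM_SPEC,
    add_intercept: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Vectorised design matrix for a cohort under a term spec.

    Term functions are defined on single profiles; here the same encodings
    are applied column-wise for speed, so this function must be kept in sync
    with :data:`~srhadvisor.model.TERM_GROUPS`.
    """
    n = len(cohort)
    age_dec = cohort["age"].to_numpy(float) / 10.0
    hii = cohort["hii"].to_numpy(float)
    hscl = cohort["hscl"].to_numpy(float)
    age_gt65 = cohort["age"].to_numpy(float) > 65.0

    def pa(intensity: str, freq: str) -> np.ndarray:
        return (
            (cohort["pa_intensity"].to_numpy() == intensity)
            & (cohort["pa_frequency"].to_numpy() == freq)
        ).astype(float)

    columns: dict[str, np.ndarray] = {
        "age_decades": age_dec,
        "age_decades_sq": age_dec**2,
        "male": (cohort["sex"].to_numpy() == "male").astype(float),
        "not_living_with_spouse": 1.0 - cohort["lives_with_spouse"].to_numpy(float),
        "lack_friend_support": 1.0 - cohort["friend_support"].to_numpy(float),
        "edu_primary": (cohort["education"].to_numpy() == "primary").astype(float),
        "edu_upper_secondary": (cohort["education"].to_numpy() == "upper_secondary").astype(float),
        "hii": hii,
        "hii_sq": hii**2,
        "bmi_underweight": (cohort["bmi_category"].to_numpy() == "underweight").astype(float),
        "bmi_normal": (cohort["bmi_category"].to_numpy() == "normal").astype(float),
        "bmi_obese": (cohort["bmi_category"].to_numpy() == "obese").astype(float),
        "hba1c_high": cohort["hba1c_high"].to_numpy(float),
        "smoker": cohort["smoker"].to_numpy(float),
        "hscl": hscl,
        "hscl_sq": hscl**2,
        "hscl_cube": hscl**3,
        "age_gt65:pa_intense_ge4": (age_gt65 & (pa("hard", "ge4_per_week") > 0)).astype(float),
        "age_gt65:bmi_normal": (age_gt65 & (cohort["bmi_category"].to_numpy() == "normal")).astype(float),
        "age_gt65:bmi_obese": (age_gt65 & (cohort["bmi_category"].to_numpy() == "obese")).astype(float),
    }
    for i in ("mild", "moderate", "hard"):
        for f in ("lt1_per_week", "1_per_week", "2_3_per_week", "ge4_per_week"):
            short = {"lt1_per_week": "lt1", "1_per_week": "1wk",
                     "2_3_per_week": "23wk", "ge4_per_week": "ge4"}[f]
            columns[f"pa_{i}_{short}"] = pa(i, f)

    names = list(spec.names)
    missing = [nm for nm in names if nm not in columns]
    if missing:
        raise FitError(f"no vectorised encoding for terms: {missing}")
    X = np.column_stack([columns[nm] for nm in names]) if names else np.empty((n, 0))
    if add_intercept:
        X = np.column_stack([np.ones(n), X])
        names = ["intercept"] + names
    return X, names


@dataclass
class FitResult:
    """Fitted mixed model: fixed effects, covariance, variance components."""

    coefficients: CoefficientTable
    random_intercept_sd: float
    residual_sd: float
    n_obs: int
    n_participants: int
    loglik: float
    pvalues: dict[str, float] = field(default_factory=dict)
    participant_ids: frozenset = field(default_factory=frozenset)
    term_spec: ModelTermSpec = field(default_factory=lambda: DEFAULT_TERM_SPEC)

    @property
    def intercept(self) -> float:
        return float(self.coefficients.intercept)

    def predict_fixed(self, cohort: pd.DataFrame) -> np.ndarray:
        """Fixed-effect (population-level) continuous SRH predictions."""
        X, names = design_matrix(cohort, self.term_spec, add_intercept=True)
        beta = np.array(
            [self.intercept]
            + [self.coefficients.estimate(nm) for nm in names[1:]]
        )
        return X @ beta

    def to_dict(self) -> dict:
        cov = self.coefficients.covariance
        return {
            "coefficients": self.coefficients.to_records(),
            "intercept": self.coefficients.intercept,
            "covariance": None if cov is None else {
                "names": list(cov.index),
                "matrix": cov.to_numpy().tolist(),
            },
            "random_intercept_sd": self.random_intercept_sd,
            "residual_sd": self.residual_sd,
            "n_obs": self.n_obs,
            "n_participants": self.n_participants,
            "loglik": self.loglik,
            "pvalues": self.pvalues,
            "participant_ids": sorted(self.participant_ids),
            "terms": self.term_spec.names,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "FitResult":
        cov = None
        if d.get("covariance"):
            cov = pd.DataFrame(
                np.asarray(d["covariance"]["matrix"], dtype=float),
                index=d["covariance"]["names"],
                columns=d["covariance"]["names"],
            )
        table = CoefficientTable.from_records(
            d["coefficients"], covariance=cov, intercept=d.get("intercept")
        )
        spec = DEFAULT_TERM_SPEC.subset(d["terms"]) if "terms" in d else DEFAULT_TERM_SPEC
        return cls(
            coefficients=table,
            random_intercept_sd=float(d["random_intercept_sd"]),
            residual_sd=float(d["residual_sd"]),
            n_obs=int(d["n_obs"]),
            n_participants=int(d["n_participants"]),
            loglik=float(d["loglik"]),
            pvalues=dict(d.get("pvalues", {})),
            participant_ids=frozenset(d.get("participant_ids", ())),
            term_spec=spec,
        )


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    # identify offending columns from the QR diagonal
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    bad = [names[j] for j in range(X.shape[1]) if diag[j] <= tol] or ["<unidentified>"]
    raise FitError(f"design matrix is rank deficient; collinear terms: {bad}")


def _fit_mixedlm(y: np.ndarray, X: np.ndarray, groups: np.ndarray, reml: bool):
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*[Cc]onverge.*")
        warnings.filterwarnings("ignore", message=".*boundary.*")
        warnings.filterwarnings("ignore", category=RuntimeWarning)
        model = sm.MixedLM(y, X, groups=groups)
        return model.fit(reml=reml)


def fit_mixed_model(
    cohort: pd.DataFrame,
    spec: ModelTermSpec = DEFAULT_TERM_SPEC,
    reml: bool = True,
) -> FitResult:
    """Fit the random-intercept linear mixed model of SRH.

    SRH (1-4) is treated as continuous; participant id is the grouping
    variable.  Participants observed in a single wave enter as singleton
    groups; if *no* participant repeats, variance components are weakly
    identified and a warning is issued rather than an error.
    """
    srh = cohort["srh"].to_numpy(float)
    if len(np.unique(srh)) < 2:
        raise FitError("SRH must take at least 2 distinct values")
    X, names = design_matrix(cohort, spec, add_intercept=True)
    # a category absent from the cohort yields an all-zero dummy: the term is
    # inestimable but the rest of the model is fine, so drop it with a warning
    zero = [j for j in range(1, X.shape[1]) if not X[:, j].any()]
    if zero:
        warnings.warn(
            f"dropping terms with no observations: {[names[j] for j in zero]}",
            stacklevel=2,
        )
        keep = [j for j in range(X.shape[1]) if j not in zero]
        X = X[:, keep]
        names = [names[j] for j in keep]
    _check_rank(X, names)
    groups = cohort["participant_id"].to_numpy()
    if pd.Series(groups).value_counts().max() == 1:
        warnings.warn(
            "no participant appears in both waves; random-intercept and "
            "residual variances are weakly identified",
            stacklevel=2,
        )
    res = _fit_mixedlm(srh, X, groups, reml)

    k = len(names)
    fe = np.asarray(res.fe_params, dtype=float)[:k]
    cov = np.asarray(res.cov_params(), dtype=float)[:k, :k]
    se = np.sqrt(np.diag(cov))
    pvals = 2 * stats.norm.sf(np.abs(fe / se))
    cov_df = pd.DataFrame(cov, index=names, columns=names)
    records = [
        {
            "term": nm,
            "estimate": fe[j],
            "ci_low": fe[j] - Z95 * se[j],
            "ci_high": fe[j] + Z95 * se[j],
        }
        for j, nm in enumerate(names)
        if nm != "intercept"
    ]
    table = CoefficientTable.from_records(records, covariance=cov_df, intercept=float(fe[0]))
    return FitResult(
        coefficients=table,
        random_intercept_sd=float(np.sqrt(np.asarray(res.cov_re)[0, 0])),
        residual_sd=float(np.sqrt(res.scale)),
        n_obs=len(cohort),
        n_participants=int(pd.Series(groups).nunique()),
        loglik=float(res.llf),
        pvalues={nm: float(p) for nm, p in zip(names, pvals)},
        participant_ids=frozenset(groups.tolist()),
        term_spec=spec.subset(names[1:]),
    )


def select_power_terms(
    cohort: pd.DataFrame,
    variable: str,
    max_degree: int = 4,
    alpha: float = 0.05,
    reml: bool = True,
) -> set[int]:
    """Powers of one continuous covariate that are significant in a
    single-variable model of SRH.

    All powers 1..max_degree are entered jointly (age is taken in decades);
    the returned set contains the powers whose Wald p-values fall below
    ``alpha``.
    """
    if variable not in ("age", "hii", "hscl"):
        raise FitError(f"variable must be one of age/hii/hscl, got {variable!r}")
    x = cohort[variable].to_numpy(float)
    if variable == "age":
        x = x / 10.0
    X = np.column_stack([np.ones(len(x))] + [x**k for k in range(1, max_degree + 1)])
    _check_rank(X, ["intercept"] + [f"{variable}^{k}" for k in range(1, max_degree + 1)])
    groups = cohort["participant_id"].to_numpy()
    if pd.Series(groups).value_counts().max() == 1:
        # no repeated participants: the random intercept is unidentified and
        # MixedLM standard errors degenerate, so fall back to OLS
        res = sm.OLS(cohort["srh"].to_numpy(float), X).fit()
    else:
        res = _fit_mixedlm(cohort["srh"].to_numpy(float), X, groups, reml)
    fe = np.asarray(getattr(res, "fe_params", res.params), dtype=float)[: max_degree + 1]
    diag = np.diag(np.asarray(res.cov_params(), dtype=float))[: max_degree + 1]
    se = np.sqrt(np.clip(diag, 1e-300, None))
    pvals = 2 * stats.norm.sf(np.abs(fe / se))
    return {k for k in range(1, max_degree + 1) if pvals[k] < alpha}


_MODIFIERS: dict[str, Callable[[pd.DataFrame], np.ndarray]] = {
    "age_gt65": lambda df: (df["age"].to_numpy(float) > 65.0),
    "male": lambda df: (df["sex"].to_numpy() == "male"),
    "hii_ge3": lambda df: (df["hii"].to_numpy(float) >= 3),
    "hii_ge2": lambda df: (df["hii"].to_numpy(float) >= 2),
}

_FACTOR_TERMS: dict[str, list[str]] = {
    "pa": [nm for nm, _ in TERM_GROUPS["pa"]],
    "bmi": [nm for nm, _ in TERM_GROUPS["bmi"]],
}


def test_interaction(
    cohort: pd.DataFrame,
    modifier: str,
    factor: str,
    spec: Optional[ModelTermSpec] = None,
    reml: bool = True,
) -> pd.DataFrame:
    """Test whether a subgroup modifies the effect of PA or BMI on SRH.

    Refits the model with modifier-by-factor interaction dummies added and
    returns each interaction's estimate, 95% CI, Wald p-value and the
    significance decision at 0.05.
    """
    if modifier not in _MODIFIERS:
        raise FitError(f"unknown modifier {modifier!r}; options: {sorted(_MODIFIERS)}")
    if factor not in _FACTOR_TERMS:
        raise FitError(f"unknown factor {factor!r}; options: {sorted(_FACTOR_TERMS)}")
    if spec is None:
        from .model import BASE_TERM_SPEC

        spec = BASE_TERM_SPEC
    ind = _MODIFIERS[modifier](cohort).astype(float)
    if ind.min() == ind.max():
        raise FitError(f"modifier {modifier!r} is constant in this cohort")
    X, names = design_matrix(cohort, spec, add_intercept=True)
    # the modifier's main effect may already be a model term (e.g. "male")
    add_main = not any(np.array_equal(X[:, j], ind) for j in range(X.shape[1]))
    cols, int_names = [], []
    for nm in _FACTOR_TERMS[factor]:
        if nm not in names:
            continue
        base_col = X[:, names.index(nm)]
        prod = base_col * ind
        if prod.sum() == 0:
            raise FitError(
                f"no observations in the {modifier} x {nm} cell; interaction not estimable"
            )
        cols.append(prod)
        int_names.append(f"{modifier}:{nm}")
    extra = ([ind] if add_main else []) + cols
    Xi = np.column_stack([X] + [c[:, None] for c in extra])
    all_names = names + ([modifier] if add_main else []) + int_names
    _check_rank(Xi, all_names)
    res = _fit_mixedlm(
        cohort["srh"].to_numpy(float), Xi, cohort["participant_id"].to_numpy(), reml
    )
    k = len(all_names)
    fe = np.asarray(res.fe_params, dtype=float)[:k]
    se = np.sqrt(np.diag(np.asarray(res.cov_params(), dtype=float)))[:k]
    rows = []
    for nm in int_names:
        j = all_names.index(nm)
        p = float(2 * stats.norm.sf(abs(fe[j] / se[j])))
        rows.append(
            {
                "term": nm,
                "estimate": float(fe[j]),
                "ci_low": float(fe[j] - Z95 * se[j]),
                "ci_high": float(fe[j] + Z95 * se[j]),
                "pvalue": p,
                "significant": p <= 0.05,
            }
        )
    return pd.DataFrame(rows).set_index("term")


def equidistance_diagnostic(fit: FitResult, cohort: pd.DataFrame) -> pd.DataFrame:
    """Check the equal-spacing assumption of the 4-level SRH scale.

    Predicted values are regressed linearly on actual SRH; per level the
    table reports mean prediction, the trendline value, their difference,
    and the SD of predictions.  If predictions are an affine function of
    actual SRH, all deviations are exactly zero; systematic deviations
    (e.g. a compressed top category) indicate unequal spacing.
    """
    pred = fit.predict_fixed(cohort)
    actual = cohort["srh"].to_numpy(float)
    slope, intercept_, *_ = stats.linregress(actual, pred)
    rows = []
    for level in (1, 2, 3, 4):
        mask = actual == level
        if not mask.any():
            rows.append(
                {"srh_level": level, "n": 0, "mean_predicted": math.nan,
                 "trendline": math.nan, "deviation": math.nan, "sd_predicted": math.nan}
            )
            continue
        mp = float(pred[mask].mean())
        tl = float(intercept_ + slope * level)
        rows.append(
            {
                "srh_level": level,
                "n": int(mask.sum()),
                "mean_predicted": mp,
                "trendline": tl,
                "deviation": mp - tl,
                "sd_predicted": float(pred[mask].std(ddof=0)),
            }
        )
    return pd.DataFrame(rows).set_index("srh_level")


def discretized_normal_gof(srh_values) -> pd.DataFrame:
    """Goodness of fit of SRH to a discretised normal distribution.

    A normal is fitted to the integer SRH values (moment estimates) and its
    probability mass over the bins (-inf, 1.5], (1.5, 2.5], (2.5, 3.5],
    (3.5, inf) is compared with the empirical level frequencies.
    """
    v = np.asarray(srh_values, dtype=float)
    if v.size == 0 or not np.isin(v, (1, 2, 3, 4)).all():
        raise FitError("SRH values must be integers in 1..4")
    mu, sd = float(v.mean()), float(v.std(ddof=0))
    if sd == 0:
        raise FitError("zero variance: all SRH values identical, normal fit undefined")
    edges = np.array([-np.inf, 1.5, 2.5, 3.5, np.inf])
    cdf = stats.norm.cdf(edges, loc=mu, scale=sd)
    theoretical = np.diff(cdf)
    empirical = np.array([(v == lev).mean() for lev in (1, 2, 3, 4)])
    return pd.DataFrame(
        {"srh_level": [1, 2, 3, 4], "theoretical": theoretical, "empirical": empirical}
    ).set_index("srh_level")


@dataclass
class MetricsReport:
    """Held-out prediction metrics for the SRH model."""

    accuracy: float
    accuracy_ci: tuple[float, float]
    auc_poor: float
    auc_excellent: float
    correlation: float
    marginal_r2: float
    n: int
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "accuracy_ci": list(self.accuracy_ci),
            "auc_poor": self.auc_poor,
            "auc_excellent": self.auc_excellent,
            "correlation": self.correlation,
            "marginal_r2": self.marginal_r2,
            "n": self.n,
            "notes": self.notes,
        }


def prediction_metrics(fit: FitResult, holdout: pd.DataFrame) -> MetricsReport:
    """Accuracy, one-vs-rest AUCs, correlation and marginal R^2 on a holdout.

    The holdout must share no participants with the training set.  Accuracy
    uses fixed-effect predictions rounded to the nearest integer and clamped
    to [1, 4]; AUCs score poor (SRH=1) and excellent (SRH=4) one-vs-rest with
    the continuous prediction as the score; marginal R^2 is the fixed-effect
    prediction variance over the total (fixed + random-intercept + residual)
    variance.
    """
    from sklearn.metrics import roc_auc_score

    overlap = fit.participant_ids & set(holdout["participant_id"])
    if overlap:
        raise FitError(
            f"{len(overlap)} holdout participants were in the training set "
            f"(e.g. {sorted(overlap)[:3]})"
        )
    pred = fit.predict_fixed(holdout)
    actual = holdout["srh"].to_numpy(float)
    n = len(actual)
    rounded = np.clip(np.rint(pred), 1, 4)
    acc = float((rounded == actual).mean())
    half = Z95 * math.sqrt(max(acc * (1 - acc), 1e-12) / n)
    notes: list[str] = []

    def one_vs_rest_auc(positive_mask: np.ndarray, score: np.ndarray) -> float:
        if positive_mask.all() or not positive_mask.any():
            notes.append("AUC undefined: one class absent in holdout")
            return math.nan
        return float(roc_auc_score(positive_mask.astype(int), score))

    # low predictions indicate poor SRH, so negate the score for the poor end
    auc_poor = one_vs_rest_auc(actual == 1, -pred)
    auc_excellent = one_vs_rest_auc(actual == 4, pred)
    if np.allclose(pred.std(ddof=0), 0.0):
        corr = math.nan
        notes.append("correlation undefined: constant predictions")
        auc_poor = 0.5 if not math.isnan(auc_poor) else auc_poor
        auc_excellent = 0.5 if not math.isnan(auc_excellent) else auc_excellent
    else:
        corr = float(stats.pearsonr(pred, actual)[0])
    var_fixed = float(np.var(pred, ddof=0))
    marginal_r2 = var_fixed / (
        var_fixed + fit.random_intercept_sd**2 + fit.residual_sd**2
    )
    return MetricsReport(
        accuracy=acc,
        accuracy_ci=(max(acc - half, 0.0), min(acc + half, 1.0)),
        auc_poor=auc_poor,
        auc_excellent=auc_excellent,
        correlation=corr,
        marginal_r2=marginal_r2,
        n=n,
        notes=notes,
    )


def sensitivity_sequence(
    cohort: pd.DataFrame,
    base_groups: Sequence[str],
    additions: Sequence[str],
    contrast: Mapping[str, float],
    reml: bool = True,
) -> pd.DataFrame:
    """Effect of one contrast across a nested sequence of models.

    ``base_groups`` and ``additions`` name entries of
    :data:`~srhadvisor.model.TERM_GROUPS`; model M0 contains the base groups
    and each M_k adds one more group.  The contrast (term -> weight) must be
    supported by the base model.  Returns one row per model with the delta-
    method 95% CI of the contrast effect.
    """
    if set(base_groups) & set(additions):
        raise FitError("additions must be disjoint from the base groups")
    unknown = [g for g in list(base_groups) + list(additions) if g not in TERM_GROUPS]
    if unknown:
        raise FitError(f"unknown term groups: {unknown}")

    rows = []
    groups = list(base_groups)
    for step in range(len(additions) + 1):
        label = "M0" if step == 0 else f"M{step} (+{additions[step - 1]})"
        if step > 0:
            groups.append(additions[step - 1])
        spec = ModelTermSpec([t for g in groups for t in TERM_GROUPS[g]])
        missing = [nm for nm, w in contrast.items() if w != 0 and nm not in spec.names]
        if missing:
            raise FitError(f"contrast terms {missing} absent from model {label}")
        fit = fit_mixed_model(cohort, spec, reml=reml)
        names = [nm for nm, w in contrast.items() if w != 0]
        w = np.array([contrast[nm] for nm in names], dtype=float)
        beta = np.array([fit.coefficients.estimate(nm) for nm in names])
        sigma = fit.coefficients.covariance.loc[names, names].to_numpy(dtype=float)
        eff = float(w @ beta)
        half = Z95 * math.sqrt(max(float(w @ sigma @ w), 0.0))
        rows.append(
            {"model": label, "effect": eff, "ci_low": eff - half, "ci_high": eff + half}
        )
    return pd.DataFrame(rows).set_index("model")


def umf_counts(cohort: pd.DataFrame) -> pd.Series:
    """Vectorised count of unhealthy modifiable factors per row."""
    return (
        (cohort["pa_frequency"] == "lt1_per_week").astype(int)
        + cohort["hba1c_high"].astype(int)
        + cohort["bmi_category"].isin(("overweight", "obese")).astype(int)
        + cohort["smoker"].astype(int)
        + (cohort["hscl"] >= HSCL_DISTRESS_THRESHOLD).astype(int)
    )


def umf_strata(cohort: pd.DataFrame) -> dict[str, np.ndarray]:
    """Boolean masks for the UMF strata 0, 1, 2, 3 and >=4."""
    counts = umf_counts(cohort)
    strata = {str(k): (counts == k).to_numpy() for k in (0, 1, 2, 3)}
    strata[">=4"] = (counts >= 4).to_numpy()
    return strata


def stratified_rates(
    cohort: pd.DataFrame,
    strata: Mapping[str, np.ndarray],
    outcome: Callable[[pd.DataFrame], np.ndarray],
    method: str = "normal",
) -> pd.DataFrame:
    """Outcome rate (%) with a 95% CI in each stratum.

    ``strata`` maps labels to boolean row masks; ``outcome`` maps the cohort
    to a boolean vector.  The default CI is the normal approximation
    p +- 1.96 sqrt(p(1-p)/n); Wilson intervals are available with
    ``method="wilson"``.  Empty strata get NaN rates.
    """
    y = np.asarray(outcome(cohort), dtype=bool)
    rows = []
    for label, mask in strata.items():
        mask = np.asarray(mask, dtype=bool)
        n = int(mask.sum())
        if n == 0:
            rows.append({"stratum": label, "n": 0, "rate_pct": math.nan,
                         "ci_low_pct": math.nan, "ci_high_pct": math.nan})
            continue
        k = int(y[mask].sum())
        p = k / n
        if method == "normal":
            half = Z95 * math.sqrt(p * (1 - p) / n)
            lo, hi = max(p - half, 0.0), min(p + half, 1.0)
        elif method == "wilson":
            z2 = Z95**2
            centre = (p + z2 / (2 * n)) / (1 + z2 / n)
            half = (Z95 / (1 + z2 / n)) * math.sqrt(p * (1 - p) / n + z2 / (4 * n**2))
            lo, hi = centre - half, centre + half
        else:
            raise FitError(f"unknown CI method {method!r}")
        rows.append(
            {"stratum": label, "n": n, "rate_pct": 100 * p,
             "ci_low_pct": 100 * lo, "ci_high_pct": 100 * hi}
        )
    return pd.DataFrame(rows).set_index("stratum")
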
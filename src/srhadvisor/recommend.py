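"""Personalised lifestyle-goal recommendation built on the SRH model.

Given a user profile, the engine finds the modifiable categories with room
for improvement, evaluates a catalog of candidate goals (always including the
model-optimal state of each category), and ranks categories by the effect of
reaching that optimal state.  Results can be rendered as a horizontal bar
chart plus a machine-readable report.

Only lifestyle categories generate goals: mental health (HSCL-10), physical
activity, weight (BMI category), smoking and blood-sugar control.  Age, sex,
education, household, friend support and comorbidity are never treated as
modifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Optional, Sequence

from .model import (
    CoefficientTable,
    EffectEstimate,
    ModelTermSpec,
    DEFAULT_TERM_SPEC,
    default_coefficients,
    effect_between,
    predict_srh,
)
from .profiles import UserProfile

__all__ = [
    "CATEGORIES",
    "GoalCatalogEntry",
    "Recommendation",
    "default_catalog",
    "find_improvable_factors",
    "optimal_state",
    "build_recommendations",
    "joint_effect",
    "render_report",
    "ASSOCIATION_CAVEAT",
]

#: Fixed category enumeration; also the tie-break order for equal effects.
CATEGORIES = ("mental_health", "physical_activity", "weight", "smoking", "blood_sugar")

#: Profile fields each category is allowed to touch.
CATEGORY_FIELDS: dict[str, tuple[str, ...]] = {
    "mental_health": ("hscl",),
    "physical_activity": ("pa_frequency", "pa_intensity"),
    "weight": ("bmi_category",),
    "smoking": ("smoker",),
    "blood_sugar": ("hba1c_high",),
}

ASSOCIATION_CAVEAT = (
    "Predicted effects are statistical associations estimated from an "
    "observational cohort; they are not causal guarantees, and reaching a "
    "goal may not produce the displayed change."
)


@dataclass(frozen=True)
class GoalCatalogEntry:
    """A candidate lifestyle target: the profile fields a goal would set."""

    category: str
    label: str
    state_override: Mapping[str, Any]

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        allowed = set(CATEGORY_FIELDS[self.category])
        bad = set(self.state_override) - allowed
        if bad:
            raise ValueError(
                f"goal {self.label!r} touches non-modifiable or foreign fields {sorted(bad)}"
            )


@dataclass
class Recommendation:
    goal: GoalCatalogEntry
    effect: EffectEstimate
    category_rank: int
    within_category_order: int
    is_optimal_state: bool


def default_catalog() -> list[GoalCatalogEntry]:
    """Shipped intermediate goals; the optimal state per category is always
    appended automatically by :func:`build_recommendations`."""
    return [
        GoalCatalogEntry(
            "mental_health",
            "Bring mental distress below the clinical threshold (HSCL-10 = 1.85)",
            {"hscl": 1.85},
        ),
        GoalCatalogEntry(
            "physical_activity",
            "Exercise with moderate intensity 2-3 times per week",
            {"pa_frequency": "2_3_per_week", "pa_intensity": "moderate"},
        ),
        GoalCatalogEntry(
            "physical_activity",
            "Exercise with moderate intensity at least 4 times per week",
            {"pa_frequency": "ge4_per_week", "pa_intensity": "moderate"},
        ),
    ]


def load_catalog(records: Sequence[Mapping[str, Any]]) -> list[GoalCatalogEntry]:
    """Build a catalog from plain mappings (e.g. parsed YAML)."""
    return [
        GoalCatalogEntry(r["category"], r["label"], dict(r["state_override"]))
        for r in records
    ]


# Candidate states per category, ordered least-extreme first so that argmax
# ties resolve toward the less extreme state.  PA candidates are generated on
# the fly (12 combinations ordered by frequency then intensity).
_BMI_CANDIDATES = ("overweight", "normal", "obese")
_PA_FREQ_ORDER = ("lt1_per_week", "1_per_week", "2_3_per_week", "ge4_per_week")
_PA_INT_ORDER = ("mild", "moderate", "hard")


def _category_candidates(category: str) -> list[dict[str, Any]]:
    if category == "mental_health":
        return [{"hscl": 1.0}]
    if category == "physical_activity":
        return [
            {"pa_frequency": f, "pa_intensity": i}
            for f in _PA_FREQ_ORDER
            for i in _PA_INT_ORDER
        ]
    if category == "weight":
        return [{"bmi_category": b} for b in _BMI_CANDIDATES]
    if category == "smoking":
        return [{"smoker": False}]
    if category == "blood_sugar":
        return [{"hba1c_high": False}]
    raise ValueError(f"unknown category {category!r}")


def optimal_state(
    profile: UserProfile,
    category: str,
    coeffs: Optional[CoefficientTable] = None,
    spec: ModelTermSpec = DEFAULT_TERM_SPEC,
) -> dict[str, Any]:
    """Model-optimal state of a category, holding everything else fixed.

    The argmax is taken over the category's state space with interactions
    evaluated at the profile's own age, so e.g. the optimal exercise schedule
    differs above age 65.  Ties break toward the less extreme state.
    """
    if coeffs is None:
        coeffs = default_coefficients()
    best: Optional[dict[str, Any]] = None
    best_val = -float("inf")
    for cand in _category_candidates(category):
        val = effect_between(profile, profile.replace(**cand), coeffs, spec).effect
        if val > best_val + 1e-12:  # strict improvement; first max wins ties
            best, best_val = cand, val
    assert best is not None
    return best


def _differs(profile: UserProfile, override: Mapping[str, Any]) -> bool:
    return any(getattr(profile, k) != v for k, v in override.items())


def find_improvable_factors(
    profile: UserProfile,
    coeffs: Optional[CoefficientTable] = None,
    spec: ModelTermSpec = DEFAULT_TERM_SPEC,
) -> set[str]:
    """Categories whose current state differs from their model-optimal state."""
    return {
        cat
        for cat in CATEGORIES
        if _differs(profile, optimal_state(profile, cat, coeffs, spec))
    }


def joint_effect(
    profile: UserProfile,
    overrides: Mapping[str, Any],
    coeffs: Optional[CoefficientTable] = None,
    spec: ModelTermSpec = DEFAULT_TERM_SPEC,
) -> EffectEstimate:
    """Predicted effect of reaching several goals at once."""
    return effect_between(profile, profile.replace(**overrides), coeffs, spec)


_OPTIMAL_LABELS = {
    "mental_health": "Reach the optimal state: no mental-distress symptoms (HSCL-10 = 1)",
    "physical_activity": "Reach the optimal exercise schedule for your age",
    "weight": "Reach the optimal BMI category",
    "smoking": "Stop smoking",
    "blood_sugar": "Bring HbA1c below 6.5%",
}


def build_recommendations(
    profile: UserProfile,
    catalog: Optional[Sequence[GoalCatalogEntry]] = None,
    coeffs: Optional[CoefficientTable] = None,
    spec: ModelTermSpec = DEFAULT_TERM_SPEC,
) -> list[Recommendation]:
    """Ranked goals for every improvable category.

    Categories are ordered by the effect of reaching their optimal state,
    descending (ties by the fixed category enumeration); within a category
    goals are ordered by increasing effect, ending at the optimal state.
    Goals whose predicted effect is not positive are dropped.  An empty list
    means the profile is already model-optimal everywhere.
    """
    if coeffs is None:
        coeffs = default_coefficients()
    if catalog is None:
        catalog = default_catalog()

    per_category: list[tuple[float, str, list[tuple[GoalCatalogEntry, EffectEstimate, bool]]]] = []
    for cat in CATEGORIES:
        opt = optimal_state(profile, cat, coeffs, spec)
        if not _differs(profile, opt):
            continue
        opt_entry = GoalCatalogEntry(cat, _OPTIMAL_LABELS[cat], opt)
        opt_est = effect_between(profile, profile.replace(**opt), coeffs, spec)
        if opt_est.effect <= 0:
            continue
        goals: list[tuple[GoalCatalogEntry, EffectEstimate, bool]] = []
        for entry in catalog:
            if entry.category != cat:
                continue
            if not _differs(profile, entry.state_override):
                continue
            if dict(entry.state_override) == dict(opt):
                continue  # collapses onto the optimal goal
            est = effect_between(
                profile, profile.replace(**entry.state_override), coeffs, spec
            )
            if est.effect <= 0:
                continue
            goals.append((entry, est, False))
        goals.append((opt_entry, opt_est, True))
        goals.sort(key=lambda t: t[1].effect)
        per_category.append((opt_est.effect, cat, goals))

    # descending optimal effect; stable on the fixed category order
    per_category.sort(key=lambda t: -t[0])

    out: list[Recommendation] = []
    for rank, (_, _, goals) in enumerate(per_category, start=1):
        for order, (entry, est, is_opt) in enumerate(goals, start=1):
            out.append(Recommendation(entry, est, rank, order, is_opt))
    return out


def render_report(
    recommendations: Sequence[Recommendation],
    anchor: Optional[float] = None,
    profile: Optional[UserProfile] = None,
    coeffs: Optional[CoefficientTable] = None,
):
    """Render recommendations as a figure plus a machine-readable report.

    Each goal becomes a horizontal bar whose length is its predicted SRH
    effect, grouped by category in rank order.  When ``anchor`` (an absolute
    intercept-based prediction of the user's current SRH) is given, bars
    start at the current prediction and a dotted vertical line marks it;
    otherwise bars start at zero and the axis is labelled as relative change.

    Returns
    -------
    (matplotlib.figure.Figure, dict)
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    current_pred = None
    if anchor is not None and profile is not None:
        current_pred = predict_srh(profile, coeffs, intercept=anchor)
    elif anchor is not None:
        current_pred = float(anchor)

    report: dict[str, Any] = {
        "status": "goals" if recommendations else "already_optimal",
        "caveat": ASSOCIATION_CAVEAT,
        "anchor": current_pred,
        "scale": "absolute SRH" if current_pred is not None else "change relative to current state",
        "goals": [
            {
                "category": r.goal.category,
                "label": r.goal.label,
                "effect": r.effect.effect,
                "ci": list(r.effect.ci) if r.effect.ci else None,
                "category_rank": r.category_rank,
                "within_category_order": r.within_category_order,
                "is_optimal_state": r.is_optimal_state,
            }
            for r in recommendations
        ],
    }

    fig, ax = plt.subplots(figsize=(8, max(2.0, 0.6 * len(recommendations) + 1)))
    if not recommendations:
        ax.text(0.5, 0.5, "All lifestyle factors already at their model-optimal state",
                ha="center", va="center", transform=ax.transAxes)
        ax.set_axis_off()
        report["message"] = "congratulations: nothing to improve"
        return fig, report

    ordered = sorted(recommendations, key=lambda r: (r.category_rank, r.within_category_order))
    labels = [r.goal.label for r in ordered]
    effects = [r.effect.effect for r in ordered]
    colors = ["#1f77b4" if not r.is_optimal_state else "#2ca02c" for r in ordered]
    y = range(len(ordered))[::-1]
    left = current_pred if current_pred is not None else 0.0
    ax.barh(list(y), effects, left=left, color=colors)
    ax.set_yticks(list(y))
    ax.set_yticklabels(labels, fontsize=8)
    if current_pred is not None:
        ax.axvline(current_pred, linestyle=":", color="black")
        ax.set_xlabel("Predicted SRH (1 poor .. 4 excellent)")
    else:
        ax.set_xlabel("Predicted SRH change relative to current state")
    ax.set_title("Predicted effect of reaching each goal")
    fig.tight_layout()
    return fig, report
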
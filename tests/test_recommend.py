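"""Goal recommendation: improvable factors, optima, ranking, rendering."""

import matplotlib

matplotlib.use("Agg")

import pytest

from srhadvisor.model import effect_between
from srhadvisor.profiles import UserProfile
from srhadvisor.recommend import (
    CATEGORIES,
    GoalCatalogEntry,
    build_recommendations,
    default_catalog,
    find_improvable_factors,
    joint_effect,
    optimal_state,
    render_report,
)


@pytest.fixture
def optimal_profile(reference):
    return reference.replace(
        hscl=1.0, pa_frequency="ge4_per_week", pa_intensity="hard", bmi_category="normal"
    )


@pytest.fixture
def distressed_woman():
    """Young woman with severe distress, little exercise, BMI 27."""
    return UserProfile(
        age=32, sex="female", education="university", lives_with_spouse=True,
        friend_support=True, hii=0.0, hscl=2.8, bmi_category="overweight",
        pa_frequency="lt1_per_week", pa_intensity="moderate",
        smoker=False, hba1c_high=False,
    )


class TestImprovableFactors:
    def test_fully_optimal_profile_empty(self, optimal_profile):
        assert find_improvable_factors(optimal_profile) == set()

    def test_smoker_only(self, optimal_profile):
        assert find_improvable_factors(optimal_profile.replace(smoker=True)) == {"smoking"}

    def test_distress_and_inactivity(self, optimal_profile):
        p = optimal_profile.replace(
            hscl=2.4, pa_frequency="lt1_per_week", pa_intensity="mild"
        )
        assert find_improvable_factors(p) == {"mental_health", "physical_activity"}


class TestOptimalState:
    def test_pa_at_age_40_is_hard_ge4(self, reference):
        assert optimal_state(reference, "physical_activity") == {
            "pa_frequency": "ge4_per_week", "pa_intensity": "hard",
        }

    def test_pa_at_age_70_switches_to_hard_23(self, reference):
        # the age>65 interaction (-0.24) makes hard 2-3/week the optimum
        assert optimal_state(reference.replace(age=70), "physical_activity") == {
            "pa_frequency": "2_3_per_week", "pa_intensity": "hard",
        }

    def test_bmi_optimum_is_normal(self, reference):
        assert optimal_state(reference, "weight") == {"bmi_category": "normal"}
        assert optimal_state(reference.replace(age=70), "weight") == {"bmi_category": "normal"}

    def test_hscl_optimum_is_floor(self, reference):
        assert optimal_state(reference.replace(hscl=3.0), "mental_health") == {"hscl": 1.0}


class TestBuildRecommendations:
    def test_priority_order_mental_then_pa_then_weight(self, distressed_woman):
        recs = build_recommendations(distressed_woman)
        order = []
        for r in sorted(recs, key=lambda r: r.category_rank):
            if r.goal.category not in order:
                order.append(r.goal.category)
        assert order == ["mental_health", "physical_activity", "weight"]

    def test_optimal_goal_always_present_per_category(self, distressed_woman):
        recs = build_recommendations(distressed_woman)
        for cat in {r.goal.category for r in recs}:
            cat_recs = [r for r in recs if r.goal.category == cat]
            assert sum(r.is_optimal_state for r in cat_recs) == 1
            assert max(cat_recs, key=lambda r: r.effect.effect).is_optimal_state

    def test_already_optimal_returns_empty(self, optimal_profile):
        assert build_recommendations(optimal_profile) == []

    def test_every_effect_matches_independent_recomputation(self, distressed_woman, coeffs):
        for r in build_recommendations(distressed_woman):
            target = distressed_woman.replace(**r.goal.state_override)
            assert r.effect.effect == pytest.approx(
                effect_between(distressed_woman, target, coeffs).effect
            )

    def test_category_rank_nonincreasing_in_optimal_effect(self, distressed_woman, coeffs):
        recs = build_recommendations(distressed_woman)
        optima = {r.category_rank: r.effect.effect for r in recs if r.is_optimal_state}
        ranks = sorted(optima)
        assert all(optima[a] >= optima[b] for a, b in zip(ranks, ranks[1:]))

    def test_tied_categories_follow_fixed_enumeration(self, optimal_profile):
        # smoking and blood sugar: if both effects were tied they keep
        # catalog-enumeration order; construct the tie via equal coefficients
        from srhadvisor.model import default_coefficients, Coefficient

        table = default_coefficients()
        table.coefficients["hba1c_high"] = table.coefficients["smoker"]
        p = optimal_profile.replace(smoker=True, hba1c_high=True)
        recs = build_recommendations(p, coeffs=table)
        by_rank = sorted(recs, key=lambda r: r.category_rank)
        cats = [r.goal.category for r in by_rank]
        assert cats == ["smoking", "blood_sugar"]
        assert CATEGORIES.index("smoking") < CATEGORIES.index("blood_sugar")

    def test_dominated_intermediate_goal_does_not_change_ranking(self, distressed_woman):
        base = build_recommendations(distressed_woman)
        extra = default_catalog() + [
            GoalCatalogEntry("physical_activity", "tiny nudge",
                             {"pa_frequency": "1_per_week", "pa_intensity": "mild"})
        ]
        with_extra = build_recommendations(distressed_woman, catalog=extra)
        rank = lambda recs: {r.goal.category: r.category_rank for r in recs}
        assert rank(base) == rank(with_extra)

    def test_negative_effect_goals_filtered(self, reference):
        # moving a moderate 2-3/wk exerciser to mild 2-3/wk would be harmful
        harmful = [
            GoalCatalogEntry("physical_activity", "downgrade",
                             {"pa_frequency": "2_3_per_week", "pa_intensity": "mild"})
        ]
        p = reference.replace(pa_frequency="1_per_week", pa_intensity="moderate")
        recs = build_recommendations(p, catalog=harmful)
        assert all(r.effect.effect > 0 for r in recs)
        assert all(r.goal.label != "downgrade" for r in recs)


class TestJointGoals:
    def test_joint_equals_sum_without_interactions(self, distressed_woman, coeffs):
        single = (
            joint_effect(distressed_woman, {"hscl": 1.0}, coeffs).effect
            + joint_effect(distressed_woman, {"bmi_category": "normal"}, coeffs).effect
        )
        joint = joint_effect(
            distressed_woman, {"hscl": 1.0, "bmi_category": "normal"}, coeffs
        ).effect
        assert joint == pytest.approx(single)


class TestRenderReport:
    def test_empty_recommendations_congratulate(self):
        fig, report = render_report([])
        assert report["status"] == "already_optimal"
        assert report["goals"] == []

    def test_report_mirrors_recommendations(self, distressed_woman):
        recs = build_recommendations(distressed_woman)
        fig, report = render_report(recs)
        assert report["status"] == "goals"
        assert len(report["goals"]) == len(recs)
        assert report["scale"].startswith("change relative")
        cats = [g["category"] for g in report["goals"] if g["is_optimal_state"]]
        assert cats[0] == "mental_health"

    def test_anchor_switches_to_absolute_scale(self, distressed_woman):
        recs = build_recommendations(distressed_woman)
        fig, report = render_report(recs, anchor=4.89, profile=distressed_woman)
        assert report["scale"] == "absolute SRH"
        assert report["anchor"] is not None

    def test_caveat_always_included(self, distressed_woman):
        _, report = render_report(build_recommendations(distressed_woman))
        assert "causal" in report["caveat"]


def test_goal_entries_cannot_touch_nonmodifiable_fields():
    with pytest.raises(ValueError, match="non-modifiable"):
        GoalCatalogEntry("weight", "cheat", {"age": 20})
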
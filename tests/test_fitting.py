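"""Mixed-model pipeline: fitting, selection, diagnostics, metrics, strata."""

import numpy as np
import pandas as pd
import pytest

from srhadvisor.fitting import (
    FitError,
    FitResult,
    discretized_normal_gof,
    equidistance_diagnostic,
    fit_mixed_model,
    prediction_metrics,
    select_power_terms,
    sensitivity_sequence,
    stratified_rates,
    test_interaction as interaction_test,  # alias: keep pytest from collecting it
    umf_counts,
    umf_strata,
)
from srhadvisor.model import BASE_TERM_SPEC, DEFAULT_TERM_SPEC, ModelTermSpec, TERM_GROUPS
from srhadvisor.synth import default_spec, generate_cohort


class TestFitMixedModel:
    def test_recovers_large_coefficients_within_3_se(self, small_fit, coeffs):
        for name in ("hscl", "male", "bmi_obese", "smoker", "edu_primary"):
            est = small_fit.coefficients.coefficients[name]
            se = est.se
            assert abs(est.estimate - coeffs.estimate(name)) < 3 * se, name

    def test_zero_random_intercept_truth_recovered_near_zero(self):
        # full two-wave overlap so the variance components are well identified
        spec = default_spec(
            n_participants=1500, random_intercept_sd=0.0, p_second_wave=1.0
        )
        fit = fit_mixed_model(generate_cohort(spec, seed=5))
        assert fit.random_intercept_sd < 0.1

    def test_single_wave_cohort_fits_with_warning(self):
        spec = default_spec(n_participants=800, p_second_wave=0.0)
        cohort = generate_cohort(spec, seed=3)
        with pytest.warns(UserWarning, match="weakly identified"):
            fit = fit_mixed_model(cohort)
        assert fit.n_obs == 800

    def test_collinear_design_raises_naming_terms(self, small_cohort):
        # binarised HII makes hii and hii^2 identical columns
        binary = small_cohort.copy()
        binary["hii"] = (binary["hii"] > 0).astype(float)
        spec = ModelTermSpec(TERM_GROUPS["hii"] + TERM_GROUPS["hscl"])
        with pytest.raises(FitError, match="collinear"):
            fit_mixed_model(binary, spec)

    def test_constant_srh_rejected(self, small_cohort):
        degenerate = small_cohort.copy()
        degenerate["srh"] = 3
        with pytest.raises(FitError, match="distinct"):
            fit_mixed_model(degenerate)

    def test_covariance_positive_semidefinite(self, small_fit):
        eigs = np.linalg.eigvalsh(small_fit.coefficients.covariance.to_numpy())
        assert eigs.min() > -1e-10

    def test_roundtrip_through_dict(self, small_fit, small_cohort):
        restored = FitResult.from_dict(small_fit.to_dict())
        assert restored.random_intercept_sd == pytest.approx(small_fit.random_intercept_sd)
        np.testing.assert_allclose(
            restored.predict_fixed(small_cohort.head(50)),
            small_fit.predict_fixed(small_cohort.head(50)),
        )


class TestPowerTermSelection:
    # The four uncentered powers are strongly collinear on [1, 4], so the
    # Wald tests need a clear signal; selection carries the usual ~5% chance
    # of a spurious power, hence the majority vote over replicates.

    @staticmethod
    def _planted_cohort(signal, seed, n=10000, noise=0.2):
        # continuous outcome: discretisation would itself add curvature
        rng = np.random.default_rng(seed)
        hscl = rng.uniform(1, 4, n)
        latent = 2.5 + signal(hscl) + rng.normal(0, noise, n)
        return pd.DataFrame(
            {
                "participant_id": [f"P{i}" for i in range(n)],
                "hscl": hscl,
                "srh": latent,
            }
        )

    def test_linear_signal_keeps_only_power_one(self):
        picks = [
            select_power_terms(self._planted_cohort(lambda x: -1.5 * x, seed=s), "hscl")
            for s in range(5)
        ]
        assert all(1 in p for p in picks)
        assert sum(p == {1} for p in picks) >= 4

    def test_quadratic_signal_recovers_planted_powers(self):
        picks = [
            select_power_terms(
                self._planted_cohort(lambda x: 0.8 * (x - 2.5) ** 2, seed=s), "hscl"
            )
            for s in range(5)
        ]
        assert all(2 in p for p in picks)
        assert sum({1, 2} <= p for p in picks) >= 4

    def test_unknown_variable_rejected(self, small_cohort):
        with pytest.raises(FitError, match="age/hii/hscl"):
            select_power_terms(small_cohort, "bmi")


class TestInteractionTests:
    def test_planted_age_interaction_recovered(self):
        spec = default_spec(n_participants=4000)
        cohort = generate_cohort(spec, seed=17)
        result = interaction_test(cohort, "age_gt65", "bmi")
        est = result.loc["age_gt65:bmi_obese"]
        # generator truth: +0.11
        se = (est.ci_high - est.ci_low) / 3.92
        assert abs(est.estimate - 0.11) < 3 * se

    def test_absent_sex_interaction_not_significant(self):
        # truth has no sex-by-smoking style interactions with BMI
        cohort = generate_cohort(default_spec(n_participants=3000), seed=23)
        result = interaction_test(cohort, "male", "bmi")
        assert (~result["significant"]).sum() >= len(result) - 1

    def test_constant_modifier_rejected(self, small_cohort):
        young = small_cohort[small_cohort["age"] < 60]
        with pytest.raises(FitError, match="constant"):
            interaction_test(young, "age_gt65", "bmi")


class TestEquidistanceDiagnostic:
    def test_affine_predictions_give_exact_zero_deviation(self, small_fit, small_cohort):
        cohort = small_cohort.copy()
        fake = small_fit
        # force predictions to an affine function of actual SRH
        pred = 0.5 + 0.7 * cohort["srh"].to_numpy(float)

        class _Affine:
            random_intercept_sd = fake.random_intercept_sd
            residual_sd = fake.residual_sd

            @staticmethod
            def predict_fixed(df):
                return 0.5 + 0.7 * df["srh"].to_numpy(float)

        table = equidistance_diagnostic(_Affine, cohort)
        np.testing.assert_allclose(table["deviation"].to_numpy(), 0.0, atol=1e-10)

    def test_correct_specification_deviation_small_vs_sd(self, small_fit, small_cohort):
        table = equidistance_diagnostic(small_fit, small_cohort)
        ok = table.dropna()
        assert (ok["deviation"].abs() < ok["sd_predicted"]).all()

    def test_compressed_top_category_detected(self):
        # squash the latent scale above 3: top level loses separation
        spec = default_spec(n_participants=3000)
        cohort = generate_cohort(spec, seed=31)
        squashed = cohort.copy()
        high = squashed["srh"] == 4
        squashed.loc[high & (np.arange(len(squashed)) % 2 == 0), "srh"] = 3
        fit = fit_mixed_model(squashed)
        table = equidistance_diagnostic(fit, squashed)
        # deviations no longer negligible relative to the affine case
        assert table["deviation"].abs().max() > 1e-3

    def test_absent_level_marked_missing(self, small_fit, small_cohort):
        trimmed = small_cohort[small_cohort["srh"] != 1]
        table = equidistance_diagnostic(small_fit, trimmed)
        assert np.isnan(table.loc[1, "deviation"])
        assert table.loc[1, "n"] == 0


class TestDiscretizedNormalGof:
    def test_discretised_normal_sample_matches_within_002(self):
        rng = np.random.default_rng(0)
        latent = rng.normal(2.8, 0.75, 10000)
        srh = np.clip(np.rint(latent), 1, 4).astype(int)
        table = discretized_normal_gof(srh)
        assert (np.abs(table["theoretical"] - table["empirical"]) < 0.02).all()

    def test_zero_variance_rejected(self):
        with pytest.raises(FitError, match="variance"):
            discretized_normal_gof([3] * 50)

    def test_symmetric_sample_symmetric_masses(self):
        srh = np.array([1] * 100 + [2] * 400 + [3] * 400 + [4] * 100)
        table = discretized_normal_gof(srh)
        assert table.loc[2, "theoretical"] == pytest.approx(table.loc[3, "theoretical"])
        assert table.loc[1, "theoretical"] == pytest.approx(table.loc[4, "theoretical"])


class TestPredictionMetrics:
    @staticmethod
    def _holdout(seed=91, n=400):
        spec = default_spec(n_participants=n, p_second_wave=0.0)
        df = generate_cohort(spec, seed=seed)
        df["participant_id"] = "H" + df["participant_id"]
        return df

    def test_perfect_predictions(self, small_fit):
        holdout = self._holdout()

        class _Perfect:
            random_intercept_sd = 0.0
            residual_sd = 0.0
            participant_ids = small_fit.participant_ids

            @staticmethod
            def predict_fixed(df):
                return df["srh"].to_numpy(float)

        report = prediction_metrics(_Perfect, holdout)
        assert report.accuracy == 1.0
        assert report.auc_poor == 1.0 and report.auc_excellent == 1.0
        assert report.marginal_r2 == pytest.approx(1.0)

    def test_constant_predictions_flagged(self, small_fit):
        holdout = self._holdout()

        class _Constant:
            random_intercept_sd = 0.3
            residual_sd = 0.5
            participant_ids = small_fit.participant_ids

            @staticmethod
            def predict_fixed(df):
                return np.full(len(df), 2.8)

        report = prediction_metrics(_Constant, holdout)
        assert report.auc_poor == 0.5 and report.auc_excellent == 0.5
        assert np.isnan(report.correlation)
        assert report.notes

    def test_overlapping_participants_rejected(self, small_fit, small_cohort):
        with pytest.raises(FitError, match="training"):
            prediction_metrics(small_fit, small_cohort.head(20))

    def test_synthetic_metrics_in_sane_ranges(self, small_fit):
        report = prediction_metrics(small_fit, self._holdout())
        assert 0.3 < report.accuracy < 0.9
        assert 0.5 < report.auc_excellent < 1.0
        assert 0.0 < report.marginal_r2 < 0.5


class TestSensitivitySequence:
    CONTRAST = {"pa_hard_ge4": 1.0, "pa_mild_lt1": -1.0}
    BASE = ("age", "demographics", "smoking", "pa")

    def test_pa_effect_stable_when_additions_independent(self, small_cohort):
        # generator draws covariates independently, so adjusting for BMI/HII/
        # HSCL must not move the PA contrast materially
        table = sensitivity_sequence(
            small_cohort, self.BASE, ("bmi", "hii", "hscl"), self.CONTRAST
        )
        effects = table["effect"].to_numpy()
        assert np.ptp(effects) < 0.15
        assert len(table) == 4

    def test_planted_mediator_shrinks_effect(self):
        rng = np.random.default_rng(12)
        n = 4000
        activity = rng.choice(["sedentary", "reference", "active"], n, p=[0.4, 0.2, 0.4])
        active = activity == "active"
        # mediator: active people mostly normal BMI; BMI carries the signal
        r = rng.random(n)
        p_normal = np.where(active, 0.7, 0.15)
        bmi = np.select(
            [r < p_normal, r < p_normal + 0.15], ["normal", "overweight"], default="obese"
        )
        latent = 2.5 + 0.25 * (bmi == "normal") + rng.normal(0, 0.4, n)
        cohort = pd.DataFrame(
            {
                "participant_id": [f"P{i}" for i in range(n)],
                "wave": 6,
                "age": 50.0,
                "sex": "female",
                "education": "university",
                "lives_with_spouse": True,
                "friend_support": True,
                "hii": 0.0,
                "hscl": rng.uniform(1, 1.5, n),
                "bmi_category": bmi,
                "pa_frequency": np.select(
                    [activity == "active", activity == "reference"],
                    ["ge4_per_week", "2_3_per_week"],
                    default="lt1_per_week",
                ),
                "pa_intensity": "moderate",
                "smoker": False,
                "hba1c_high": False,
                "srh": np.clip(np.rint(latent), 1, 4).astype(int),
            }
        )
        contrast = {"pa_moderate_ge4": 1.0, "pa_moderate_lt1": -1.0}
        with pytest.warns(UserWarning):  # single wave, absent categories
            table = sensitivity_sequence(cohort, ("pa",), ("bmi",), contrast)
        assert table["effect"].iloc[1] < table["effect"].iloc[0] - 0.05

    def test_empty_additions_single_model(self, small_cohort):
        table = sensitivity_sequence(small_cohort, self.BASE, (), self.CONTRAST)
        assert list(table.index) == ["M0"]

    def test_overlapping_groups_rejected(self, small_cohort):
        with pytest.raises(FitError, match="disjoint"):
            sensitivity_sequence(small_cohort, self.BASE, ("pa",), self.CONTRAST)


class TestStratifiedRates:
    def test_closed_form_normal_approximation(self):
        df = pd.DataFrame({"hit": [True] * 40 + [False] * 60})
        table = stratified_rates(
            df, {"all": np.ones(100, bool)}, outcome=lambda d: d["hit"].to_numpy()
        )
        row = table.loc["all"]
        assert row["rate_pct"] == pytest.approx(40.0)
        assert row["ci_low_pct"] == pytest.approx(30.4, abs=0.1)
        assert row["ci_high_pct"] == pytest.approx(49.6, abs=0.1)

    def test_empty_stratum_undefined(self):
        df = pd.DataFrame({"hit": [True, False]})
        table = stratified_rates(
            df,
            {"none": np.zeros(2, bool), "all": np.ones(2, bool)},
            outcome=lambda d: d["hit"].to_numpy(),
        )
        assert np.isnan(table.loc["none", "rate_pct"])
        assert table.loc["none", "n"] == 0

    def test_always_true_predicate_is_100_pct(self):
        df = pd.DataFrame({"x": range(10)})
        table = stratified_rates(
            df, {"all": np.ones(10, bool)}, outcome=lambda d: np.ones(len(d), bool)
        )
        assert table.loc["all", "rate_pct"] == 100.0

    def test_wilson_interval_stays_inside_unit_range(self):
        df = pd.DataFrame({"hit": [True] * 2 + [False] * 1})
        table = stratified_rates(
            df, {"all": np.ones(3, bool)}, outcome=lambda d: d["hit"].to_numpy(),
            method="wilson",
        )
        assert 0 <= table.loc["all", "ci_low_pct"] <= table.loc["all", "ci_high_pct"] <= 100

    def test_umf_strata_partition_cohort(self, small_cohort):
        strata = umf_strata(small_cohort)
        total = sum(int(m.sum()) for m in strata.values())
        assert total == len(small_cohort)
        counts = umf_counts(small_cohort)
        assert ((counts >= 0) & (counts <= 5)).all()
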
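import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import bovitherm as bt
from bovitherm.thermal import DEFAULT_SOURCE_GROUPS
from conftest import seeds_from


class TestUnitConversion:
    @pytest.mark.parametrize("f, c", [(32, 0), (212, 100), (-40, -40)])
    def test_fahrenheit_to_celsius(self, f, c):
        assert bt.fahrenheit_to_celsius(f) == pytest.approx(c)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            bt.fahrenheit_to_celsius(np.nan)


class TestDeltaT:
    def test_study_mean_difference(self):
        assert bt.compute_delta_t(32.4, 4.4) == pytest.approx(28.0)

    def test_zero_and_sign(self):
        assert bt.compute_delta_t(5.0, 5.0) == 0.0
        assert bt.compute_delta_t(0.0, 2.2) == pytest.approx(-2.2)

    @given(
        a=st.floats(-50, 100, allow_nan=False),
        b=st.floats(-50, 100, allow_nan=False),
    )
    def test_antisymmetric(self, a, b):
        assert bt.compute_delta_t(a, b) == pytest.approx(-bt.compute_delta_t(b, a))


class TestAssemble:
    def test_complete_join_preserves_rows(self):
        obs = pd.DataFrame({"date_index": [0, 1, 1], "temp_cow": [30.0, 31.0, 29.0]})
        cov = pd.DataFrame({"date_index": [0, 1, 2], "rad_lw": [5.0, 6.0, 7.0]})
        merged = bt.assemble_dataset(obs, cov)
        assert len(merged) == 3
        assert set(merged.columns) == {"date_index", "temp_cow", "rad_lw"}

    def test_missing_date_named_in_error(self):
        obs = pd.DataFrame({"date_index": [0, 5]})
        cov = pd.DataFrame({"date_index": [0], "rad_lw": [5.0]})
        with pytest.raises(ValueError, match="5"):
            bt.assemble_dataset(obs, cov)


class TestPruning:
    def test_duplicated_column_removes_exactly_one(self):
        rng = np.random.default_rng(0)
        humidity = rng.uniform(10, 80, 50)
        df = pd.DataFrame({"humidity": humidity, "wind_speed": humidity})
        retained, report = bt.prune_correlated(df)
        assert retained == ["wind_speed"]
        assert len(report) == 1 and report.loc[0, "r"] == pytest.approx(1.0)

    def test_uncorrelated_variables_untouched(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {"humidity": rng.normal(size=200), "wind_speed": rng.normal(size=200)}
        )
        retained, report = bt.prune_correlated(df)
        assert retained == ["humidity", "wind_speed"] and report.empty

    def test_synthetic_default_pruning_outcomes(self, model_mode_data):
        merged, _ = model_mode_data
        retained, report = bt.prune_correlated(merged)
        assert set(report["dropped"]) == {"temp_earth", "humidity", "vpd"}
        assert "temp_earth" not in retained and "rad_lw" in retained

    def test_idempotent(self, model_mode_data):
        merged, _ = model_mode_data
        retained, _ = bt.prune_correlated(merged)
        retained2, report2 = bt.prune_correlated(merged[retained])
        assert retained2 == retained and report2.empty

    def test_cross_source_pairs_not_compared(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=100)
        # perfectly correlated, but in different source groups
        df = pd.DataFrame({"temp_amb": x, "rad_lw": x})
        retained, report = bt.prune_correlated(df)
        assert retained == ["temp_amb", "rad_lw"] and report.empty

    def test_ambiguous_pair_demands_rule(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=100)
        df = pd.DataFrame({"rad_lw": x, "rad_sw": x + rng.normal(0, 0.1, 100)})
        with pytest.raises(ValueError, match="rule"):
            bt.prune_correlated(df)


class TestFitOLS:
    def test_identity_line(self):
        data = pd.DataFrame({"x": [0.0, 1.0, 2.0, 3.0, 4.0], "y": [0.0, 1.0, 2.0, 3.0, 4.0]})
        fit = bt.fit_ols(data, "y", ["x"])
        assert fit.params["x"] == pytest.approx(1.0)
        assert fit.params["intercept"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_normal_equations(self):
        # y = {1, 2, 4} on x = {0, 1, 2}: slope 3/2, intercept 7/3 - 3/2 = 5/6
        # (duplicating the points leaves the normal equations' solution alone
        #  while giving AICc its required residual degrees of freedom)
        sub = pd.DataFrame({"x": [0.0, 1.0, 2.0], "y": [1.0, 2.0, 4.0]})
        fit = bt.fit_ols(pd.concat([sub, sub], ignore_index=True), "y", ["x"])
        assert fit.params["x"] == pytest.approx(1.5)
        assert fit.params["intercept"] == pytest.approx(5 / 6)

    def test_k_convention(self, model_mode_data):
        merged, _ = model_mode_data
        null = bt.fit_ols(merged, "temp_cow", [])
        one = bt.fit_ols(merged, "temp_cow", ["temp_amb"])
        assert (null.k, one.k) == (2, 3)

    def test_collinear_design_rejected(self, model_mode_data):
        merged, _ = model_mode_data
        merged = merged.assign(temp_amb_copy=merged["temp_amb"])
        with pytest.raises(ValueError, match="rank"):
            bt.fit_ols(merged, "temp_cow", ["temp_amb", "temp_amb_copy"])

    def test_aicc_agrees_with_rss_closed_form(self, model_mode_data):
        # Gaussian log-likelihood route vs the n*ln(RSS/n) closed form
        merged, _ = model_mode_data
        fit = bt.fit_ols(merged, "temp_cow", ["temp_amb", "ktclear"])
        n = fit.n
        loglik_closed = -0.5 * n * (np.log(2 * np.pi * fit.ssr / n) + 1)
        assert fit.loglik == pytest.approx(loglik_closed, abs=1e-8)
        assert fit.aicc == pytest.approx(bt.aicc(loglik_closed, fit.k, n), abs=1e-6)


class TestAICc:
    def test_hand_value(self):
        assert bt.aicc(-10.0, 3, 10) == pytest.approx(30.0)  # 20 + 6 + 24/6

    def test_approaches_aic_for_large_n(self):
        assert bt.aicc(-10.0, 3, 10**7) == pytest.approx(26.0, abs=1e-5)

    def test_rejects_small_n(self):
        with pytest.raises(ValueError):
            bt.aicc(-10.0, 3, 4)


class TestAkaikeWeights:
    def test_two_equal_models(self):
        delta, w = bt.akaike_weights([100.0, 100.0])
        assert delta.tolist() == [0.0, 0.0]
        assert w.tolist() == [0.5, 0.5]

    def test_shift_invariance(self):
        a = [4988.16, 4995.78, 4998.08, 5023.93]
        _, w1 = bt.akaike_weights(a)
        _, w2 = bt.akaike_weights([x + 123.4 for x in a])
        assert np.allclose(w1, w2)
        assert w1.sum() == pytest.approx(1.0)

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            bt.akaike_weights([])


class TestCIScreen:
    def test_study_scale_confidence_intervals(self, model_mode_data):
        merged, _ = model_mode_data
        fit = bt.fit_ols(merged, "temp_cow", ["temp_amb", "ktclear", "albedo"])
        flags = bt.ci_screen(fit)
        # all three generating effects are strong at this n and noise level
        assert flags == {"temp_amb": True, "ktclear": True, "albedo": True}

    def test_straddling_zero_is_uninformative(self):
        rng = np.random.default_rng(12)
        data = pd.DataFrame({"x": rng.normal(size=100), "y": rng.normal(size=100)})
        fit = bt.fit_ols(data, "y", ["x"])
        assert bt.ci_screen(fit) == {"x": False}


class TestStagedSelection:
    def test_ledger_invariants(self, model_mode_data):
        merged, _ = model_mode_data
        report = bt.staged_selection(merged, "temp_cow")
        for step in report.steps:
            assert step.table["delta_aicc"].iloc[0] == 0.0
            assert step.table["weight"].sum() == pytest.approx(1.0)
            assert "null" in step.table["model"].values
        assert report.weather_term == "temp_amb"
        assert report.radiation_term == "ktclear"
        assert report.final_terms == ("temp_amb", "ktclear", "albedo")

    def test_delta_t_response_includes_temp_cow_attribute(self, model_mode_data):
        merged, _ = model_mode_data
        report = bt.staged_selection(merged, "delta_t")
        step3_models = report.steps[2].table["model"].tolist()
        assert any("temp_cow" in m for m in step3_models)

    def test_pure_noise_keeps_null_in_top_set(self):
        seeds = seeds_from(400, 20)
        null_in_top = 0
        for seed in seeds:
            rng = np.random.default_rng(seed)
            obs, cov, _ = bt.generate_thermal_observations(
                bt.ThermalGenParams(n=200, seed=seed)
            )
            merged = bt.assemble_dataset(obs, cov)
            merged["noise_response"] = rng.normal(size=len(merged))
            report = bt.staged_selection(merged, "noise_response", animal_terms=("albedo",))
            step = report.steps[0].table
            if step.loc[step["model"] == "null", "in_top_set"].iloc[0]:
                null_in_top += 1
        assert null_in_top > len(seeds) / 2

    def test_selector_estimator_prunes_then_selects(self, model_mode_data):
        merged, _ = model_mode_data
        selector = bt.StagedAICcSelector(response="temp_cow").fit(merged)
        assert "temp_earth" in set(selector.pruning_report_["dropped"])
        assert selector.final_terms_ == ("temp_amb", "ktclear", "albedo")
        assert all(selector.ci_flags_.values())
        params = selector.get_params()
        assert params["response"] == "temp_cow"
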
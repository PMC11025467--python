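"""Regression engine, drought-effect residuals and species comparison."""

import numpy as np
import pandas as pd
import pytest

from stemflux import (
    DegenerateFitError,
    InsufficientDataError,
    RegressionResult,
    ValidationError,
    compare_species_growth_fit,
    drought_effect,
    fit_exponential,
    fit_linear,
    pearson_correlation,
)
from stemflux.stats import campaign_plot_means, mixed_model_table, predict_linear

from conftest import ols_normal_equations


class TestFitLinear:
    def test_perfect_line(self):
        fit = fit_linear([1, 2, 3], [1, 2, 3])
        assert fit.slope == pytest.approx(1.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_flat_response_flagged(self):
        fit = fit_linear([1, 2, 3], [2, 2, 2])
        assert fit.slope == pytest.approx(0.0, abs=1e-12)
        assert fit.intercept == pytest.approx(2.0, abs=1e-12)
        assert fit.r_squared == 0.0
        assert fit.flag == "flat_response"

    def test_zero_x_variance_rejected(self):
        with pytest.raises(DegenerateFitError):
            fit_linear([2, 2, 2], [1, 2, 3])

    def test_temperature_response_coefficient_recovery(self, rng):
        x = rng.uniform(12, 30, size=20)
        y = 23.3 * x - 271.5 + rng.normal(0, 20, size=20)
        fit = fit_linear(x, y)
        assert 20 <= fit.slope <= 27

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(3, 40))
            x = rng.normal(0, 3, size=n)
            y = rng.normal(0, 5, size=n)
            if np.ptp(x) == 0:
                continue
            fit = fit_linear(x, y)
            beta, se = ols_normal_equations(np.column_stack([np.ones(n), x]), y)
            assert fit.intercept == pytest.approx(beta[0], abs=1e-10)
            assert fit.slope == pytest.approx(beta[1], abs=1e-10)
            if n > 2:
                assert fit.intercept_se == pytest.approx(se[0], rel=1e-9)
                assert fit.slope_se == pytest.approx(se[1], rel=1e-9)


class TestFitExponential:
    def test_exact_exponential(self):
        x = np.linspace(0, 10, 12)
        y = 2.0 * np.exp(0.1 * x)
        fit = fit_exponential(x, y)
        assert fit.rate == pytest.approx(0.1, abs=1e-12)
        assert fit.scale == pytest.approx(2.0, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_linear_data_favours_linear_model(self):
        x = np.arange(1.0, 11.0)
        y = x + 10.0
        lin = fit_linear(x, y)
        exp = fit_exponential(x, y)
        assert exp.r_squared < lin.r_squared
        assert lin.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_y_rejected(self):
        with pytest.raises(ValidationError):
            fit_exponential([1, 2, 3], [1.0, -0.5, 2.0])

    def test_single_point_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_exponential([1.0], [2.0])


class TestDroughtEffect:
    FIT = RegressionResult(slope=1.0, slope_se=0.0, intercept=0.0,
                           intercept_se=0.0, r_squared=1.0, n=10,
                           residual_se=0.0)

    def _points(self, rs_values, temp=20.0):
        return pd.DataFrame(
            {"date": "2017-07-04",
             "plot_id": [f"P{i}" for i in range(len(rs_values))],
             "tstem_c": temp, "rs": rs_values, "species": "oak"}
        )

    def test_on_the_line_gives_zero_residual_and_100_percent(self):
        (eff,) = drought_effect(self.FIT, self._points([20.0]))
        assert eff.residual_mean == pytest.approx(0.0)
        assert eff.percent_mean == pytest.approx(100.0)

    def test_half_expected(self):
        (eff,) = drought_effect(self.FIT, self._points([10.0]))
        assert eff.residual_mean == pytest.approx(-10.0)
        assert eff.percent_mean == pytest.approx(50.0)

    def test_residual_percent_consistency(self, rng):
        rs = rng.uniform(5, 40, size=4)
        (eff,) = drought_effect(self.FIT, self._points(list(rs)))
        predicted = 20.0
        assert eff.residual_mean == pytest.approx(
            predicted * (eff.percent_mean / 100.0 - 1.0), rel=1e-12
        )

    def test_sd_over_plots(self):
        (eff,) = drought_effect(self.FIT, self._points([10.0, 20.0, 30.0, 40.0]))
        assert eff.n_plots == 4
        assert eff.residual_sd == pytest.approx(np.std([-10, 0, 10, 20], ddof=1))

    def test_nonpositive_prediction_excluded_with_warning(self):
        fit = RegressionResult(slope=23.3, slope_se=0, intercept=-271.5,
                               intercept_se=0, r_squared=0.9, n=24,
                               residual_se=0)
        pts = pd.DataFrame(
            {"date": "2017-06-07", "plot_id": ["a", "b"],
             "tstem_c": [10.0, 20.0], "rs": [15.0, 100.0]}  # 10 degC -> pred < 0
        )
        with pytest.warns(UserWarning, match="non-positive"):
            (eff,) = drought_effect(fit, pts)
        assert eff.n_excluded == 1
        assert eff.percent_mean == pytest.approx(
            100.0 * 100.0 / predict_linear(fit, 20.0)
        )


class TestSpeciesComparison:
    def test_identical_species_have_zero_differences(self):
        x = np.arange(10.0)
        df = pd.DataFrame(
            {"species": ["oak"] * 10 + ["hornbeam"] * 10,
             "increment_rate": np.concatenate([x, x]),
             "r15": np.concatenate([2 * x + 5, 2 * x + 5])}
        )
        fit = compare_species_growth_fit(df)
        assert fit.intercept_diff == pytest.approx(0.0, abs=1e-9)
        assert fit.slope_diff == pytest.approx(0.0, abs=1e-9)

    def test_noise_free_contrast_recovered_exactly(self):
        x = np.arange(8.0)
        df = pd.DataFrame(
            {"species": ["A"] * 8 + ["B"] * 8,
             "increment_rate": np.concatenate([x, x]),
             "r15": np.concatenate([100 + x, 50 + 3 * x])}
        )
        fit = compare_species_growth_fit(df)
        assert fit.intercepts == pytest.approx({"A": 100.0, "B": 50.0}, abs=1e-9)
        assert fit.slopes == pytest.approx({"A": 1.0, "B": 3.0}, abs=1e-10)
        assert fit.intercept_diff == pytest.approx(-50.0, abs=1e-9)
        assert fit.slope_diff == pytest.approx(2.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        n = 14
        for _ in range(20):
            rate = rng.uniform(0, 100, size=2 * n)
            ind = np.repeat([0.0, 1.0], n)
            y = 80 + 20 * ind + 1.5 * rate + 0.8 * ind * rate + rng.normal(0, 10, 2 * n)
            df = pd.DataFrame(
                {"species": np.where(ind == 0, "oak", "hornbeam"),
                 "increment_rate": rate, "r15": y}
            )
            fit = compare_species_growth_fit(df)
            # baseline label is alphabetical: hornbeam first
            ind_oak = (df["species"] == "oak").to_numpy(float)
            X = np.column_stack([np.ones(2 * n), ind_oak, rate, ind_oak * rate])
            beta, se = ols_normal_equations(X, y)
            assert fit.intercepts["hornbeam"] == pytest.approx(beta[0], abs=1e-9)
            assert fit.intercept_diff == pytest.approx(beta[1], abs=1e-9)
            assert fit.slopes["hornbeam"] == pytest.approx(beta[2], abs=1e-10)
            assert fit.slope_diff == pytest.approx(beta[3], abs=1e-10)
            assert fit.slope_diff_se == pytest.approx(se[3], rel=1e-9)

    def test_ratio_at_rate(self):
        x = np.arange(6.0)
        df = pd.DataFrame(
            {"species": ["A"] * 6 + ["B"] * 6,
             "increment_rate": np.concatenate([x, x]),
             "r15": np.concatenate([100 + 3 * x, 100 + x])}
        )
        fit = compare_species_growth_fit(df)
        assert fit.ratio_at_rate("A", 0.0) == pytest.approx(100.0)
        assert fit.ratio_at_rate("A", 100.0) == pytest.approx(400.0)

    def test_single_species_fallback(self):
        df = pd.DataFrame(
            {"species": "oak", "increment_rate": np.arange(5.0),
             "r15": 2 * np.arange(5.0) + 1}
        )
        with pytest.warns(UserWarning, match="one species"):
            fit = compare_species_growth_fit(df)
        assert fit.flag == "single_species"
        assert np.isnan(fit.slope_diff)


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert pearson_correlation(x, 3 * x + 1)[0] == pytest.approx(1.0)
        assert pearson_correlation(x, -x)[0] == pytest.approx(-1.0)

    def test_independent_samples_near_zero(self, rng):
        x = rng.normal(size=1000)
        y = rng.normal(size=1000)
        r, p = pearson_correlation(x, y)
        assert abs(r) < 0.1

    def test_zero_variance_undefined(self):
        with pytest.warns(UserWarning, match="zero variance"):
            r, p = pearson_correlation([1, 1, 1], [1, 2, 3])
        assert np.isnan(r) and np.isnan(p)

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            pearson_correlation([1, 2], [3, 4])


def test_campaign_plot_means_aggregates_and_filters():
    fluxes = pd.DataFrame(
        {"species": "oak", "plot_id": "C-0", "date": "2016-06-07",
         "rs_volume": [10.0, 20.0, -5.0], "r15": [8.0, 16.0, -4.0],
         "tstem_c": [20.0, 21.0, 22.0],
         "quality_flag": ["ok", "ok", "negative_slope"]}
    )
    means = campaign_plot_means(fluxes)
    assert len(means) == 1
    assert means.loc[0, "rs_volume"] == pytest.approx(15.0)  # flagged row dropped


def test_mixed_model_table_decodes_treatments():
    fluxes = pd.DataFrame(
        {"sprout_id": ["a", "b", "c", "d"],
         "plot_id": ["C-0", "T-0", "C-r", "T-r"],
         "species": "oak", "date": "2016-06-07", "r15": 1.0}
    )
    out = mixed_model_table(fluxes)
    assert out["thinning"].tolist() == [0, 1, 0, 1]
    assert out["reduction"].tolist() == [0, 0, 1, 1]
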
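"""Day-of-week ratio effects: OLS exactness, bootstrap behavior, invariances."""

import numpy as np
import pandas as pd
import pytest

from searchrhythms import (
    DayOfWeekModel,
    SeriesSpec,
    bootstrap_effects,
    dow_percent_effects,
    fit_dow_model,
    generate_daily_series,
    sunday_contrast,
)
from searchrhythms.dayofweek import (
    EFFECT_DAYS,
    WEEKDAY_NAMES,
    DayOfWeekError,
    DowModelFit,
    _weekday_groups,
)


def _random_series(seed, n=70):
    rng = np.random.default_rng(seed)
    values = np.abs(50 + 10 * rng.normal(size=n))
    return pd.Series(values, index=pd.date_range("2016-03-01", periods=n))


def _weekday_mean_oracle(series):
    idx = pd.DatetimeIndex(series.index)
    values = np.asarray(series.values, dtype=float)
    return {name: values[idx.dayofweek == w].mean() for w, name in enumerate(WEEKDAY_NAMES)}


class TestFactorModel:
    def test_constant_series(self, dates_364):
        series = pd.Series(np.full(364, 100.0), index=dates_364)
        fit = fit_dow_model(series)
        assert fit.beta_intercept == pytest.approx(100.0, abs=1e-10)
        assert all(abs(b) < 1e-10 for b in fit.beta_day.values())

    def test_planted_sunday_step(self, flat_uplift_series):
        fit = fit_dow_model(flat_uplift_series)
        assert fit.beta_intercept == pytest.approx(100.0, abs=1e-10)
        assert fit.beta_day["Sunday"] == pytest.approx(10.0, abs=1e-10)
        for day in EFFECT_DAYS[:-1]:
            assert fit.beta_day[day] == pytest.approx(0.0, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_coefficients_equal_weekday_mean_differences(self, seed):
        series = _random_series(seed)
        fit = fit_dow_model(series)
        means = _weekday_mean_oracle(series)
        assert fit.beta_intercept == pytest.approx(means["Monday"], abs=1e-10)
        for day in EFFECT_DAYS:
            assert fit.beta_day[day] == pytest.approx(means[day] - means["Monday"], abs=1e-10)

    def test_residuals_orthogonal_to_design(self):
        series = _random_series(42)
        fit = fit_dow_model(series)
        idx = pd.DatetimeIndex(series.index)
        for w in range(7):
            assert abs(fit.residuals[idx.dayofweek == w].sum()) < 1e-8

    def test_missing_weekday_named_in_error(self):
        # a gappy index reaching the grouping helper directly
        dates = pd.date_range("2016-03-07", periods=40, freq="D")
        keep = dates.dayofweek != 4
        series = pd.Series(100.0, index=dates[keep])
        with pytest.raises(DayOfWeekError, match="Friday"):
            _weekday_groups(series)


class TestPercentEffects:
    @pytest.mark.parametrize(
        "intercept, day, beta, expected",
        [(100.0, "Sunday", 10.0, 10.0), (100.0, "Tuesday", 0.0, 0.0), (50.0, "Saturday", -5.0, -10.0)],
    )
    def test_ratio_formula(self, intercept, day, beta, expected):
        betas = {d: 0.0 for d in EFFECT_DAYS}
        betas[day] = beta
        fit = DowModelFit(beta_intercept=intercept, beta_day=betas, residuals=np.zeros(1), n_obs=1)
        assert dow_percent_effects(fit)[day] == pytest.approx(expected)

    def test_zero_intercept_rejected(self):
        fit = DowModelFit(beta_intercept=0.0, beta_day={d: 1.0 for d in EFFECT_DAYS}, residuals=np.zeros(1), n_obs=1)
        with pytest.raises(DayOfWeekError, match="Monday level is zero"):
            dow_percent_effects(fit)


class TestBootstrap:
    def test_noise_free_series_gives_degenerate_interval(self, flat_uplift_series):
        effects = bootstrap_effects(flat_uplift_series, n_boot=200, seed=1)
        assert effects.percent_by_day["Sunday"] == pytest.approx(10.0, abs=1e-10)
        assert effects.ci_by_day["Sunday"] == pytest.approx((10.0, 10.0), abs=1e-10)
        assert effects.sd_by_day["Sunday"] == pytest.approx(0.0, abs=1e-10)
        assert "Sunday" in effects.significant_days

    def test_deterministic_given_seed(self, noisy_series):
        a = bootstrap_effects(noisy_series, n_boot=300, seed=5)
        b = bootstrap_effects(noisy_series, n_boot=300, seed=5)
        assert a == b

    def test_point_estimate_inside_interval(self, noisy_series):
        effects = bootstrap_effects(noisy_series, n_boot=500, seed=3)
        for day in EFFECT_DAYS:
            lo, hi = effects.ci_by_day[day]
            assert lo <= effects.percent_by_day[day] <= hi

    def test_invalid_arguments(self, noisy_series):
        with pytest.raises(DayOfWeekError):
            bootstrap_effects(noisy_series, n_boot=0, seed=1)
        with pytest.raises(DayOfWeekError):
            bootstrap_effects(noisy_series, n_boot=100, seed=None)


class TestSundayContrast:
    def test_planted_step_recovered_exactly(self, flat_uplift_series):
        contrast = sunday_contrast(flat_uplift_series, n_boot=100, seed=1)
        assert contrast.percent == pytest.approx(10.0, abs=1e-10)
        assert contrast.significant

    def test_flat_series_gives_zero(self, dates_364):
        series = pd.Series(np.full(364, 80.0), index=dates_364)
        contrast = sunday_contrast(series, n_boot=100, seed=1)
        assert contrast.percent == pytest.approx(0.0, abs=1e-10)

    def test_quantized_uplift_within_rounding_error(self):
        # integer normalization is the only error source on a noise-free series
        for uplift in (0.05, 0.109, 0.2):
            spec = SeriesSpec(sunday_uplift=uplift, seasonal_amplitude=0, trend_per_year=0, noise_sd=0)
            series = generate_daily_series(spec, seed=0)
            contrast = sunday_contrast(series, n_boot=10, seed=0)
            assert contrast.percent == pytest.approx(100 * uplift, abs=1.0)


class TestModelObject:
    def test_scale_invariance_of_percent_effects(self, noisy_series):
        r1 = DayOfWeekModel(noisy_series).fit(n_boot=50, seed=9)
        r2 = DayOfWeekModel(noisy_series * 3.5).fit(n_boot=50, seed=9)
        for day in EFFECT_DAYS:
            assert r1.effects.percent_by_day[day] == pytest.approx(
                r2.effects.percent_by_day[day], abs=1e-10
            )
        assert r1.sunday.percent == pytest.approx(r2.sunday.percent, abs=1e-10)

    def test_reconstruction_removes_slow_confounds(self):
        """Strong seasonality plus trend biases raw weekday contrasts (each
        weekday samples the ramp at a different phase); the sub-14-day
        reconstruction removes most of that bias."""
        planted = 10.0
        spec = SeriesSpec(
            sunday_uplift=planted / 100, seasonal_amplitude=0.455, trend_per_year=1.0,
            noise_sd=0, n_days=364, start_date="2016-01-04",
        )
        series = generate_daily_series(spec, seed=0)
        raw = DayOfWeekModel(series, reconstruct=False).fit(n_boot=1, seed=0)
        rec = DayOfWeekModel(series).fit(n_boot=1, seed=0)
        raw_bias = abs(raw.effects.percent_by_day["Sunday"] - planted)
        rec_bias = abs(rec.effects.percent_by_day["Sunday"] - planted)
        assert rec_bias <= 0.5 * raw_bias

    def test_summary_lists_all_days(self, noisy_series):
        text = DayOfWeekModel(noisy_series).fit(n_boot=50, seed=2).summary()
        for day in EFFECT_DAYS:
            assert day in text
        assert "Sunday vs rest" in text

    def test_from_dataframe(self, noisy_series):
        frame = pd.DataFrame({"date": noisy_series.index, "value": noisy_series.values})
        model = DayOfWeekModel.from_dataframe(frame, reconstruct=False)
        assert model.series.equals(model.raw_series)
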
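"""Daily means, seasonal smoother, closure detection, and the light LMM."""

import warnings
from datetime import datetime

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from herbphys.canopy import (
    closure_day,
    daily_means,
    fit_canopy_smooth,
    fit_ppfd_lmm,
    lmm_term_table,
    lr_test,
    treatment_means_original_scale,
)
from herbphys.records import GasExchangeRecord
from herbphys.simulate import paper_like_season, season_trajectory, simulate_season


def _sensor_rec(hour, minute, ppfd, day=1):
    return GasExchangeRecord(plant_id="sensor", species="other",
                             treatment="fenced",
                             timestamp=datetime(2015, 6, day, hour, minute),
                             ppfd=ppfd, a_net=0.0)


class TestDailyMeans:
    def test_window_is_inclusive_start_exclusive_end(self):
        recs = [_sensor_rec(9, 59, 500.0), _sensor_rec(14, 0, 500.0)]
        assert daily_means(recs).empty

    def test_mean_of_in_window_records(self):
        recs = [_sensor_rec(10, 0, 100.0), _sensor_rec(13, 59, 300.0)]
        out = daily_means(recs)
        assert len(out) == 1
        assert out["mean_ppfd"].iloc[0] == pytest.approx(200.0)
        assert out["n_obs"].iloc[0] == 2

    def test_one_row_per_day(self):
        recs = [_sensor_rec(11, 0, 100.0 * d, day=d) for d in range(1, 8)]
        out = daily_means(recs)
        assert len(out) == 7
        assert out["day_of_year"].is_unique


class TestCanopySmooth:
    def test_noise_free_decline_recovered(self):
        sc = paper_like_season(seed=0, sensor_lognorm_sd=0.0)
        data = simulate_season(sc)
        smooth = fit_canopy_smooth(data.sensor)
        truth = season_trajectory(sc, "sensor", smooth.days)
        interior = (smooth.days > smooth.days[0] + 5) & \
                   (smooth.days < smooth.days[-1] - 5)
        rel = np.abs(smooth.fitted[interior] - truth[interior]) / truth[interior]
        assert np.max(rel) < 0.02

    def test_derivative_matches_finite_differences_of_spline(self):
        data = simulate_season(paper_like_season(seed=1)).sensor
        smooth = fit_canopy_smooth(data)
        spl = smooth.spline()
        h = 1e-3
        fd = (spl(smooth.days + h) - spl(smooth.days - h)) / (2 * h)
        assert np.max(np.abs(fd - smooth.derivative)) < 1e-4 * max(
            1.0, np.max(np.abs(smooth.derivative)))

    def test_constant_series_derivative_ci_contains_zero(self):
        days = np.arange(91, 160)
        series = pd.DataFrame({"day_of_year": days,
                               "mean_ppfd": np.full(len(days), 50.0),
                               "n_obs": 48})
        smooth = fit_canopy_smooth(series)
        assert np.max(np.abs(smooth.derivative)) < 1e-6
        assert np.all(smooth.deriv_lo <= 1e-6)
        assert np.all(smooth.deriv_hi >= -1e-6)

    def test_too_few_days_refused(self):
        series = pd.DataFrame({"day_of_year": np.arange(10),
                               "mean_ppfd": np.linspace(300, 100, 10)})
        with pytest.raises(ValueError):
            fit_canopy_smooth(series)


class TestClosureDay:
    def test_low_noise_scenario_detected_in_reported_window(self):
        sc = paper_like_season(seed=11, sensor_lognorm_sd=0.05)
        data = simulate_season(sc)
        day = closure_day(fit_canopy_smooth(data.sensor))
        assert day is not None
        assert 143 <= day <= 153

    def test_strictly_linear_decline_gives_none(self, rng):
        days = np.arange(91, 200)
        series = pd.DataFrame({"day_of_year": days,
                               "mean_ppfd": 500.0 - 4.0 * (days - 91)
                               + rng.normal(0, 3, len(days))})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assert closure_day(fit_canopy_smooth(series)) is None

    def test_flat_series_gives_none(self, rng):
        days = np.arange(91, 200)
        series = pd.DataFrame({"day_of_year": days,
                               "mean_ppfd": 50.0 + rng.normal(0, 2, len(days))})
        with pytest.warns(UserWarning, match="decline"):
            assert closure_day(fit_canopy_smooth(series)) is None

    def test_invariant_to_unit_rescaling(self):
        data = simulate_season(paper_like_season(seed=21)).sensor
        day1 = closure_day(fit_canopy_smooth(data))
        scaled = data.assign(mean_ppfd=data["mean_ppfd"] * 1000.0)
        day2 = closure_day(fit_canopy_smooth(scaled))
        assert day1 == day2


@pytest.fixture(scope="module")
def season_plants():
    return simulate_season(paper_like_season(seed=5)).plants


class TestPpfdLmm:
    def test_homoscedastic_fit_matches_mixedlm(self, season_plants):
        """delta = 0 imposed: agrees with an independent direct ML fit."""
        mine = fit_ppfd_lmm(season_plants, heteroscedastic=False)
        df = season_plants.copy()
        s = (df["day_of_year"] - mine.day_center) / mine.day_scale
        X = pd.DataFrame({
            "const": 1.0, "s": s, "s2": s ** 2,
            "f": (df["treatment"] == "fenced").astype(float)})
        X["sf"] = X["s"] * X["f"]
        ref = sm.MixedLM(np.log(df["mean_ppfd"]), X,
                         groups=df["day_of_year"]).fit(reml=False)
        assert mine.loglik == pytest.approx(ref.llf, abs=1e-4)
        assert np.allclose(mine.beta, ref.fe_params.values, atol=1e-5)

    def test_heteroscedastic_loglik_dominates_homoscedastic(self, season_plants):
        homo = fit_ppfd_lmm(season_plants, heteroscedastic=False)
        het = fit_ppfd_lmm(
            season_plants, heteroscedastic=True,
            theta0=np.array([homo.theta_opt[0], 0.0, 0.0]))
        assert het.loglik >= homo.loglik - 1e-8

    def test_parameter_counts_follow_term_sequence(self, season_plants):
        base = fit_ppfd_lmm(season_plants, terms=("1",))
        full = fit_ppfd_lmm(season_plants)
        assert base.n_params == 5
        assert full.n_params == 9

    def test_lr_test_identical_models_is_null(self, season_plants):
        fit = fit_ppfd_lmm(season_plants, terms=("1", "day"))
        res = lr_test(fit, fit)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_term_table_reports_df_pairs(self, season_plants):
        table = lmm_term_table(season_plants)
        assert list(table["df"]) == ["(5,6)", "(6,7)", "(7,8)", "(8,9)"]
        assert (table["likelihood_ratio"] >= 0).all()

    def test_lrt_invariant_to_treatment_recoding(self, season_plants):
        full = fit_ppfd_lmm(season_plants)
        red = fit_ppfd_lmm(season_plants, terms=("1", "day", "day2", "fencing"),
                           theta0=full.theta_opt)
        stat1 = lr_test(full, red).statistic

        flipped = season_plants.assign(
            treatment=season_plants["treatment"].map(
                {"fenced": "unfenced", "unfenced": "fenced"}))
        fullf = fit_ppfd_lmm(flipped, theta0=full.theta_opt)
        redf = fit_ppfd_lmm(flipped, terms=("1", "day", "day2", "fencing"),
                            theta0=full.theta_opt)
        stat2 = lr_test(fullf, redf).statistic
        assert stat1 == pytest.approx(stat2, abs=5e-3)

    def test_non_nested_models_rejected(self, season_plants):
        a = fit_ppfd_lmm(season_plants, terms=("1", "day"))
        b = fit_ppfd_lmm(season_plants, terms=("1", "fencing"))
        with pytest.raises(ValueError):
            lr_test(a, b)


class TestOriginalScaleMeans:
    def test_noise_free_scenario_recovers_plateau_means(self):
        # flat per-treatment trajectories: the fixed-effect structure is
        # exact, so predictions must equal the plateau levels
        sc = paper_like_season(
            seed=0, noise_lognorm_sd=0.0, day_effect_sd=0.0,
            pre_closure_ppfd={"fenced": 15.6, "unfenced": 52.0},
            post_closure_ppfd={"fenced": 15.6, "unfenced": 52.0})
        data = simulate_season(sc)
        model = fit_ppfd_lmm(data.plants)
        out = treatment_means_original_scale(model, 172)
        expect = {g: season_trajectory(sc, g, 172.0) for g in ("fenced", "unfenced")}
        for _, row in out.iterrows():
            assert row["mean_ppfd"] == pytest.approx(expect[row["treatment"]],
                                                     rel=0.02)

    def test_extrapolation_refused(self, season_plants):
        model = fit_ppfd_lmm(season_plants)
        with pytest.raises(ValueError, match="range"):
            treatment_means_original_scale(model, 300)

    def test_se_shrinks_with_more_plants(self):
        small = simulate_season(paper_like_season(
            seed=8, plant_count={"fenced": 20, "unfenced": 25}))
        big = simulate_season(paper_like_season(
            seed=8, plant_count={"fenced": 150, "unfenced": 220}))
        se_small = treatment_means_original_scale(
            fit_ppfd_lmm(small.plants), 160)["se"].mean()
        se_big = treatment_means_original_scale(
            fit_ppfd_lmm(big.plants), 160)["se"].mean()
        assert se_big < se_small
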
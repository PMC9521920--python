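"""Seasonal summaries, freeze dates, PET, SPEI, and timber-area binning."""

import calendar

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from elkdemog import covariates as cov
from conftest import make_daily


class TestSeasonalMetrics:
    def test_constant_winter_tmean(self):
        daily = make_daily("2000-01-01", "2001-12-31", tmean=2.0, tmin=0.0,
                           tmax=4.0)
        out = cov.derive_seasonal_metrics(daily, 2001)
        assert out["mean_winter_temp"] == pytest.approx(2.0)

    def test_gdd_zero_at_base_temperature(self):
        daily = make_daily("2000-06-01", "2000-08-31", tmin=5.0, tmax=5.0)
        out = cov.derive_seasonal_metrics(daily, 2000)
        assert out["gdd"] == 0.0

    def test_gdd_monotone_in_temperature(self):
        rng = np.random.default_rng(1)
        base = make_daily("2000-06-01", "2000-08-31",
                          tmin=rng.normal(8, 3, 92), tmax=rng.normal(16, 3, 92))
        warmer = base + 1.0
        g0 = cov.derive_seasonal_metrics(base, 2000)["gdd"]
        g1 = cov.derive_seasonal_metrics(warmer, 2000)["gdd"]
        assert g1 >= g0 >= 0.0

    def test_monthly_min_matches_bruteforce_scan(self):
        idx = pd.date_range("2000-11-01", "2001-03-31", freq="D")
        rng = np.random.default_rng(7)
        tmin = -5 + 4 * np.sin(np.arange(len(idx)) / 9.0) + rng.normal(0, 2, len(idx))
        daily = pd.DataFrame({"tmin": tmin, "tmax": tmin + 6.0}, index=idx)
        out = cov.derive_seasonal_metrics(daily, 2001)
        # oracle: scan every day, track the minimum per winter month
        per_month: dict[tuple[int, int], float] = {}
        for day, t in zip(idx, tmin):
            key = (day.year, day.month)
            per_month[key] = min(per_month.get(key, np.inf), t)
        assert out["mean_monthly_min_winter_temp"] == pytest.approx(
            np.mean(list(per_month.values())))

    def test_season_windows_are_disjoint(self, station_daily):
        seen = {}
        for season in cov.SEASON_MONTHS:
            frame = cov._season_frame(station_daily, 2000, season)
            for ts in frame.index:
                assert ts not in seen, f"{ts} in both {seen.get(ts)} and {season}"
                seen[ts] = season

    def test_missing_window_gives_nan(self):
        daily = make_daily("2000-06-01", "2000-08-31", tmin=6.0, tmax=12.0)
        out = cov.derive_seasonal_metrics(daily, 2000)
        assert np.isnan(out["mean_winter_temp"])


class TestFreezeMetrics:
    def test_no_fall_freeze_is_missing(self):
        daily = make_daily("2018-08-01", "2019-06-30", tmin=2.0, tmax=8.0)
        out = cov.freeze_metrics(daily, 2019)
        assert np.isnan(out["first_fall_freeze"])
        assert np.isnan(out["winter_duration"])

    def test_winter_duration_by_date_arithmetic(self):
        daily = make_daily("2018-08-01", "2019-06-30", tmin=2.0, tmax=8.0)
        daily.loc["2018-09-20", "tmin"] = -1.0
        daily.loc["2019-05-10", "tmin"] = -0.5
        out = cov.freeze_metrics(daily, 2019)
        assert out["first_fall_freeze"] == pd.Timestamp("2018-09-20").dayofyear
        assert out["last_spring_freeze"] == pd.Timestamp("2019-05-10").dayofyear
        assert out["winter_duration"] == 232  # Sep 20 -> May 10

    def test_synthetic_freeze_dates_fall_in_plausible_season(self, station_daily):
        out = cov.freeze_metrics(station_daily, 2000)
        # first freeze in Sep-Nov, last in Mar-Jun for a subpolar maritime record
        assert 244 <= out["first_fall_freeze"] <= 334
        assert 60 <= out["last_spring_freeze"] <= 181


class TestThornthwaitePET:
    def test_subzero_month_has_zero_pet(self):
        t = np.full(12, 10.0)
        t[0] = -5.0
        pet = cov.thornthwaite_pet(t, latitude=40.0)
        assert pet[0] == 0.0
        assert (pet[1:] > 0).all()

    def test_formula_against_hand_evaluation(self):
        # T = 10 everywhere; at the equator L = 12 h exactly
        pet = cov.thornthwaite_pet([10.0] * 12, latitude=0.0)
        I = 12 * (10 / 5) ** 1.514
        a = 6.75e-7 * I**3 - 7.71e-5 * I**2 + 1.792e-2 * I + 0.49239
        jan = 16.0 * (12.0 / 12.0) * (31 / 30) * (10 * 10 / I) ** a
        assert pet[0] == pytest.approx(jan, rel=1e-12)
        assert pet[0] == pytest.approx(50.52, abs=0.01)

    def test_linear_in_day_length(self):
        t = np.full(12, 10.0)
        pet_eq = cov.thornthwaite_pet(t, latitude=0.0)
        pet_mid = cov.thornthwaite_pet(t, latitude=45.0)
        for m in range(12):
            ratio = cov.day_length_hours(45.0, m + 1) / cov.day_length_hours(0.0, m + 1)
            assert pet_mid[m] / pet_eq[m] == pytest.approx(ratio, rel=1e-9)

    def test_all_subzero_is_an_error(self):
        with pytest.raises(ValueError, match="heat index"):
            cov.thornthwaite_pet(np.full(12, -2.0), latitude=50.0)


class TestSPEI:
    @pytest.fixture(scope="class")
    def monthly(self, station_daily):
        m = cov.monthly_climate_series(station_daily)
        pet = cov.monthly_pet_series(m, 58.0)
        return m["precip"], pet

    def test_index_monotone_in_current_balance(self, monthly):
        precip, pet = monthly
        idx = cov.spei_index(precip, pet, 3, (1950, 2021))
        target = pd.Period("1990-09", freq="M")
        bumped = precip.copy()
        bumped[target] += 50.0
        idx2 = cov.spei_index(bumped, pet, 3, (1950, 2021))
        assert idx2[target] > idx[target]

    def test_scale_window_contains_exactly_k_months(self, monthly):
        precip, pet = monthly
        idx = cov.spei_index(precip, pet, 3, (1950, 2021))
        sep = pd.Period("1985-09", freq="M")
        bumped = precip.copy()
        bumped[pd.Period("1985-06", freq="M")] += 100.0  # outside Jul-Sep
        idx2 = cov.spei_index(bumped, pet, 3, (1950, 2021))
        assert idx2[sep] == pytest.approx(idx[sep])
        bumped2 = precip.copy()
        bumped2[pd.Period("1985-07", freq="M")] += 100.0  # inside Jul-Sep
        idx3 = cov.spei_index(bumped2, pet, 3, (1950, 2021))
        assert idx3[sep] > idx[sep]

    def test_iid_k1_median_maps_near_zero(self):
        rng = np.random.default_rng(5)
        periods = pd.period_range("1950-01", "2019-12", freq="M")
        d = pd.Series(rng.gamma(4.0, 20.0, len(periods)), index=periods)
        pet = pd.Series(0.0, index=periods)
        idx = cov.spei_index(d, pet, 1, (1950, 2019))
        jan = d[d.index.month == 1]
        median_period = (jan - jan.median()).abs().idxmin()
        # empirical-quantile oracle: the median balance should map near 0
        assert abs(idx[median_period]) < 0.15

    def test_insufficient_calibration_errors(self):
        periods = pd.period_range("2000-01", "2010-12", freq="M")
        d = pd.Series(np.arange(len(periods), dtype=float), index=periods)
        with pytest.raises(ValueError, match="calibration"):
            cov.spei_index(d, pd.Series(0.0, index=periods), 3, (2000, 2010))


class TestTimberAreas:
    def test_single_fresh_stand(self):
        stands = pd.DataFrame({"harvest_year": [2000], "area": [2.0]})
        out = cov.timber_age_class_areas(stands, 2000)
        assert out == {"timber_age_lt1": 2.0, "timber_age_1_5": 0.0,
                       "timber_age_6_30": 0.0, "timber_age_gt30": 0.0,
                       "timber_total": 2.0}

    def test_one_stand_per_bin(self):
        stands = pd.DataFrame({"harvest_year": [2000, 1997, 1990, 1960],
                               "area": [1.0] * 4})
        out = cov.timber_age_class_areas(stands, 2000)
        assert [out[k] for k in ("timber_age_lt1", "timber_age_1_5",
                                 "timber_age_6_30", "timber_age_gt30")] == [1, 1, 1, 1]
        assert out["timber_total"] == 4.0

    def test_matches_per_stand_binning_oracle(self):
        rng = np.random.default_rng(11)
        stands = pd.DataFrame({
            "harvest_year": rng.integers(1950, 2011, 60),
            "area": rng.gamma(2.0, 2.0, 60),
        })
        out = cov.timber_age_class_areas(stands, 2010)
        oracle = dict.fromkeys(out, 0.0)
        for _, s in stands.iterrows():
            age = 2010 - s["harvest_year"]
            if age == 0:
                oracle["timber_age_lt1"] += s["area"]
            elif age <= 5:
                oracle["timber_age_1_5"] += s["area"]
            elif age <= 30:
                oracle["timber_age_6_30"] += s["area"]
            else:
                oracle["timber_age_gt30"] += s["area"]
            oracle["timber_total"] += s["area"]
        for k in out:
            assert out[k] == pytest.approx(oracle[k])

    def test_future_stand_errors(self):
        stands = pd.DataFrame({"harvest_year": [2005], "area": [1.0]})
        with pytest.raises(ValueError, match="after"):
            cov.timber_age_class_areas(stands, 2000)


class TestPredictorTable:
    def test_lagged_predictors_come_from_prior_year(self, station_daily):
        spec = cov.PredictorTableSpec(range(1990, 1993), 58.0)
        table = cov.build_predictor_table(station_daily, spec)
        prior = cov.derive_seasonal_metrics(station_daily, 1990)
        assert table.loc[1991, "mean_summer_temp"] == pytest.approx(
            prior["mean_summer_temp"])
        assert table.loc[1991, "mean_fall_temp"] == pytest.approx(
            prior["mean_fall_temp"])
        current = cov.derive_seasonal_metrics(station_daily, 1991)
        assert table.loc[1991, "mean_winter_temp"] == pytest.approx(
            current["mean_winter_temp"])
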
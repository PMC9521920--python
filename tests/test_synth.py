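"""Simulator determinism, calibration moments, and file round-trips."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from elkdemog import io, synth
from elkdemog.mcmc import MCMCConfig
from elkdemog.recruitment import fit_recruitment_glm


class TestDeterminism:
    def test_weather_bit_reproducible(self):
        cfg = synth.WeatherConfig(start_year=2000, end_year=2002)
        a = synth.simulate_daily_weather(cfg, seed=5)
        b = synth.simulate_daily_weather(cfg, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_bear_and_elk_bit_reproducible(self):
        ra, ta, tra = synth.simulate_bear_harvest(
            synth.BearConfig(deterministic=False), seed=5)
        rb, tb, trb = synth.simulate_bear_harvest(
            synth.BearConfig(deterministic=False), seed=5)
        pd.testing.assert_frame_equal(ra, rb)
        pd.testing.assert_series_equal(tra.abundance, trb.abundance)
        sa = synth.simulate_elk_system(synth.ElkConfig(), seed=5)
        sb = synth.simulate_elk_system(synth.ElkConfig(), seed=5)
        pd.testing.assert_series_equal(sa["counts"], sb["counts"])
        pd.testing.assert_series_equal(sa["ratios"], sb["ratios"])


class TestWeather:
    def test_long_run_mean_temperature(self, station_daily):
        cfg = synth.WeatherConfig()
        tm = station_daily["tmean"]
        se = tm.std() / np.sqrt(len(tm) / 30)  # ~monthly effective samples
        assert abs(tm.mean() - cfg.mean_temp) < 3 * se

    def test_tmin_below_tmax_everywhere(self, station_daily):
        assert (station_daily["tmin"] <= station_daily["tmax"]).all()
        assert (station_daily[["precip", "snowfall", "snow_depth"]] >= 0).all().all()

    def test_noise_free_freeze_matches_analytic_crossing(self):
        cfg = synth.WeatherConfig(start_year=2000, end_year=2001,
                                  mean_temp=3.0, amplitude=15.0,
                                  daily_sd=0.0, margin_sd=0.0)
        daily = synth.simulate_daily_weather(cfg, seed=0)
        half = cfg.diurnal_range / 2.0

        def tmin_of(doy):
            return (cfg.mean_temp - cfg.amplitude
                    * np.cos(2 * np.pi * (doy - cfg.coldest_doy) / 365.25)
                    - half)

        # analytic first autumn crossing of tmin = 0 (descending branch)
        root = optimize.brentq(tmin_of, 200, 365)
        fall = daily.loc["2000-08-01":"2000-12-31", "tmin"]
        first_freeze_doy = fall[fall <= 0].index[0].dayofyear
        assert first_freeze_doy == int(np.ceil(root))


class TestBearSimulator:
    def test_aged_fraction_moment(self):
        cfg = synth.BearConfig(deterministic=False, final_cull=False,
                               aged_fraction=0.92)
        records, _, _ = synth.simulate_bear_harvest(cfg, seed=9)
        aged = records[[f"class_{i}" for i in range(1, 6)]].sum(axis=1).sum()
        total = records["total_mortalities"].sum()
        p = aged / total
        se = np.sqrt(0.92 * 0.08 / total)
        assert abs(p - 0.92) < 4 * se

    def test_study_scale_defaults(self):
        _, table, truth = synth.simulate_bear_harvest(synth.BearConfig(), seed=0)
        assert 15 < table.counts.iloc[:-1].sum(axis=1).mean() < 30
        assert truth.abundance.iloc[0] < truth.abundance.loc[2013]


class TestElkSimulator:
    def test_noise_free_geometric_growth(self):
        cfg = synth.ElkConfig(a=0.05, b=0.0, n0=100.0, sigma_proc=0.0,
                              sigma_obs=0.0, harvest_rate=0.0,
                              start_year=2000, end_year=2019)
        sim = synth.simulate_elk_system(cfg, seed=0)
        ratios = sim["counts"].to_numpy()[1:] / sim["counts"].to_numpy()[:-1]
        np.testing.assert_allclose(ratios, np.exp(0.05), rtol=2e-2)

    def test_null_recruitment_rarely_flags_predictors(self):
        influential = 0
        years = np.arange(1970, 2014)
        cfg_fit = MCMCConfig(chains=3, iterations=1200, burn_in=400, thin=1,
                             seed=0)
        for seed in range(8):
            rng = np.random.default_rng([71, seed])
            z = pd.DataFrame(rng.standard_normal((len(years), 4)),
                             columns=list("abcd"), index=years)
            cfg = synth.ElkConfig(ratio_coefs={}, ratio_start_year=1970)  # beta = 0
            sim = synth.simulate_elk_system(cfg, covariates=z, seed=seed)
            fit = fit_recruitment_glm(sim["ratios"], z.loc[sim["ratios"].index],
                                      cfg_fit)
            influential += int(fit.summary.loc[list("abcd"), "influential"].sum())
        # 32 null slope intervals at the 95% level: a handful of flags at most
        assert influential <= 4

    def test_harvest_collapse_raises(self):
        # permit over-issue: harvest demand exceeds true abundance
        cfg = synth.ElkConfig(a=0.0, b=0.0, n0=50.0, harvest_rate=1.5,
                              sigma_proc=0.0, sigma_obs=0.0,
                              start_year=2000, end_year=2019)
        with pytest.raises(ValueError, match="<= 0"):
            synth.simulate_elk_system(cfg, seed=0)


class TestRoundTrips:
    def test_all_tables_round_trip(self, tmp_path):
        daily = synth.simulate_daily_weather(
            synth.WeatherConfig(start_year=2000, end_year=2001), seed=1)
        io.write_daily_weather(daily, tmp_path / "w.csv")
        back = io.read_daily_weather(tmp_path / "w.csv")
        pd.testing.assert_frame_equal(back, daily.round(2), check_freq=False,
                                      check_names=False)

        records, _, _ = synth.simulate_bear_harvest(
            synth.BearConfig(deterministic=False), seed=1)
        io.write_mortality_records(records, tmp_path / "m.csv")
        back = io.read_mortality_records(tmp_path / "m.csv")
        pd.testing.assert_frame_equal(back, records, check_dtype=False)

        sim = synth.simulate_elk_system(synth.ElkConfig(), seed=1)
        io.write_count_series(sim["counts"], sim["harvest"], tmp_path / "c.csv")
        counts, harvest = io.read_count_series(tmp_path / "c.csv")
        pd.testing.assert_series_equal(counts, sim["counts"],
                                       check_dtype=False, check_names=False)

        comp = synth.composition_from_ratios(sim["ratios"], seed=1)
        io.write_composition(comp, tmp_path / "comp.csv")
        back = io.read_composition(tmp_path / "comp.csv")
        pd.testing.assert_frame_equal(back, comp, check_dtype=False)

    def test_ghcn_style_column_names(self, tmp_path):
        daily = synth.simulate_daily_weather(
            synth.WeatherConfig(start_year=2000, end_year=2000), seed=2)
        renamed = daily.rename(columns={"tmean": "TAVG", "precip": "PRCP",
                                        "snowfall": "SNOW",
                                        "snow_depth": "SNWD"})
        renamed.to_csv(tmp_path / "ghcn.csv", index_label="DATE")
        back = io.read_daily_weather(tmp_path / "ghcn.csv")
        assert {"tmin", "tmax", "tmean", "precip", "snowfall",
                "snow_depth"} <= set(back.columns)
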
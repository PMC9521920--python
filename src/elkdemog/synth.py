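"""Synthetic weather, bear-mortality, and elk datasets for testing the pipeline.

Each simulator draws from the same generative families the analysis
assumes — a seasonal sinusoid plus noise for daily weather, an
age-structured harvested population for bears, the exact Gompertz
state-space process for elk counts, and the linear-Gaussian model for age
ratios — so every stage of the pipeline can be exercised end to end with
known truth. Defaults are sized to the study system: a subpolar maritime
station record spanning 1950–2021, ~50 years of bear mortalities averaging
~20/yr from a population growing from below 100 to above 300, 63 years of
counts for a herd of 10–230 animals, and 44 years of age ratios centered
near 33 calves per 100 cows.

Every simulator is a deterministic function of (config, seed); random
streams are spawned hierarchically so the simulators stay independent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bear import HarvestAtAgeTable

log = logging.getLogger(__name__)


def _rng(seed: int | None, salt: int) -> np.random.Generator:
    if seed is None:
        return np.random.default_rng()
    return np.random.default_rng(np.random.SeedSequence([seed, salt]))


# ---------------------------------------------------------------------------
# Weather
# ---------------------------------------------------------------------------

@dataclass
class WeatherConfig:
    """Daily weather generator (subpolar maritime defaults).

    Mean annual temperature ~5 °C with a 7 °C seasonal amplitude puts winter
    means slightly below freezing and summer means near 12 °C; wet-day
    gamma precipitation yields ~1.7 m annual rainfall.
    """

    start_year: int = 1950
    end_year: int = 2021
    mean_temp: float = 5.0          # °C annual mean
    amplitude: float = 7.0          # °C seasonal half-range
    coldest_doy: int = 32           # early February minimum
    daily_sd: float = 2.5           # °C day-to-day noise
    diurnal_range: float = 6.0      # °C tmax − tmin
    margin_sd: float = 1.0          # °C extra half-normal spread of tmin/tmax
    trend_per_year: float = 0.0     # °C/yr linear warming
    wet_prob: float = 0.5
    precip_shape: float = 0.7
    precip_scale: float = 14.0      # mm, wet-day gamma scale
    melt_rate: float = 5.0          # mm snow depth lost per degree-day > 0


def simulate_daily_weather(
    config: WeatherConfig, seed: int | None = None
) -> pd.DataFrame:
    """Generate a daily station record (tmin/tmax/tmean °C, precip/snow mm)."""
    cfg = config
    dates = pd.date_range(f"{cfg.start_year}-01-01", f"{cfg.end_year}-12-31",
                          freq="D")
    rng = _rng(seed, 10)
    doy = dates.dayofyear.to_numpy()
    yrs = dates.year.to_numpy() - cfg.start_year
    seasonal = cfg.mean_temp - cfg.amplitude * np.cos(
        2 * np.pi * (doy - cfg.coldest_doy) / 365.25
    )
    tmean = seasonal + cfg.trend_per_year * yrs + rng.normal(0, cfg.daily_sd, len(dates))
    half = cfg.diurnal_range / 2.0
    tmin = tmean - half - np.abs(rng.normal(0, 1.0, len(dates))) * cfg.margin_sd
    tmax = tmean + half + np.abs(rng.normal(0, 1.0, len(dates))) * cfg.margin_sd

    wet = rng.uniform(size=len(dates)) < cfg.wet_prob
    amounts = rng.gamma(cfg.precip_shape, cfg.precip_scale, len(dates)) * wet
    snowfall = np.where(tmean < 0.0, amounts, 0.0)
    rain = np.where(tmean < 0.0, 0.0, amounts)

    depth = np.zeros(len(dates))
    d = 0.0
    for i in range(len(dates)):
        d += snowfall[i] * 7.0  # fresh snow depth ~7x water equivalent
        d -= cfg.melt_rate * max(tmean[i], 0.0) * 7.0
        d = max(d, 0.0)
        depth[i] = d

    return pd.DataFrame(
        {
            "tmin": tmin, "tmax": tmax, "tmean": (tmin + tmax) / 2.0,
            "precip": rain + snowfall, "snowfall": snowfall,
            "snow_depth": depth,
        },
        index=dates,
    )


# ---------------------------------------------------------------------------
# Bears
# ---------------------------------------------------------------------------

@dataclass
class BearConfig:
    """Age-structured (5 stage classes) harvested bear population.

    With harvest as the dominant mortality and per-capita recruitment just
    above removal, abundance roughly quadruples over the default 51 years,
    mirroring a reconstructed series rising from below 100 toward ~330 with
    ~20 known mortalities per year.
    """

    start_year: int = 1967
    end_year: int = 2017
    n_classes: int = 5
    initial_per_class: tuple[float, ...] = (30.0, 22.0, 16.0, 12.0, 10.0)
    recruit_rate: float = 0.15      # class-1 entrants per bear per year
    natural_survival: float = 1.0   # harvest-only mortality by default
    harvest_rate: float = 0.12      # equal across classes
    aged_fraction: float = 0.92
    deterministic: bool = True      # fractional animals; exact harvest rates
    final_cull: bool = True         # harvest everything in the last year


@dataclass
class BearTruth:
    abundance: pd.Series            # true pre-harvest N_t by year
    per_class: pd.DataFrame


def simulate_bear_harvest(
    config: BearConfig, seed: int | None = None
) -> tuple[pd.DataFrame, HarvestAtAgeTable, BearTruth]:
    """Simulate the bear population and its mortality record.

    Returns the raw mortality-record table (year, aged counts per class,
    total mortalities — the on-disk layout), the allocated
    :class:`HarvestAtAgeTable` built from the *full* harvest (useful as
    ground truth when `aged_fraction` < 1), and the true abundance.

    In deterministic mode harvest is exactly `harvest_rate` × class
    abundance (fractional animals), so with `natural_survival` = 1 and
    `final_cull` the Downing reconstruction recovers the truth exactly.
    """
    cfg = config
    rng = _rng(seed, 20)
    if len(cfg.initial_per_class) != cfg.n_classes:
        raise ValueError("initial_per_class length must equal n_classes")
    years = np.arange(cfg.start_year, cfg.end_year + 1)
    m = cfg.n_classes
    N = np.array(cfg.initial_per_class, dtype=float)
    truth_rows, harvest_rows, aged_rows, totals = [], [], [], []
    for i, year in enumerate(years):
        truth_rows.append(N.copy())
        rate = 1.0 if (cfg.final_cull and i == len(years) - 1) else cfg.harvest_rate
        if cfg.deterministic:
            H = rate * N
        else:
            H = rng.binomial(np.round(N).astype(int), rate).astype(float)
        harvest_rows.append(H)
        if cfg.aged_fraction >= 1.0 or cfg.deterministic:
            aged = H * min(cfg.aged_fraction, 1.0)
        else:
            aged = rng.binomial(H.astype(int), cfg.aged_fraction).astype(float)
        aged_rows.append(aged)
        totals.append(H.sum())

        surv = np.maximum(N - H, 0.0) * cfg.natural_survival
        recruits = cfg.recruit_rate * N.sum()
        N = np.empty(m)
        N[0] = recruits
        N[1:m - 1] = surv[0:m - 2]
        N[m - 1] = surv[m - 2] + surv[m - 1]
        if N.sum() < 1e-9:
            log.warning("bear population extinct in %d; truncating", year)
            years = years[: i + 1]
            break

    per_class_truth = pd.DataFrame(
        truth_rows, index=years[: len(truth_rows)],
        columns=[f"class_{i}" for i in range(1, m + 1)])
    truth = BearTruth(per_class_truth.sum(axis=1).rename("abundance"),
                      per_class_truth)

    Hm = np.array(harvest_rows)
    records = pd.DataFrame(
        np.array(aged_rows), index=years[: len(aged_rows)],
        columns=[f"class_{i}" for i in range(1, m + 1)])
    records.insert(0, "total_mortalities", totals)
    records.index.name = "year"
    records = records.reset_index()

    full = pd.DataFrame(Hm, index=years[: len(harvest_rows)],
                        columns=[f"class_{i}" for i in range(1, m + 1)])
    full.index.name = "year"
    table = HarvestAtAgeTable(
        full, pd.Series(1.0, index=full.index, name="proportion_aged"))
    return records, table, truth


# ---------------------------------------------------------------------------
# Elk
# ---------------------------------------------------------------------------

@dataclass
class ElkConfig:
    """Gompertz count dynamics and linear recruitment generator.

    Transition parameters default to the abundance-model scale of the
    analysis (a = 1.45, b = −0.27, σ_proc = 0.23, σ_obs = 0.20); the
    recruitment coefficients default to the fitted effect sizes of the
    island-wide model (intercept ~33 calves per 100 cows, residual SD ~6.4).
    """

    start_year: int = 1958
    end_year: int = 2020
    n0: float = 40.0
    a: float = 1.45
    b: float = -0.27
    cov_coefs: dict[str, float] = field(default_factory=dict)
    sigma_proc: float = 0.23
    sigma_obs: float = 0.20
    harvest_rate: float = 0.10      # of the observed count, post-count
    ratio_start_year: int = 1967
    ratio_end_year: int = 2013
    ratio_intercept: float = 33.0
    ratio_coefs: dict[str, float] = field(default_factory=dict)
    ratio_sd: float = 6.4


@dataclass
class ElkTruth:
    log_abundance: pd.Series
    params: dict


def simulate_elk_system(
    config: ElkConfig,
    covariates: pd.DataFrame | None = None,
    seed: int | None = None,
) -> dict:
    """Simulate counts, harvest, and age ratios from the model likelihoods.

    `covariates` (standardized, year-indexed) supplies any columns named in
    `cov_coefs` / `ratio_coefs`; missing values are treated as zero effect.
    Returns dict with 'counts', 'harvest', 'ratios', and 'truth'.
    """
    cfg = config
    rng = _rng(seed, 30)
    years = np.arange(cfg.start_year, cfg.end_year + 1)
    T = len(years)

    def _cov(name: str) -> np.ndarray:
        if covariates is not None and name in covariates.columns:
            return covariates[name].reindex(years).fillna(0.0).to_numpy()
        return np.zeros(T)

    cz = np.zeros(T)
    for name, coef in cfg.cov_coefs.items():
        cz += coef * _cov(name)

    x = np.empty(T)
    H = np.zeros(T)
    counts = np.empty(T)
    x[0] = np.log(cfg.n0)
    for t in range(T):
        n_true = np.exp(x[t])
        counts[t] = max(np.exp(x[t] + cfg.sigma_obs * rng.standard_normal()), 1.0)
        if t == T - 1:
            break
        H[t] = np.floor(cfg.harvest_rate * counts[t])
        post = n_true - H[t]
        if post <= 0:
            raise ValueError(f"harvest rule drove abundance <= 0 in {years[t]}")
        q = np.log(post)
        x[t + 1] = (q + cfg.a + cfg.b * q + cz[t + 1]
                    + cfg.sigma_proc * rng.standard_normal())

    ratio_years = np.arange(cfg.ratio_start_year, cfg.ratio_end_year + 1)
    rz = np.zeros(len(ratio_years))
    if covariates is not None:
        for name, coef in cfg.ratio_coefs.items():
            rz += coef * covariates[name].reindex(ratio_years).fillna(0.0).to_numpy()
    ratios = cfg.ratio_intercept + rz + cfg.ratio_sd * rng.standard_normal(len(ratio_years))
    ratios = np.maximum(ratios, 0.0)

    return {
        "counts": pd.Series(np.round(counts), index=years, name="count"),
        "harvest": pd.Series(H, index=years, name="harvest"),
        "ratios": pd.Series(ratios, index=ratio_years, name="age_ratio"),
        "truth": ElkTruth(
            pd.Series(x, index=years, name="log_abundance"),
            {
                "a": cfg.a, "b": cfg.b, "sigma_proc": cfg.sigma_proc,
                "sigma_obs": cfg.sigma_obs, "cov_coefs": dict(cfg.cov_coefs),
                "ratio_intercept": cfg.ratio_intercept,
                "ratio_coefs": dict(cfg.ratio_coefs), "ratio_sd": cfg.ratio_sd,
            },
        ),
    }


def composition_from_ratios(
    ratios: pd.Series,
    herds: tuple[str, ...] = ("north", "south", "east"),
    mean_cows_per_herd: float = 60.0,
    error_prob: float = 0.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Herd-level composition counts whose pooled ratio tracks `ratios`.

    Cow counts are Poisson per herd; calves Poisson at the year's ratio.
    With `error_prob` > 0 a few records are corrupted into the failure modes
    the filters screen for (calves > cows, zero calves, unsexed adults) so
    exclusion logging can be exercised.
    """
    rng = _rng(seed, 40)
    rows = []
    for year, ratio in ratios.items():
        for herd in herds:
            cows = max(int(rng.poisson(mean_cows_per_herd)), 1)
            calves = int(rng.poisson(cows * ratio / 100.0))
            bulls = int(rng.poisson(cows * 0.3))
            u = rng.uniform()
            if u < error_prob:
                fault = rng.integers(3)
                if fault == 0:
                    calves = cows + 1 + int(rng.poisson(3))
                elif fault == 1:
                    calves = 0
                else:
                    cows = np.nan
            rows.append({"year": year, "herd": herd, "cows": cows,
                         "calves": calves, "bulls": bulls})
    return pd.DataFrame(rows)


def simulate_timber_stands(
    start_year: int = 1977,
    end_year: int = 2013,
    mean_area: float = 3.0,
    stands_per_year: int = 2,
    seed: int | None = None,
) -> pd.DataFrame:
    """Stand harvest table (harvest_year, area km²) with gamma-sized stands."""
    rng = _rng(seed, 50)
    rows = []
    for year in range(start_year, end_year + 1):
        for _ in range(stands_per_year):
            rows.append({"harvest_year": year,
                         "area": float(rng.gamma(2.0, mean_area / 2.0))})
    return pd.DataFrame(rows)
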
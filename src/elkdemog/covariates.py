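"""Weather- and land-use-derived predictor variables.

Builds the annual predictor table used by the recruitment and abundance
models from daily weather-station records and timber-stand harvest tables:
seasonal temperature/precipitation/snow summaries, freeze dates and winter
duration, growing degree days, the standardized precipitation-
evapotranspiration index (SPEI) with Thornthwaite potential
evapotranspiration, and timber-stand areas by age class.

Conventions
-----------
* Seasons: winter = 1 Nov–31 Mar (labeled by its *ending* calendar year, so
  the winter predictors for response year t cover Nov t−1 through Mar t);
  spring = 1 Apr–31 May; summer = 1 Jun–31 Aug; fall = 1 Sep–31 Oct.
* Maternal-carryover predictors (summer, fall, SPEI, growing degree days,
  first fall freeze) and timber areas enter the table for response year t
  from calendar year t−1.
* A freeze is a day with tmin ≤ 0 °C.
"""

from __future__ import annotations

import calendar
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gamma as _gamma_fn
from scipy.special import ndtri

log = logging.getLogger(__name__)

#: season name -> list of calendar months. Winter months 11, 12 belong to the
#: calendar year *before* the season label.
SEASON_MONTHS = {
    "winter": [11, 12, 1, 2, 3],
    "spring": [4, 5],
    "summer": [6, 7, 8],
    "fall": [9, 10],
}

GDD_BASE_C = 5.0
FREEZE_THRESHOLD_C = 0.0


@dataclass
class CovariateConfig:
    """Tunable conventions for predictor construction.

    Attributes
    ----------
    max_missing_frac : maximum fraction of days missing in a seasonal window
        before the derived value is reported as missing.
    monthly_min_mode : "monthly" averages each winter month's minimum daily
        tmin over the five winter months; "daily" averages daily tmin.
    spei6_months : number of months aggregated for the forest (July) SPEI.
        The default 6 spans Feb–Jul; 7 spans Jan–Jul.
    spei_calibration : (start year, end year) inclusive span of the SPEI
        log-logistic calibration period.
    """

    max_missing_frac: float = 0.10
    monthly_min_mode: str = "monthly"
    spei6_months: int = 6
    spei_calibration: tuple[int, int] = (1950, 2021)
    freeze_threshold: float = FREEZE_THRESHOLD_C


def _season_frame(daily: pd.DataFrame, year: int, season: str) -> pd.DataFrame:
    """Rows of `daily` inside the named season for label year `year`."""
    months = SEASON_MONTHS[season]
    idx = daily.index
    if season == "winter":
        mask = ((idx.year == year - 1) & idx.month.isin([11, 12])) | (
            (idx.year == year) & idx.month.isin([1, 2, 3])
        )
    else:
        mask = (idx.year == year) & idx.month.isin(months)
    return daily.loc[mask]


def _season_n_days(year: int, season: str) -> int:
    if season == "winter":
        return 61 + 90 + (1 if calendar.isleap(year) else 0)
    start_year = year
    return sum(calendar.monthrange(start_year, m)[1] for m in SEASON_MONTHS[season])


def _guarded(series: pd.Series, expected_n: int, max_missing_frac: float,
             reducer, label: str) -> float:
    present = series.dropna()
    if expected_n == 0 or len(present) == 0:
        log.warning("window entirely missing for %s", label)
        return np.nan
    if 1.0 - len(present) / expected_n > max_missing_frac:
        log.warning(
            "%s: %d/%d days present exceeds missing tolerance", label,
            len(present), expected_n,
        )
        return np.nan
    return float(reducer(present.to_numpy()))


def _tmean(frame: pd.DataFrame) -> pd.Series:
    """Daily mean temperature, falling back to (tmax+tmin)/2."""
    t = frame.get("tmean")
    if t is None:
        return (frame["tmax"] + frame["tmin"]) / 2.0
    fallback = (frame["tmax"] + frame["tmin"]) / 2.0
    return t.fillna(fallback)


def derive_seasonal_metrics(
    daily: pd.DataFrame, year: int, config: CovariateConfig | None = None
) -> dict[str, float]:
    """Seasonal weather summaries for label year `year` (no lagging applied).

    `daily` must be indexed by date with columns tmin/tmax (°C), optionally
    tmean, precip/snowfall/snow_depth (mm). Returns the winter metrics of the
    winter *ending* in `year`, and spring/summer/fall metrics of calendar
    year `year`. Lag alignment into a response-year table is done by
    :func:`build_predictor_table`.
    """
    cfg = config or CovariateConfig()
    out: dict[str, float] = {}

    win = _season_frame(daily, year, "winter")
    n_win = _season_n_days(year, "winter")
    tm = _tmean(win) if len(win) else pd.Series(dtype=float)
    out["mean_winter_temp"] = _guarded(tm, n_win, cfg.max_missing_frac,
                                       np.mean, f"winter tmean {year}")
    if cfg.monthly_min_mode == "monthly":
        if len(win) and win["tmin"].notna().any():
            monthly_min = win["tmin"].groupby(win.index.month).min()
            out["mean_monthly_min_winter_temp"] = (
                float(monthly_min.mean()) if len(monthly_min) == 5 else np.nan
            )
        else:
            out["mean_monthly_min_winter_temp"] = np.nan
    else:
        out["mean_monthly_min_winter_temp"] = _guarded(
            win.get("tmin", pd.Series(dtype=float)), n_win,
            cfg.max_missing_frac, np.mean, f"winter tmin {year}")
    out["total_snowfall"] = _guarded(
        win.get("snowfall", pd.Series(dtype=float)), n_win,
        cfg.max_missing_frac, np.sum, f"winter snowfall {year}")
    out["mean_snow_depth"] = _guarded(
        win.get("snow_depth", pd.Series(dtype=float)), n_win,
        cfg.max_missing_frac, np.mean, f"winter snow depth {year}")

    spr = _season_frame(daily, year, "spring")
    n_spr = _season_n_days(year, "spring")
    out["mean_spring_temp"] = _guarded(
        _tmean(spr) if len(spr) else pd.Series(dtype=float), n_spr,
        cfg.max_missing_frac, np.mean, f"spring tmean {year}")
    out["spring_precip"] = _guarded(
        spr.get("precip", pd.Series(dtype=float)), n_spr,
        cfg.max_missing_frac, np.sum, f"spring precip {year}")

    summ = _season_frame(daily, year, "summer")
    n_sum = _season_n_days(year, "summer")
    out["mean_summer_temp"] = _guarded(
        _tmean(summ) if len(summ) else pd.Series(dtype=float), n_sum,
        cfg.max_missing_frac, np.mean, f"summer tmean {year}")
    out["summer_precip"] = _guarded(
        summ.get("precip", pd.Series(dtype=float)), n_sum,
        cfg.max_missing_frac, np.sum, f"summer precip {year}")
    if len(summ):
        davg = (summ["tmax"] + summ["tmin"]) / 2.0
        gdd_daily = np.maximum(0.0, davg - GDD_BASE_C)
        out["gdd"] = _guarded(gdd_daily, n_sum, cfg.max_missing_frac,
                              np.sum, f"summer gdd {year}")
    else:
        out["gdd"] = np.nan

    fall = _season_frame(daily, year, "fall")
    n_fall = _season_n_days(year, "fall")
    out["mean_fall_temp"] = _guarded(
        _tmean(fall) if len(fall) else pd.Series(dtype=float), n_fall,
        cfg.max_missing_frac, np.mean, f"fall tmean {year}")
    out["fall_precip"] = _guarded(
        fall.get("precip", pd.Series(dtype=float)), n_fall,
        cfg.max_missing_frac, np.sum, f"fall precip {year}")
    return out


def freeze_metrics(
    daily: pd.DataFrame, year: int, config: CovariateConfig | None = None
) -> dict[str, float]:
    """First fall freeze (year−1), last spring freeze (year), winter duration.

    Freeze dates are returned as day-of-year within their own calendar year;
    winter duration is the calendar-day separation of the two dates. The
    fall search window is 1 Aug–31 Dec of year−1 and the spring window is
    1 Jan–30 Jun of `year`.
    """
    cfg = config or CovariateConfig()
    thr = cfg.freeze_threshold
    idx = daily.index

    fall_mask = (idx.year == year - 1) & (idx.month >= 8)
    fall = daily.loc[fall_mask, "tmin"].dropna()
    freezes = fall[fall <= thr]
    first_fall = freezes.index.min() if len(freezes) else None

    spring_mask = (idx.year == year) & (idx.month <= 6)
    spring = daily.loc[spring_mask, "tmin"].dropna()
    freezes = spring[spring <= thr]
    last_spring = freezes.index.max() if len(freezes) else None

    out = {
        "first_fall_freeze": float(first_fall.dayofyear) if first_fall is not None else np.nan,
        "last_spring_freeze": float(last_spring.dayofyear) if last_spring is not None else np.nan,
    }
    if first_fall is not None and last_spring is not None:
        out["winter_duration"] = float((last_spring - first_fall).days)
    else:
        if first_fall is None:
            log.warning("no fall freeze found for winter %d", year)
        if last_spring is None:
            log.warning("no spring freeze found for winter %d", year)
        out["winter_duration"] = np.nan
    return out


# ---------------------------------------------------------------------------
# Thornthwaite potential evapotranspiration
# ---------------------------------------------------------------------------

def day_length_hours(latitude: float, month: int) -> float:
    """Mean astronomical day length (h) for a calendar month at `latitude`.

    Uses the standard solar-declination / sunset-hour-angle formula averaged
    over the days of the month (non-leap calendar).
    """
    if abs(latitude) > 66.0:
        raise ValueError("latitude must be within ±66°")
    start = sum(calendar.monthrange(2001, m)[1] for m in range(1, month))
    ndays = calendar.monthrange(2001, month)[1]
    j = np.arange(start + 1, start + ndays + 1)
    phi = np.deg2rad(latitude)
    delta = 0.409 * np.sin(2 * np.pi * j / 365.0 - 1.39)
    cos_omega = np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0)
    omega = np.arccos(cos_omega)
    return float(np.mean(24.0 / np.pi * omega))


def thornthwaite_pet(monthly_mean_temp, latitude: float) -> np.ndarray:
    """Monthly Thornthwaite potential evapotranspiration (mm).

    Parameters
    ----------
    monthly_mean_temp : 12 mean temperatures (°C), January first.
    latitude : station latitude in degrees, |lat| ≤ 66.

    The heat index I sums (T/5)^1.514 over months with T > 0;
    a = 6.75e-7 I³ − 7.71e-5 I² + 1.792e-2 I + 0.49239; for T > 0,
    PET = 16 (L/12)(N/30)(10T/I)^a with L the mean day length and N the days
    in the month, else PET = 0.
    """
    t = np.asarray(monthly_mean_temp, dtype=float)
    if t.shape != (12,):
        raise ValueError("monthly_mean_temp must have 12 entries (Jan..Dec)")
    pos = t > 0
    if not pos.any():
        raise ValueError("heat index undefined: no month with T > 0 °C")
    heat_index = float(np.sum((t[pos] / 5.0) ** 1.514))
    a = (6.75e-7 * heat_index**3 - 7.71e-5 * heat_index**2
         + 1.792e-2 * heat_index + 0.49239)
    pet = np.zeros(12)
    for m in range(12):
        if t[m] <= 0:
            continue
        L = day_length_hours(latitude, m + 1)
        N = calendar.monthrange(2001, m + 1)[1]
        pet[m] = 16.0 * (L / 12.0) * (N / 30.0) * (10.0 * t[m] / heat_index) ** a
    return pet


def monthly_climate_series(daily: pd.DataFrame) -> pd.DataFrame:
    """Monthly mean temperature and total precipitation from daily records."""
    tm = _tmean(daily)
    by = pd.PeriodIndex(daily.index, freq="M")
    return pd.DataFrame({
        "tmean": tm.groupby(by).mean(),
        "precip": daily["precip"].groupby(by).sum(min_count=1),
    })


def monthly_pet_series(monthly: pd.DataFrame, latitude: float) -> pd.Series:
    """Thornthwaite PET per month for a monthly climate table.

    The heat index is computed per calendar year from that year's available
    months (all 12 for complete years).
    """
    out = {}
    for year, grp in monthly.groupby(monthly.index.year):
        t12 = np.zeros(12)
        have = np.zeros(12, dtype=bool)
        for p, v in grp["tmean"].items():
            t12[p.month - 1] = v
            have[p.month - 1] = True
        t12[~have] = 0.0  # missing months contribute nothing to I
        try:
            pet = thornthwaite_pet(t12, latitude)
        except ValueError:
            continue
        for m in range(12):
            if have[m]:
                out[pd.Period(f"{year}-{m + 1:02d}", freq="M")] = pet[m]
    return pd.Series(out).sort_index()


# ---------------------------------------------------------------------------
# SPEI: log-logistic standardization of the climatic water balance
# ---------------------------------------------------------------------------

def _unbiased_pwm(x: np.ndarray) -> tuple[float, float, float]:
    """Unbiased probability-weighted moments b0, b1, b2 of a sample."""
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    i = np.arange(1, n + 1)
    b0 = x.mean()
    b1 = np.sum((i - 1) / (n - 1) * x) / n
    b2 = np.sum((i - 1) * (i - 2) / ((n - 1) * (n - 2)) * x) / n
    return b0, b1, b2


def fit_loglogistic_pwm(x: np.ndarray) -> tuple[float, float, float]:
    """Fit a 3-parameter log-logistic distribution by unbiased PWMs.

    Returns (shape beta, scale alpha, location gamma) for the CDF
    F(x) = [1 + (alpha / (x − gamma))^beta]^(−1).
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 4 or np.ptp(x) == 0:
        raise ValueError("degenerate sample for log-logistic fit")
    b0, b1, b2 = _unbiased_pwm(x)
    # convert to (1-F)-weighted moments used by the log-logistic estimators
    w0, w1, w2 = b0, b0 - b1, b0 - 2.0 * b1 + b2
    denom = 6.0 * w1 - w0 - 6.0 * w2
    if denom == 0:
        raise ValueError("degenerate PWMs for log-logistic fit")
    beta = (2.0 * w1 - w0) / denom
    if beta <= 1.0:
        raise ValueError(f"log-logistic shape {beta:.3f} <= 1; fit invalid")
    g = _gamma_fn(1.0 + 1.0 / beta) * _gamma_fn(1.0 - 1.0 / beta)
    alpha = (w0 - 2.0 * w1) * beta / g
    loc = w0 - alpha * g
    return beta, alpha, loc


def _loglogistic_cdf(x, beta, alpha, loc):
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    above = x > loc
    out[above] = 1.0 / (1.0 + (alpha / (x[above] - loc)) ** beta)
    return out


_INDEX_CLIP = (1e-8, 1 - 1e-8)  # keeps the normal quantile finite


def spei_index(
    monthly_precip: pd.Series,
    monthly_pet: pd.Series,
    scale_k: int,
    calibration: tuple[int, int],
) -> pd.Series:
    """SPEI at time scale `scale_k` months.

    The climatic water balance D = P − PET is summed over trailing
    `scale_k`-month windows; for each calendar month separately a
    3-parameter log-logistic distribution is fit by unbiased PWMs over the
    calibration years and the aggregate balance is mapped through the fitted
    CDF to standard-normal deviates.

    Series are indexed by monthly ``pd.Period``; `calibration` is an
    inclusive (start year, end year) span.
    """
    d = (monthly_precip - monthly_pet).dropna().sort_index()
    agg = d.rolling(scale_k).sum().dropna()
    # windows spanning gaps in the monthly record are invalid
    steps = np.diff(agg.index.asi8)
    idx_ok = np.concatenate([[True], steps == 1])
    if len(agg) and not idx_ok.all():
        agg = agg[idx_ok]
    start, end = calibration
    out = pd.Series(index=agg.index, dtype=float)
    for month in range(1, 13):
        sel = agg.index.month == month
        vals = agg[sel]
        calib = vals[(vals.index.year >= start) & (vals.index.year <= end)]
        if len(calib) < 30:
            raise ValueError(
                f"insufficient calibration data for month {month}: {len(calib)} < 30"
            )
        try:
            beta, alpha, loc = fit_loglogistic_pwm(calib.to_numpy())
            cdf = _loglogistic_cdf(vals.to_numpy(), beta, alpha, loc)
            out[sel] = ndtri(np.clip(cdf, *_INDEX_CLIP))
        except ValueError:
            # the log-logistic only represents non-negative skew; for
            # negatively skewed months fit the reflected balance and negate
            beta, alpha, loc = fit_loglogistic_pwm(-calib.to_numpy())
            cdf = _loglogistic_cdf(-vals.to_numpy(), beta, alpha, loc)
            out[sel] = -ndtri(np.clip(cdf, *_INDEX_CLIP))
    return out


def seasonal_spei(
    daily: pd.DataFrame,
    latitude: float,
    scale_k: int,
    month: int,
    config: CovariateConfig | None = None,
) -> pd.Series:
    """Year-indexed SPEI sampled in a fixed calendar month.

    The forest index is the July value at a 6-month scale; the grassland
    index is the September value at a 3-month scale (aggregating exactly the
    Jul+Aug+Sep balances).
    """
    cfg = config or CovariateConfig()
    monthly = monthly_climate_series(daily)
    pet = monthly_pet_series(monthly, latitude)
    idx = spei_index(monthly["precip"], pet, scale_k, cfg.spei_calibration)
    sel = idx[idx.index.month == month]
    return pd.Series(sel.to_numpy(), index=sel.index.year)


# ---------------------------------------------------------------------------
# Timber-stand age classes
# ---------------------------------------------------------------------------

TIMBER_CLASSES = ("timber_age_lt1", "timber_age_1_5", "timber_age_6_30",
                  "timber_age_gt30", "timber_total")


def timber_age_class_areas(stands: pd.DataFrame, year: int) -> dict[str, float]:
    """Areas (km²) of harvested stands by age class in `year`.

    Stand age = year − harvest_year; classes: clear-cut (age 0), early
    regeneration (1–5), late regeneration (6–30), mature (>30), plus the
    total harvested area.
    """
    out = dict.fromkeys(TIMBER_CLASSES, 0.0)
    if stands is None or len(stands) == 0:
        return out
    ages = year - stands["harvest_year"].to_numpy()
    if (ages < 0).any():
        raise ValueError(f"stand harvested after query year {year}")
    area = stands["area"].to_numpy(dtype=float)
    out["timber_age_lt1"] = float(area[ages == 0].sum())
    out["timber_age_1_5"] = float(area[(ages >= 1) & (ages <= 5)].sum())
    out["timber_age_6_30"] = float(area[(ages >= 6) & (ages <= 30)].sum())
    out["timber_age_gt30"] = float(area[ages > 30].sum())
    out["timber_total"] = float(area.sum())
    return out


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

@dataclass
class PredictorTableSpec:
    """Inputs and alignment rules for building the annual predictor table."""

    years: range
    latitude: float = 58.0
    config: CovariateConfig = field(default_factory=CovariateConfig)


def build_predictor_table(
    daily: pd.DataFrame,
    spec: PredictorTableSpec,
    stands: pd.DataFrame | None = None,
    bear_abundance: pd.Series | None = None,
) -> pd.DataFrame:
    """Assemble the full predictor table, one row per response year t.

    Winter (ending year t), spring (year t), last spring freeze and winter
    duration are contemporaneous; summer, fall, growing degree days, SPEI,
    first fall freeze, and timber areas are taken from year t−1 (maternal
    carryover / habitat lag); bear abundance is contemporaneous.
    """
    cfg = spec.config
    rows = {}
    try:
        spei_forest = seasonal_spei(daily, spec.latitude, cfg.spei6_months, 7, cfg)
        spei_grass = seasonal_spei(daily, spec.latitude, 3, 9, cfg)
    except ValueError as exc:
        log.warning("SPEI unavailable: %s", exc)
        spei_forest = pd.Series(dtype=float)
        spei_grass = pd.Series(dtype=float)

    for year in spec.years:
        row: dict[str, float] = {}
        current = derive_seasonal_metrics(daily, year, cfg)
        prior = derive_seasonal_metrics(daily, year - 1, cfg)
        for key in ("mean_winter_temp", "mean_monthly_min_winter_temp",
                    "total_snowfall", "mean_snow_depth",
                    "mean_spring_temp", "spring_precip"):
            row[key] = current[key]
        for key in ("mean_summer_temp", "summer_precip", "gdd",
                    "mean_fall_temp", "fall_precip"):
            row[key] = prior[key]
        fz = freeze_metrics(daily, year, cfg)
        row["first_fall_freeze"] = fz["first_fall_freeze"]
        row["last_spring_freeze"] = fz["last_spring_freeze"]
        row["winter_duration"] = fz["winter_duration"]
        row["spei_forest"] = float(spei_forest.get(year - 1, np.nan))
        row["spei_grassland"] = float(spei_grass.get(year - 1, np.nan))
        if stands is not None:
            usable = stands[stands["harvest_year"] <= year - 1]
            row.update(timber_age_class_areas(usable, year - 1))
        if bear_abundance is not None:
            row["bear_abundance"] = float(bear_abundance.get(year, np.nan))
        rows[year] = row
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    table.index.name = "year"
    return table
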
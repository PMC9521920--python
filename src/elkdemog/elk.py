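"""Elk composition/count ingestion, filtering, aggregation, and trends.

Composition surveys report cows, calves, and bulls per herd; the response
modeled is the age ratio — calves per 100 adult females — pooled over the
herds in a group (counts are summed before dividing, never averaged across
herds). Records are screened for known survey failure modes before pooling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

#: reason codes attached to the exclusion log
REASON_CALVES_EXCEED_COWS = "calves_exceed_cows"
REASON_ZERO_CALVES = "zero_calves"
REASON_ADULTS_UNKNOWN = "adults_unknown"
REASON_HERD_BLOCKED = "herd_blocklisted"
REASON_GROUP_TOTAL = "group_total_below_min"


@dataclass
class FilterResult:
    retained: pd.DataFrame
    exclusions: pd.DataFrame  # columns: year, herd, reason


def filter_composition_counts(
    records: pd.DataFrame,
    min_group_total: int = 5,
    herd_blocklist: tuple[str, ...] = (),
) -> FilterResult:
    """Screen herd composition records before pooling.

    Drops records where calves exceed cows (recording error or partial
    group), where zero calves were counted (survey too late to distinguish
    calves), where adults were not sexed (cows missing), and blocklisted
    herds (e.g. herds whose canopy cover precludes accurate counts). After
    record-level screening, any survey year whose summed group total
    (cows+calves+bulls) is ≤ `min_group_total` is dropped whole.

    Every drop is logged with a reason code; filtering is idempotent.
    """
    df = records.copy()
    excl: list[dict] = []

    def _drop(mask: pd.Series, reason: str) -> None:
        nonlocal df
        for _, r in df[mask].iterrows():
            excl.append({"year": r["year"], "herd": r.get("herd", ""),
                         "reason": reason})
        df = df[~mask]

    if herd_blocklist:
        _drop(df["herd"].isin(herd_blocklist), REASON_HERD_BLOCKED)
    _drop(df["cows"].isna(), REASON_ADULTS_UNKNOWN)
    _drop(df["calves"] > df["cows"], REASON_CALVES_EXCEED_COWS)
    _drop(df["calves"] == 0, REASON_ZERO_CALVES)

    totals = (
        df[["cows", "calves"]].sum(axis=1)
        + df.get("bulls", pd.Series(0, index=df.index)).fillna(0)
    ).groupby(df["year"]).sum()
    bad_years = totals[totals <= min_group_total].index
    _drop(df["year"].isin(bad_years), REASON_GROUP_TOTAL)

    exclusions = pd.DataFrame(excl, columns=["year", "herd", "reason"])
    if len(exclusions):
        log.info("excluded %d composition records (%s)", len(exclusions),
                 exclusions["reason"].value_counts().to_dict())
    return FilterResult(df.reset_index(drop=True), exclusions)


def aggregate_age_ratios(records: pd.DataFrame) -> pd.Series:
    """Pooled age ratio per year: 100 × Σ calves / Σ cows over group herds.

    `records` must already be filtered. Years whose pooled cow count is zero
    are omitted (logged).
    """
    grouped = records.groupby("year")[["cows", "calves"]].sum()
    zero = grouped["cows"] == 0
    if zero.any():
        log.warning("omitting years with zero pooled cows: %s",
                    list(grouped.index[zero]))
        grouped = grouped[~zero]
    ratio = 100.0 * grouped["calves"] / grouped["cows"]
    ratio.name = "age_ratio"
    return ratio


@dataclass
class CountSeries:
    """September counts with post-count harvest and imputation flags."""

    counts: pd.Series
    harvest: pd.Series | None = None
    imputed: pd.Series = field(default_factory=lambda: pd.Series(dtype=bool))


def interpolate_missing_counts(counts: pd.Series) -> CountSeries:
    """Fill interior missing years by linear interpolation.

    The first and last years must be observed; the returned flags mark
    imputed years. Values at observed years are untouched.
    """
    s = counts.sort_index()
    full = s.reindex(range(int(s.index.min()), int(s.index.max()) + 1))
    if np.isnan(full.iloc[0]) or np.isnan(full.iloc[-1]):
        raise ValueError("leading/trailing years must be observed")
    filled = full.interpolate(method="index")
    imputed = full.isna()
    if imputed.any():
        log.info("interpolated count years: %s", list(full.index[imputed]))
    return CountSeries(filled, imputed=imputed)


def standardize_predictors(
    table: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Z-score each column by its sample mean and SD over the given rows.

    Returns the standardized table and a scaling table (mean, sd per column)
    for back-transformation. Standardization must be done over exactly the
    years entering a model, so slice first, then standardize.
    """
    means = table.mean()
    sds = table.std(ddof=1)
    constant = sds[(sds == 0) | sds.isna()]
    if len(constant):
        raise ValueError(
            f"constant or empty predictor column(s): {list(constant.index)}"
        )
    z = (table - means) / sds
    scaling = pd.DataFrame({"mean": means, "sd": sds})
    return z, scaling


def linear_trend(series: pd.Series) -> dict[str, float]:
    """OLS of a value on calendar year with a two-sided t-test on the slope."""
    s = series.dropna()
    if len(s) < 3:
        raise ValueError("need at least 3 points for a trend")
    res = stats.linregress(s.index.to_numpy(dtype=float), s.to_numpy())
    return {
        "slope": res.slope,
        "intercept": res.intercept,
        "r2": res.rvalue**2,
        "t": res.slope / res.stderr,
        "p": res.pvalue,
        "n": len(s),
    }
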
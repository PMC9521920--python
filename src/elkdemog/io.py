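"""Delimited-text readers and writers for the pipeline's tabular formats.

All tables are plain CSV with a header row; dates are ISO-8601; missing
values are empty fields. Weather files may use GHCN-Daily-style column
names via a column-mapping dict.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

#: accepted aliases for daily-weather columns (lowercased header -> field)
DEFAULT_WEATHER_COLUMNS = {
    "date": "date", "tmin": "tmin", "tmax": "tmax", "tavg": "tmean",
    "tmean": "tmean", "prcp": "precip", "precip": "precip",
    "snow": "snowfall", "snowfall": "snowfall", "snwd": "snow_depth",
    "snow_depth": "snow_depth",
}


def read_daily_weather(
    path: str | Path, column_map: dict[str, str] | None = None
) -> pd.DataFrame:
    """Read a daily weather table into a date-indexed frame (°C / mm)."""
    mapping = dict(DEFAULT_WEATHER_COLUMNS)
    if column_map:
        mapping.update({k.lower(): v for k, v in column_map.items()})
    df = pd.read_csv(path)
    df.columns = [c.lower() for c in df.columns]
    df = df.rename(columns={c: mapping[c] for c in df.columns if c in mapping})
    if "date" not in df.columns:
        raise ValueError(f"{path}: no date column found")
    df["date"] = pd.to_datetime(df["date"])
    return df.set_index("date").sort_index()


def write_daily_weather(daily: pd.DataFrame, path: str | Path) -> None:
    daily.to_csv(path, index_label="date", float_format="%.2f")


def read_mortality_records(path: str | Path) -> pd.DataFrame:
    """Bear mortality table: year, class_* (or age_*) counts, total_mortalities."""
    df = pd.read_csv(path)
    if "year" not in df.columns or "total_mortalities" not in df.columns:
        raise ValueError(f"{path}: need 'year' and 'total_mortalities' columns")
    return df


def write_mortality_records(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False)


def read_composition(path: str | Path) -> pd.DataFrame:
    """Herd composition counts: year, herd, cows, calves, bulls."""
    df = pd.read_csv(path)
    missing = {"year", "herd", "cows", "calves"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_composition(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False)


def read_count_series(path: str | Path) -> tuple[pd.Series, pd.Series | None]:
    """September count + harvest table: year, count[, harvest]."""
    df = pd.read_csv(path).set_index("year").sort_index()
    counts = df["count"]
    harvest = df["harvest"] if "harvest" in df.columns else None
    return counts, harvest


def write_count_series(
    counts: pd.Series, harvest: pd.Series | None, path: str | Path
) -> None:
    out = counts.rename("count").to_frame()
    if harvest is not None:
        out["harvest"] = harvest
    out.to_csv(path, index_label="year")


def read_stands(path: str | Path) -> pd.DataFrame:
    """Timber stand table: harvest_year, area (km²)."""
    df = pd.read_csv(path)
    if (df["area"] <= 0).any():
        raise ValueError(f"{path}: stand areas must be positive")
    return df[["harvest_year", "area"]]


def write_table(df: pd.DataFrame, path: str | Path, **kwargs) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, **kwargs)
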
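"""Weather file I/O: plain CSV and the DSSAT WTH fixed-column dialect."""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .weather import DailyWeatherSeries

__all__ = ["read_weather_csv", "write_weather_csv", "read_wth", "write_wth"]

PathLike = Union[str, Path]


def write_weather_csv(series: DailyWeatherSeries, path: PathLike) -> None:
    """CSV with header date,tmax,tmin,rain,srad; empty cell = missing."""
    df = series.frame.copy()
    df["date"] = df["date"].dt.strftime("%Y-%m-%d")
    df[["date", "tmax", "tmin", "rain", "srad"]].to_csv(path, index=False, float_format="%.3f")


def read_weather_csv(path: PathLike) -> DailyWeatherSeries:
    df = pd.read_csv(path, parse_dates=["date"])
    required = {"date", "tmax", "tmin", "rain", "srad"}
    if not required.issubset(df.columns):
        raise ConfigurationError(f"weather CSV must carry columns {sorted(required)}")
    df = df.sort_values("date").reset_index(drop=True)
    df["day"] = np.arange(len(df))
    df["tavg"] = np.nan
    return DailyWeatherSeries(df[["date", "day", "tmax", "tmin", "tavg", "rain", "srad"]])


def write_wth(
    series: DailyWeatherSeries,
    path: PathLike,
    station: str = "TDAR",
    latitude: float = 24.0,
    longitude: float = 120.9,
    elevation: float = 19.0,
) -> None:
    """Write the DSSAT weather dialect (station header; DATE SRAD TMAX TMIN RAIN).

    DATE is YYDDD (2-digit year, day of year).  Missing values are written
    as the conventional -99 sentinel.
    """
    df = series.frame
    lines = [
        f"*WEATHER DATA : {station}",
        "",
        "@ INSI      LAT     LONG  ELEV   TAV   AMP REFHT WNDHT",
        f"  {station:<4} {latitude:8.3f} {longitude:8.3f} {elevation:5.0f}  23.0   8.0  1.50  2.00",
        "@DATE  SRAD  TMAX  TMIN  RAIN",
    ]

    def fmt(v: float) -> str:
        return f"{v:5.1f}" if pd.notna(v) else f"{-99.0:5.1f}"

    for _, row in df.iterrows():
        ts = row["date"]
        yyddd = f"{ts.year % 100:02d}{ts.dayofyear:03d}"
        lines.append(f"{yyddd} {fmt(row['srad'])} {fmt(row['tmax'])} {fmt(row['tmin'])} {fmt(row['rain'])}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_wth(path: PathLike, century: int = 2000) -> DailyWeatherSeries:
    """Read the DSSAT weather dialect written by :func:`write_wth`.

    Two-digit years are resolved against ``century`` (YY < 50 maps into it).
    The -99 sentinel becomes a missing value.
    """
    rows = []
    in_data = False
    for raw in Path(path).read_text().splitlines():
        line = raw.rstrip()
        if not line:
            continue
        if line.startswith("@DATE"):
            in_data = True
            continue
        if line.startswith(("*", "@")) or not in_data:
            continue
        parts = line.split()
        if len(parts) < 5:
            raise ConfigurationError(f"malformed WTH data line: {line!r}")
        yyddd, srad, tmax, tmin, rain = parts[:5]
        yy, ddd = int(yyddd[:2]), int(yyddd[2:])
        year = century + yy if yy < 50 else century - 100 + yy
        date = pd.Timestamp(year, 1, 1) + pd.Timedelta(days=ddd - 1)

        def val(s: str) -> float:
            v = float(s)
            return np.nan if v <= -99.0 else v

        rows.append((date, val(tmax), val(tmin), val(rain), val(srad)))
    if not rows:
        raise ConfigurationError(f"no data lines found in {path}")
    df = pd.DataFrame(rows, columns=["date", "tmax", "tmin", "rain", "srad"])
    df = df.sort_values("date").reset_index(drop=True)
    df["day"] = np.arange(len(df))
    df["tavg"] = np.nan
    return DailyWeatherSeries(df[["date", "day", "tmax", "tmin", "tavg", "rain", "srad"]])
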
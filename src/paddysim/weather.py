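"""Synthetic daily weather, gap repair and seasonal climate summaries.

The analysis downstream (crop simulation, deficit-irrigation scenarios,
yield-response modelling) needs daily maximum/minimum temperature,
precipitation and solar radiation for a rice growing season.  This module
provides

* a stochastic season generator that reproduces the two features the
  scenario analysis depends on: contrasting rainfall *timing* between the
  spring crop (rain arrives late in the season) and the autumn crop (rain
  arrives early, with occasional heavy typhoon-like bursts), and a
  configurable seasonal precipitation total so that simulated years span
  the dry (<500 mm), intermediate (500-1000 mm) and wet (>1000 mm) strata;
* missing-value imputation rules for observational records (neighbour
  station transfer, adjacent-day temperature averaging, monthly means for
  rain and radiation);
* growing-degree-day and accumulation summaries over the standard three
  growth-stage windows.

Weather series are plain pandas DataFrames wrapped in a thin container so
invariants (tmax >= tmin, non-negative rain/srad) are checked in one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, UnrecoverableRecordError, WindowBoundsError

__all__ = [
    "DailyWeatherSeries",
    "SeasonSpec",
    "StageWindows",
    "ClimateSummary",
    "SPRING_DEFAULT",
    "AUTUMN_DEFAULT",
    "generate_season_weather",
    "impute_missing",
    "climate_summary",
]

#: Conventional base temperature for rice thermal-time accumulation (degC).
T_BASE_DEFAULT = 10.0

_COLUMNS = ["date", "day", "tmax", "tmin", "tavg", "rain", "srad"]


class DailyWeatherSeries:
    """A dated daily weather record for one growing season.

    Parameters
    ----------
    frame : pandas.DataFrame
        Columns ``date`` (Timestamp), ``day`` (days after transplanting,
        0-based), ``tmax``, ``tmin``, ``tavg`` (degC), ``rain`` (mm/day),
        ``srad`` (MJ/m2/day).  ``NaN`` marks a missing value.  ``tavg`` is
        derived as ``(tmax + tmin) / 2`` wherever it is absent but both
        extremes are present.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in _COLUMNS if c not in frame.columns]
        if missing:
            raise ConfigurationError(f"weather frame missing columns: {missing}")
        frame = frame.loc[:, _COLUMNS].reset_index(drop=True).copy()
        # derive tavg where possible
        derivable = frame["tavg"].isna() & frame["tmax"].notna() & frame["tmin"].notna()
        frame.loc[derivable, "tavg"] = (
            frame.loc[derivable, "tmax"] + frame.loc[derivable, "tmin"]
        ) / 2.0
        bad = (frame["tmax"] < frame["tmin"]).fillna(False)
        if bad.any():
            raise ConfigurationError(
                f"tmax < tmin on {int(bad.sum())} day(s), first at row {int(bad.idxmax())}"
            )
        for col in ("rain", "srad"):
            neg = (frame[col] < 0).fillna(False)
            if neg.any():
                raise ConfigurationError(f"negative {col} on {int(neg.sum())} day(s)")
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, DailyWeatherSeries):
            return NotImplemented
        return self.frame.equals(other.frame)

    @property
    def has_missing(self) -> bool:
        return bool(self.frame[["tmax", "tmin", "tavg", "rain", "srad"]].isna().any().any())

    def total_rain(self) -> float:
        """Accumulated precipitation over the whole series (mm)."""
        return float(self.frame["rain"].sum())

    def copy(self) -> "DailyWeatherSeries":
        return DailyWeatherSeries(self.frame.copy())


@dataclass(frozen=True)
class SeasonSpec:
    """Configuration of one synthetic cropping season.

    Temperature and radiation follow linear seasonal ramps with i.i.d.
    Gaussian noise.  Rainfall is a wet/dry Bernoulli daily process with
    gamma-distributed wet-day amounts; a day-position weight concentrates
    rainfall mass late in the season (``rainfall_timing='late'``, the
    spring-crop pattern) or early (``'early'``, the autumn-crop pattern).
    Autumn seasons additionally carry a Poisson number of heavy convective
    events (typhoon bursts) placed with the same timing weight.

    ``target_precip_total`` is the *expected* seasonal accumulated rainfall;
    amounts are scaled so the expectation is met exactly, with realised
    totals varying stochastically around it.
    """

    season: str  # "spring" | "autumn"
    transplant_doy: int
    n_days: int
    year: int = 2001
    latitude: float = 24.0
    rainfall_timing: Optional[str] = None  # "late" | "early" | None (uniform)
    target_precip_total: float = 600.0
    precip_dispersion: float = 0.45  # lognormal sigma of year-to-year target draws
    wet_prob: float = 0.30
    rain_shape: float = 0.7  # gamma shape of wet-day amounts; 0 => deterministic
    heavy_event_rate: float = 0.0  # expected heavy events per season
    heavy_event_mean: float = 90.0  # mm per heavy event
    tmax_start: float = 24.0
    tmax_end: float = 32.0
    trange_mean: float = 9.0
    temp_noise_sd: float = 1.6
    srad_start: float = 13.0
    srad_end: float = 18.0
    srad_noise_sd: float = 3.0

    def __post_init__(self):
        if self.season not in ("spring", "autumn"):
            raise ConfigurationError(f"unknown season {self.season!r}")
        if self.n_days <= 0:
            raise ConfigurationError("n_days must be positive")
        if self.target_precip_total < 0 or self.precip_dispersion < 0:
            raise ConfigurationError("precipitation targets must be non-negative")
        if not 0.0 <= self.wet_prob <= 1.0:
            raise ConfigurationError("wet_prob must lie in [0, 1]")
        if self.rainfall_timing not in (None, "late", "early"):
            raise ConfigurationError(f"unknown rainfall_timing {self.rainfall_timing!r}")
        if self.temp_noise_sd < 0 or self.srad_noise_sd < 0 or self.rain_shape < 0:
            raise ConfigurationError("noise scales must be non-negative")

    def with_year(self, year: int, target_precip_total: Optional[float] = None) -> "SeasonSpec":
        if target_precip_total is None:
            return replace(self, year=year)
        return replace(self, year=year, target_precip_total=target_precip_total)


# Defaults emulate the Taichung basin (24 deg N): spring transplanting in
# early March with rainfall arriving with the plum-rain front late in the
# season; autumn transplanting in late July with early-season convective and
# typhoon rainfall, cooling towards harvest.
SPRING_DEFAULT = SeasonSpec(
    season="spring",
    transplant_doy=61,
    n_days=130,
    rainfall_timing="late",
    target_precip_total=550.0,
    wet_prob=0.45,
    tmax_start=23.0,
    tmax_end=32.0,
    trange_mean=9.5,
    srad_start=12.0,
    srad_end=18.0,
)

AUTUMN_DEFAULT = SeasonSpec(
    season="autumn",
    transplant_doy=208,
    n_days=100,
    rainfall_timing="early",
    target_precip_total=650.0,
    precip_dispersion=0.50,
    wet_prob=0.45,
    heavy_event_rate=1.5,
    heavy_event_mean=90.0,
    tmax_start=33.0,
    tmax_end=26.0,
    trange_mean=8.0,
    srad_start=18.0,
    srad_end=13.0,
)


def _timing_weight(n: int, timing: Optional[str]) -> np.ndarray:
    """Relative rainfall weight per day; mean normalised to 1."""
    if timing is None or n == 1:
        return np.ones(n)
    pos = np.linspace(0.0, 1.0, n)
    if timing == "late":
        w = 0.55 + 1.6 * pos**2
    else:  # early
        w = 0.55 + 1.6 * (1.0 - pos) ** 2
    return w / w.mean()


def generate_season_weather(spec: SeasonSpec, seed: Optional[int] = None) -> DailyWeatherSeries:
    """Draw one season of daily weather from the configured process.

    The same ``spec`` and ``seed`` always produce an identical series.  The
    expected seasonal rainfall total equals ``spec.target_precip_total``:
    the heavy-event budget (``heavy_event_rate * heavy_event_mean``) is
    carved out of the target first and the background wet-day amounts are
    scaled to supply the remainder.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_days
    pos = np.linspace(0.0, 1.0, n) if n > 1 else np.zeros(1)

    tmax = spec.tmax_start + (spec.tmax_end - spec.tmax_start) * pos
    tmax = tmax + rng.normal(0.0, spec.temp_noise_sd, n) if spec.temp_noise_sd > 0 else tmax
    trange = np.maximum(
        0.1,
        spec.trange_mean
        + (rng.normal(0.0, spec.temp_noise_sd, n) if spec.temp_noise_sd > 0 else 0.0),
    )
    tmin = tmax - trange

    srad = spec.srad_start + (spec.srad_end - spec.srad_start) * pos
    srad = srad + rng.normal(0.0, spec.srad_noise_sd, n) if spec.srad_noise_sd > 0 else srad
    srad = np.maximum(0.05, srad)

    # --- rainfall -------------------------------------------------------
    w = _timing_weight(n, spec.rainfall_timing)
    p_wet = np.clip(spec.wet_prob * w, 0.0, 1.0)
    heavy_budget = spec.heavy_event_rate * spec.heavy_event_mean
    background_budget = max(0.0, spec.target_precip_total - heavy_budget)
    denom = float(np.sum(p_wet * w))
    scale = background_budget / denom if denom > 0 else 0.0
    mean_amount = scale * w  # E[total] = sum(p_wet * mean_amount) = budget

    wet = rng.random(n) < p_wet
    if spec.rain_shape > 0:
        amounts = np.where(
            mean_amount > 0,
            rng.gamma(spec.rain_shape, np.maximum(mean_amount, 1e-300) / spec.rain_shape),
            0.0,
        )
    else:
        amounts = mean_amount.copy()
    rain = np.where(wet, amounts, 0.0)

    if spec.heavy_event_rate > 0:
        n_events = rng.poisson(spec.heavy_event_rate)
        if n_events > 0:
            days = rng.choice(n, size=n_events, p=w / w.sum())
            sizes = rng.gamma(2.0, spec.heavy_event_mean / 2.0, n_events)
            np.add.at(rain, days, sizes)

    start = pd.Timestamp(spec.year, 1, 1) + pd.Timedelta(days=spec.transplant_doy - 1)
    frame = pd.DataFrame(
        {
            "date": pd.date_range(start, periods=n, freq="D"),
            "day": np.arange(n),
            "tmax": tmax,
            "tmin": tmin,
            "tavg": np.nan,
            "rain": rain,
            "srad": srad,
        }
    )
    return DailyWeatherSeries(frame)


# ---------------------------------------------------------------------------
# Missing-value imputation
# ---------------------------------------------------------------------------

_TEMP_COLS = ("tmax", "tmin", "tavg")


def impute_missing(
    series: DailyWeatherSeries, neighbor: Optional[DailyWeatherSeries] = None
) -> DailyWeatherSeries:
    """Fill gaps in a daily weather record.

    Temperatures are first transferred from a neighbouring station, when one
    is supplied, as ``neighbor value + mean(self - neighbor)`` over jointly
    observed days (a bias-correcting same-day transfer).  Any temperature
    gap that remains is filled with the mean of the two adjacent days.
    Rain and radiation gaps are filled with that calendar month's mean of
    the observed values in the same series.

    Raises
    ------
    UnrecoverableRecordError
        If a temperature gap sits at the series boundary (no two adjacent
        days) or persists after adjacent-day filling, or if a month has no
        observed rain/srad value at all.
    """
    df = series.frame.copy()

    if neighbor is not None:
        ndf = neighbor.frame.set_index("date")
        for col in _TEMP_COLS:
            if not df[col].isna().any():
                continue
            nb = df["date"].map(ndf[col])
            both = df[col].notna() & nb.notna()
            if both.any():
                offset = float((df.loc[both, col] - nb[both]).mean())
                fill = df[col].isna() & nb.notna()
                df.loc[fill, col] = nb[fill] + offset

    for col in _TEMP_COLS:
        gaps = np.flatnonzero(df[col].isna().to_numpy())
        for i in gaps:
            if i == 0 or i == len(df) - 1:
                raise UnrecoverableRecordError(
                    f"{col} missing at series boundary (row {i}); no two adjacent days"
                )
            lo, hi = df[col].iloc[i - 1], df[col].iloc[i + 1]
            if pd.isna(lo) or pd.isna(hi):
                raise UnrecoverableRecordError(
                    f"{col} gap at row {i} flanked by another gap; cannot average adjacent days"
                )
            df.iloc[i, df.columns.get_loc(col)] = (lo + hi) / 2.0

    month = df["date"].dt.month
    for col in ("rain", "srad"):
        if not df[col].isna().any():
            continue
        monthly = df.groupby(month)[col].transform("mean")
        gaps = df[col].isna()
        if monthly[gaps].isna().any():
            bad = sorted(month[gaps & monthly.isna()].unique())
            raise UnrecoverableRecordError(f"{col}: month(s) {bad} have no observed values")
        df.loc[gaps, col] = monthly[gaps]

    # re-derive tavg where it was absent but extremes are now known
    return DailyWeatherSeries(df)


# ---------------------------------------------------------------------------
# Stage windows and climate summaries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StageWindows:
    """Inclusive day-after-transplanting intervals for the three growth stages.

    Initial (transplanting to tillering initiation) spans days 0-20 in both
    seasons; the vegetative stage (tillering to panicle initiation) runs to
    day 50 in spring and day 40 in autumn; the reproductive stage covers the
    remainder to harvest.
    """

    initial: tuple[int, int]
    vegetative: tuple[int, int]
    reproductive: tuple[int, int]

    def __post_init__(self):
        ivals = [self.initial, self.vegetative, self.reproductive]
        for lo, hi in ivals:
            if lo > hi:
                raise ConfigurationError(f"empty window ({lo}, {hi})")
        for (a, b), (c, _d) in zip(ivals, ivals[1:]):
            if c != b + 1:
                raise ConfigurationError("windows must be contiguous, ordered, non-overlapping")

    @classmethod
    def for_season(cls, season: str, harvest_day: int) -> "StageWindows":
        veg_end = 50 if season == "spring" else 40
        if harvest_day <= veg_end:
            raise ConfigurationError("harvest_day must exceed the vegetative window")
        return cls((0, 20), (21, veg_end), (veg_end + 1, harvest_day))

    @property
    def last_day(self) -> int:
        return self.reproductive[1]


@dataclass(frozen=True)
class ClimateSummary:
    """The eleven seasonal climate covariates used in the yield correlations."""

    year: int
    acc_temp: float
    gdd: float
    acc_precip: float
    acc_srad: float
    acc_temp_initial: float
    acc_temp_vegetative: float
    acc_temp_reproductive: float
    gdd_initial: float
    gdd_vegetative: float
    gdd_reproductive: float

    _FIELDS = (
        "year",
        "acc_temp",
        "gdd",
        "acc_precip",
        "acc_srad",
        "acc_temp_initial",
        "acc_temp_vegetative",
        "acc_temp_reproductive",
        "gdd_initial",
        "gdd_vegetative",
        "gdd_reproductive",
    )

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self._FIELDS}


def climate_summary(
    series: DailyWeatherSeries, windows: StageWindows, t_base: float = T_BASE_DEFAULT
) -> ClimateSummary:
    """Accumulate temperature, GDD, rain and radiation over a season.

    Daily GDD is ``max(0, tavg - t_base)``; accumulated temperature sums
    ``tavg`` over all days (no floor).  Whole-season accumulations run over
    the entire series; stage accumulations over the three windows.
    """
    df = series.frame
    if series.has_missing:
        raise UnrecoverableRecordError("summaries require an imputed (gap-free) series")
    if windows.last_day >= len(df):
        raise WindowBoundsError(
            f"windows extend to day {windows.last_day} but series has {len(df)} days"
        )
    tavg = df["tavg"].to_numpy()
    gdd_day = np.maximum(0.0, tavg - t_base)

    def _stage(arr, window):
        lo, hi = window
        return float(arr[lo : hi + 1].sum())

    return ClimateSummary(
        year=int(df["date"].iloc[0].year),
        acc_temp=float(tavg.sum()),
        gdd=float(gdd_day.sum()),
        acc_precip=float(df["rain"].sum()),
        acc_srad=float(df["srad"].sum()),
        acc_temp_initial=_stage(tavg, windows.initial),
        acc_temp_vegetative=_stage(tavg, windows.vegetative),
        acc_temp_reproductive=_stage(tavg, windows.reproductive),
        gdd_initial=_stage(gdd_day, windows.initial),
        gdd_vegetative=_stage(gdd_day, windows.vegetative),
        gdd_reproductive=_stage(gdd_day, windows.reproductive),
    )
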
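"""Deficit-irrigation scenario engine.

For each (cultivar, season, year) a fully-irrigated baseline is simulated
with demand-triggered flood irrigation (refill to field capacity when
plant-available water falls below 50% of capacity over the 30 cm managed
depth), and its irrigation schedule is recorded.  The schedule is then
replayed under two treatments:

* ``water_saving`` — every recorded application scaled to ``(1 - s)`` of
  the recorded amount, for saving proportions s in {0, 0.2, ..., 1.0};
* ``sensitive_stage`` — the same, except applications falling between
  panicle initiation and heading (the water-sensitive window, taken from
  the baseline run's own phenology) stay at the full recorded amount.

Note the axis convention: s is the *saving* proportion, so an "80% of the
full amount" treatment corresponds to s = 0.2.  Yield ratios are reported
rounded half-up to 2 decimals, with full precision retained internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

import pandas as pd

from .cultivars import CULTIVARS, GenotypeParams
from .exceptions import ConfigurationError, DegenerateBaselineError
from .simulator import (
    AutoIrrigationPolicy,
    Forcing,
    ManagementPlan,
    ScheduledFractionPolicy,
    SimConfig,
    SimulationResult,
    SoilProfile,
    prepare_forcing,
    run_simulation,
)
from .weather import DailyWeatherSeries

__all__ = ["TreatmentGrid", "yield_ratio", "run_baseline", "run_grid", "grid_means", "to_wide_table"]

TREATMENTS = ("water_saving", "sensitive_stage")
DEFAULT_LEVELS = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass(frozen=True)
class TreatmentGrid:
    """Cross-product of cultivars, seasons, years, treatments and saving levels."""

    cultivars: tuple
    seasons: tuple
    years: tuple
    treatments: tuple = TREATMENTS
    levels: tuple = DEFAULT_LEVELS

    def __post_init__(self):
        if not self.cultivars or not self.seasons or not self.years:
            raise ConfigurationError("grid axes must be non-empty")
        if list(self.levels) != sorted(self.levels):
            raise ConfigurationError("saving levels must be sorted ascending")
        if self.levels[0] != 0.0:
            raise ConfigurationError("level 0 (fully irrigated reference) is required")
        if any(not 0.0 <= s <= 1.0 for s in self.levels):
            raise ConfigurationError("saving levels must lie in [0, 1]")
        unknown = set(self.treatments) - set(TREATMENTS)
        if unknown:
            raise ConfigurationError(f"unknown treatments {sorted(unknown)}")


def yield_ratio(ws_yield: float, full_yield: float) -> float:
    """Deficit-to-full yield ratio, rounded half-up to 2 decimals."""
    if not full_yield > 0:
        raise DegenerateBaselineError(f"full-irrigation yield must be positive, got {full_yield}")
    ratio = Decimal(ws_yield) / Decimal(full_yield)
    return float(ratio.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def run_baseline(
    params: GenotypeParams,
    weather,
    soil: SoilProfile = SoilProfile(),
    mgmt: Optional[ManagementPlan] = None,
    config: SimConfig = SimConfig(),
    threshold_fraction: float = 0.5,
) -> SimulationResult:
    """Fully-irrigated reference run; its event log is the recorded schedule."""
    policy = AutoIrrigationPolicy(threshold_fraction=threshold_fraction)
    return run_simulation(weather, params, soil=soil, mgmt=mgmt, policy=policy, config=config)


def run_grid(
    grid: TreatmentGrid,
    weather_bank: Mapping,
    cultivar_params: Optional[Mapping[str, GenotypeParams]] = None,
    soil: SoilProfile = SoilProfile(),
    config: SimConfig = SimConfig(),
) -> pd.DataFrame:
    """Simulate the full treatment grid.

    Parameters
    ----------
    weather_bank : mapping
        ``(season, year) -> DailyWeatherSeries`` covering every grid cell.
    cultivar_params : mapping, optional
        ``cultivar -> GenotypeParams``; defaults to the packaged sets.

    Returns
    -------
    pandas.DataFrame
        One row per (cultivar, season, year, treatment, saving): columns
        ``yield_kg_ha``, ``full_yield_kg_ha``, ``ratio`` (full precision),
        ``ratio_2dp``, ``acc_precip_mm``, ``irrigation_mm``.
    """
    cultivar_params = cultivar_params or CULTIVARS
    records = []
    for season in grid.seasons:
        mgmt = ManagementPlan.for_season(season)
        for year in grid.years:
            key = (season, year)
            if key not in weather_bank:
                raise ConfigurationError(f"weather bank has no series for {key}")
            weather = weather_bank[key]
            forcing = prepare_forcing(weather, config) if isinstance(weather, DailyWeatherSeries) else weather
            acc_precip = float(sum(forcing.rain))
            for cultivar in grid.cultivars:
                params = cultivar_params[cultivar]
                base = run_baseline(params, forcing, soil=soil, mgmt=mgmt, config=config)
                if not base.yield_kg_ha > 0:
                    raise DegenerateBaselineError(
                        f"baseline yield non-positive for {cultivar}/{season}/{year}"
                    )
                window = (base.pi_day, base.heading_day)
                for treatment in grid.treatments:
                    sens = window if treatment == "sensitive_stage" else None
                    for s in grid.levels:
                        policy = ScheduledFractionPolicy(base.irrigation_events, s, sens)
                        res = run_simulation(
                            forcing, params, soil=soil, mgmt=mgmt, policy=policy, config=config
                        )
                        records.append(
                            {
                                "cultivar": cultivar,
                                "season": season,
                                "year": year,
                                "treatment": treatment,
                                "saving": s,
                                "yield_kg_ha": res.yield_kg_ha,
                                "full_yield_kg_ha": base.yield_kg_ha,
                                "ratio": res.yield_kg_ha / base.yield_kg_ha,
                                "ratio_2dp": yield_ratio(res.yield_kg_ha, base.yield_kg_ha),
                                "acc_precip_mm": acc_precip,
                                "irrigation_mm": res.total_irrigation,
                            }
                        )
    return pd.DataFrame.from_records(records)


def grid_means(records: pd.DataFrame) -> pd.DataFrame:
    """Across-year mean yield and ratio per (cultivar, season, treatment, saving)."""
    g = records.groupby(["cultivar", "season", "treatment", "saving"], as_index=False)
    out = g.agg(
        mean_yield_kg_ha=("yield_kg_ha", "mean"),
        mean_ratio=("ratio", "mean"),
        n_years=("year", "nunique"),
    )
    out["mean_ratio_2dp"] = [
        float(Decimal(r).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)) for r in out["mean_ratio"]
    ]
    return out


def to_wide_table(records: pd.DataFrame, cultivar: str) -> pd.DataFrame:
    """Wide report for one cultivar: rows = saving level, columns =
    treatment x season, cells 'mean yield (ratio)'."""
    means = grid_means(records[records["cultivar"] == cultivar])
    rows = {}
    for _, r in means.iterrows():
        col = f"{r['treatment']}:{r['season']}"
        rows.setdefault(r["saving"], {})[col] = f"{r['mean_yield_kg_ha']:.0f} ({r['mean_ratio_2dp']:.2f})"
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    out.index.name = "saving"
    return out
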
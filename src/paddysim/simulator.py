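"""Surrogate CERES-like rice model.

A deliberately small daily-timestep rice model carrying the *semantics* of
the eight CERES-Rice genotype coefficients: thermal-time/photoperiod
phenology (P1, P2O, P2R, P5), radiation-driven biomass with a
spikelet-sink yield formation (G1, G2, G3, G4), and a single-layer
soil-water bucket whose stress index modulates both assimilation and sink
formation.  It is the forward model for GLUE calibration and the engine
behind the deficit-irrigation scenario analysis; it makes no claim of
numeric agreement with DSSAT.

Model outline, per day after transplanting:

1. phenology advances on growing degree days ``max(0, tavg - t_base)``;
   the juvenile phase ends at P1 degC day, panicle initiation follows after
   an additional photoperiod-induced requirement ``P2R * max(0, daylength -
   P2O)``, heading after a fixed thermal lag, maturity after P5;
2. the water bucket receives rain, drains to field capacity, loses
   crop-coefficient-scaled Priestley-Taylor ET reduced by the stress index
   Ks, then receives any irrigation the policy decides for that day;
3. biomass grows by ``RUE * G3 * interception * srad * Ks * T-penalty``.

Yield formation: spikelet number is set at heading, proportional to
``G1 * biomass`` and damped by the mean Ks over the panicle-initiation to
heading window (the water-sensitive stage); grain yield is the spikelet
sink ``N * G2`` scaled by grain-fill completion and mean Ks during fill,
and capped by a maximum harvest index on final biomass.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .cultivars import GenotypeParams
from .exceptions import ConfigurationError, ForcingError, TruncatedSeasonError
from .weather import DailyWeatherSeries, T_BASE_DEFAULT

__all__ = [
    "SoilProfile",
    "ManagementPlan",
    "SimConfig",
    "Forcing",
    "SimulationResult",
    "IrrigationEvent",
    "AutoIrrigationPolicy",
    "ScheduledFractionPolicy",
    "daylength",
    "reference_et",
    "water_stress_index",
    "step_water_balance",
    "prepare_forcing",
    "run_simulation",
]


# ---------------------------------------------------------------------------
# Soil and management
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SoilProfile:
    """Single-bucket soil over the managed irrigation depth (default 30 cm)."""

    management_depth: float = 300.0  # mm
    theta_fc: float = 0.33
    theta_wp: float = 0.15
    theta_sat: float = 0.45
    initial_water: Optional[float] = None  # mm; default: at field capacity

    def __post_init__(self):
        if not (0.0 < self.theta_wp < self.theta_fc < self.theta_sat < 1.0):
            raise ConfigurationError("need 0 < theta_wp < theta_fc < theta_sat < 1")
        if self.management_depth <= 0:
            raise ConfigurationError("management_depth must be positive")

    @property
    def fc_mm(self) -> float:
        return self.theta_fc * self.management_depth

    @property
    def wp_mm(self) -> float:
        return self.theta_wp * self.management_depth

    @property
    def sat_mm(self) -> float:
        return self.theta_sat * self.management_depth

    @property
    def pawc(self) -> float:
        """Plant-available water capacity (mm)."""
        return self.fc_mm - self.wp_mm

    @property
    def start_storage(self) -> float:
        return self.fc_mm if self.initial_water is None else self.initial_water


@dataclass(frozen=True)
class ManagementPlan:
    """Transplant-relative nitrogen schedule.

    Fertiliser events are carried for record-keeping and interface fidelity;
    the surrogate has no nitrogen response (a hook for a future N term).
    """

    season: str
    fertilizer_events: tuple[tuple[int, float], ...]  # (day after transplanting, N kg/ha)

    SPLITS = (0.25, 0.20, 0.30, 0.25)

    def __post_init__(self):
        if abs(sum(self.SPLITS) - 1.0) > 1e-12:
            raise ConfigurationError("fertilizer splits must sum to 100%")
        if any(day < 0 or n < 0 for day, n in self.fertilizer_events):
            raise ConfigurationError("fertilizer events must have non-negative day and amount")

    @classmethod
    def for_season(cls, season: str) -> "ManagementPlan":
        # basal at transplanting, two side-dressings, one earing application;
        # 140 kg N/ha in spring, 100 in autumn, split 25/20/30/25 %
        if season == "spring":
            total, days = 140.0, (0, 15, 22, 61)
        elif season == "autumn":
            total, days = 100.0, (0, 19, 28, 54)
        else:
            raise ConfigurationError(f"unknown season {season!r}")
        events = tuple((d, total * s) for d, s in zip(days, cls.SPLITS))
        return cls(season=season, fertilizer_events=events)

    @property
    def total_n(self) -> float:
        return sum(n for _, n in self.fertilizer_events)


@dataclass(frozen=True)
class SimConfig:
    """Numerical constants of the surrogate model."""

    t_base: float = T_BASE_DEFAULT  # degC
    latitude: float = 24.0  # deg, for daylength
    heading_lag: float = 450.0  # degC day from panicle initiation to heading
    pt_alpha: float = 1.26  # Priestley-Taylor coefficient
    crop_coeff: float = 1.05  # single-crop coefficient for paddy rice
    p_threshold: float = 0.6  # plant-available fraction below which Ks < 1
    rue: float = 1.1  # radiation-use efficiency, g/MJ intercepted
    interception_gdd: float = 350.0  # canopy closure thermal scale (degC day)
    spikelet_scale: float = 0.33  # spikelets per (G1 x g/m2 biomass at heading)
    canopy_ks_exponent: float = 0.15  # sensitivity of assimilation to stress
    sens_exponent: float = 2.0  # sensitivity of sink to stress in PI->heading
    fill_exponent: float = 0.2  # sensitivity of grain fill to stress
    hi_max: float = 0.58  # source limit: max harvest index
    t_high: float = 32.0  # degC, onset of heat penalty (shifted by G4)
    t_low: float = 16.0  # degC, onset of chilling penalty
    allow_harvest_cap: bool = True  # truncate grain fill at series end


# ---------------------------------------------------------------------------
# Primitive operations
# ---------------------------------------------------------------------------


def daylength(latitude: float, day_of_year: int) -> float:
    """Astronomical daylength (h) from the standard solar-declination formula."""
    if abs(latitude) >= 66.5:
        raise ConfigurationError("polar latitudes are unsupported")
    decl = math.radians(23.45) * math.sin(2.0 * math.pi * (284 + day_of_year) / 365.0)
    cos_h = -math.tan(math.radians(latitude)) * math.tan(decl)
    cos_h = min(1.0, max(-1.0, cos_h))
    return 24.0 / math.pi * math.acos(cos_h)


def reference_et(srad: float, tavg: float, pt_alpha: float = 1.26) -> float:
    """Priestley-Taylor reference evapotranspiration (mm/day).

    Net radiation is approximated as 75% of incident shortwave; the slope of
    the saturation vapour-pressure curve is evaluated at ``tavg`` with the
    psychrometric constant at 0.067 kPa/degC.
    """
    es = 0.6108 * math.exp(17.27 * tavg / (tavg + 237.3))
    slope = 4098.0 * es / (tavg + 237.3) ** 2
    gamma = 0.067
    rn = 0.75 * srad
    return max(0.0, pt_alpha * slope / (slope + gamma) * rn * 0.408)


def water_stress_index(storage: float, soil: SoilProfile, p_threshold: float = 0.5) -> float:
    """Ks in [0, 1]: 1 above the stress-onset fraction, linear to 0 at wilting."""
    paw_frac = (storage - soil.wp_mm) / soil.pawc
    if paw_frac >= p_threshold:
        return 1.0
    if paw_frac <= 0.0:
        return 0.0
    return paw_frac / p_threshold


def step_water_balance(
    storage: float,
    rain: float,
    irrigation: float,
    et_ref: float,
    crop_coeff: float,
    soil: SoilProfile,
    p_threshold: float = 0.5,
) -> tuple[float, dict]:
    """One day of the bucket: rain in, drain to FC, stressed ET out, irrigate.

    Irrigation enters at the end of the day (after ET), matching the refill
    semantics of flood irrigation triggered on the day's closing storage;
    water above field capacity from rain drains the same day, and anything
    irrigation pushes above saturation drains immediately.

    Returns the new storage and a flux dict with keys ``rain``,
    ``irrigation``, ``aet``, ``drainage``, ``ks``.
    """
    if rain < 0 or irrigation < 0 or et_ref < 0:
        raise ForcingError("rain, irrigation and ET forcing must be non-negative")
    storage += rain
    drainage = max(0.0, storage - soil.fc_mm)
    storage -= drainage
    ks = water_stress_index(storage, soil, p_threshold)
    aet = min(crop_coeff * et_ref * ks, max(0.0, storage))
    storage -= aet
    storage += irrigation
    if storage > soil.sat_mm:
        drainage += storage - soil.sat_mm
        storage = soil.sat_mm
    return storage, {"rain": rain, "irrigation": irrigation, "aet": aet, "drainage": drainage, "ks": ks}


# ---------------------------------------------------------------------------
# Irrigation policies
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IrrigationEvent:
    day: int  # day after transplanting
    amount: float  # mm applied


class AutoIrrigationPolicy:
    """Demand-triggered flood irrigation: refill to field capacity whenever
    the plant-available fraction falls below the threshold (default 50% of
    field capacity on the available-water scale), evaluated on the day's
    closing storage."""

    def __init__(self, threshold_fraction: float = 0.5):
        if not 0.0 <= threshold_fraction <= 1.0:
            raise ConfigurationError("threshold_fraction must lie in [0, 1]")
        self.threshold_fraction = threshold_fraction

    def scheduled_amount(self, day: int) -> float:
        return 0.0

    def end_of_day_amount(self, storage: float, soil: SoilProfile) -> float:
        paw_frac = (storage - soil.wp_mm) / soil.pawc
        if paw_frac < self.threshold_fraction:
            return soil.fc_mm - storage
        return 0.0


class ScheduledFractionPolicy:
    """Replay a recorded irrigation schedule at a fractional amount.

    ``saving`` is the water-saving proportion s: each baseline event is
    applied at ``(1 - s)`` of its recorded amount.  Inside the optional
    sensitive window (inclusive day interval, normally panicle initiation to
    heading) the full recorded amount is applied instead.
    """

    def __init__(
        self,
        baseline_events: Sequence[IrrigationEvent],
        saving: float,
        sensitive_window: Optional[tuple[int, int]] = None,
    ):
        if not 0.0 <= saving <= 1.0:
            raise ConfigurationError(f"saving proportion must lie in [0, 1], got {saving}")
        self.saving = saving
        self.sensitive_window = sensitive_window
        self._by_day: dict[int, float] = {}
        for ev in baseline_events:
            self._by_day[ev.day] = self._by_day.get(ev.day, 0.0) + ev.amount

    def _factor(self, day: int) -> float:
        if self.sensitive_window is not None:
            lo, hi = self.sensitive_window
            if lo <= day <= hi:
                return 1.0
        return 1.0 - self.saving

    def scheduled_amount(self, day: int) -> float:
        base = self._by_day.get(day, 0.0)
        return base * self._factor(day) if base else 0.0

    def end_of_day_amount(self, storage: float, soil: SoilProfile) -> float:
        return 0.0


# ---------------------------------------------------------------------------
# Forcing preparation and the daily loop
# ---------------------------------------------------------------------------


@dataclass
class Forcing:
    """Weather pre-processed for the daily loop (shared across GLUE draws)."""

    n_days: int
    tavg: list
    srad: list
    rain: list
    et_ref: list
    daylen: list
    dates: pd.Series


def prepare_forcing(weather: DailyWeatherSeries, config: SimConfig = SimConfig()) -> Forcing:
    df = weather.frame
    if weather.has_missing:
        raise ForcingError("weather contains missing values; impute first")
    tavg = df["tavg"].to_numpy(float)
    srad = df["srad"].to_numpy(float)
    rain = df["rain"].to_numpy(float)
    if not (np.isfinite(tavg).all() and np.isfinite(srad).all() and np.isfinite(rain).all()):
        raise ForcingError("non-finite weather forcing")
    doy = df["date"].dt.dayofyear.to_numpy()
    et0 = [reference_et(s, t, config.pt_alpha) for s, t in zip(srad, tavg)]
    dl = [daylength(config.latitude, int(d)) for d in doy]
    return Forcing(
        n_days=len(df),
        tavg=tavg.tolist(),
        srad=srad.tolist(),
        rain=rain.tolist(),
        et_ref=et0,
        daylen=dl,
        dates=df["date"],
    )


@dataclass
class SimulationResult:
    """Outcome of one season run."""

    yield_kg_ha: float
    biomass_g_m2: float
    pi_day: Optional[int]
    heading_day: Optional[int]
    maturity_day: Optional[int]
    storage: np.ndarray  # end-of-day storage, mm
    ks: np.ndarray  # daily stress index
    irrigation_events: list[IrrigationEvent]
    totals: dict  # rain, irrigation, aet, drainage (mm)
    initial_storage: float

    @property
    def total_irrigation(self) -> float:
        return self.totals["irrigation"]

    def water_balance_residual(self) -> float:
        """Season mass balance: inputs - outputs - storage change (mm)."""
        d_storage = float(self.storage[-1]) - self.initial_storage
        return (
            self.totals["rain"]
            + self.totals["irrigation"]
            - self.totals["aet"]
            - self.totals["drainage"]
            - d_storage
        )

    def to_daily_frame(self) -> pd.DataFrame:
        n = len(self.storage)
        stage = np.full(n, "vegetative", dtype=object)
        if self.pi_day is not None:
            stage[self.pi_day :] = "reproductive"
        if self.heading_day is not None:
            stage[self.heading_day :] = "grain_fill"
        if self.maturity_day is not None:
            stage[self.maturity_day :] = "mature"
        irr = np.zeros(n)
        for ev in self.irrigation_events:
            irr[ev.day] += ev.amount
        return pd.DataFrame(
            {"day": np.arange(n), "stage": stage, "storage_mm": self.storage, "ks": self.ks, "irrigation_mm": irr}
        )

    def summary(self) -> dict:
        return {
            "yield_kg_ha": round(self.yield_kg_ha, 1),
            "biomass_g_m2": round(self.biomass_g_m2, 1),
            "pi_day": self.pi_day,
            "heading_day": self.heading_day,
            "maturity_day": self.maturity_day,
            "total_irrigation_mm": round(self.totals["irrigation"], 2),
            "total_rain_mm": round(self.totals["rain"], 2),
            "n_irrigation_events": len(self.irrigation_events),
        }


def run_simulation(
    weather: Union[DailyWeatherSeries, Forcing],
    params: GenotypeParams,
    soil: SoilProfile = SoilProfile(),
    mgmt: Optional[ManagementPlan] = None,
    policy=None,
    seed: int = 0,
    config: SimConfig = SimConfig(),
) -> SimulationResult:
    """Run one season.  Deterministic: the model has no internal noise, so
    ``seed`` is accepted only for interface stability.

    Raises :class:`TruncatedSeasonError` if the series ends before heading,
    or before maturity when ``config.allow_harvest_cap`` is false.
    """
    forcing = weather if isinstance(weather, Forcing) else prepare_forcing(weather, config)
    if policy is None:
        policy = AutoIrrigationPolicy()

    n = forcing.n_days
    t_base = config.t_base
    heat_onset = config.t_high + 2.0 * (params.G4 - 1.0)

    storage = soil.start_storage
    storage_trace = np.empty(n)
    ks_trace = np.empty(n)
    events: list[IrrigationEvent] = []
    totals = {"rain": 0.0, "irrigation": 0.0, "aet": 0.0, "drainage": 0.0}

    # phenology bookkeeping
    STAGE_JUV, STAGE_PHOTO, STAGE_REPRO, STAGE_FILL, STAGE_MATURE = range(5)
    stage = STAGE_JUV
    cum_stage = 0.0  # thermal time within current stage
    cum_total = 0.0
    pi_day = heading_day = maturity_day = None

    biomass = 0.0
    ks_sens_sum, ks_sens_n = 0.0, 0
    ks_fill_sum, ks_fill_n = 0.0, 0
    fill_gdd = 0.0
    biomass_heading = None

    for d in range(n):
        tavg = forcing.tavg[d]
        gdd = tavg - t_base
        if gdd < 0.0:
            gdd = 0.0

        # --- phenology -------------------------------------------------
        if stage != STAGE_MATURE:
            cum_stage += gdd
            cum_total += gdd
            if stage == STAGE_JUV and cum_stage >= params.P1:
                cum_stage -= params.P1
                stage = STAGE_PHOTO
            if stage == STAGE_PHOTO:
                photo_req = params.P2R * max(0.0, forcing.daylen[d] - params.P2O)
                if cum_stage >= photo_req:
                    cum_stage -= photo_req
                    stage = STAGE_REPRO
                    pi_day = d
            elif stage == STAGE_REPRO and cum_stage >= config.heading_lag:
                cum_stage -= config.heading_lag
                stage = STAGE_FILL
                heading_day = d
                biomass_heading = biomass
            elif stage == STAGE_FILL:
                fill_gdd += gdd
                if fill_gdd >= params.P5:
                    stage = STAGE_MATURE
                    maturity_day = d

        # --- water balance --------------------------------------------
        sched = policy.scheduled_amount(d)
        storage, flux = step_water_balance(
            storage, forcing.rain[d], sched, forcing.et_ref[d], config.crop_coeff, soil, config.p_threshold
        )
        topup = policy.end_of_day_amount(storage, soil)
        if topup > 0.0:
            storage += topup
            flux["irrigation"] += topup
        irr_today = flux["irrigation"]
        if irr_today > 0.0:
            events.append(IrrigationEvent(day=d, amount=irr_today))
        for k in totals:
            totals[k] += flux[k]
        ks = flux["ks"]
        storage_trace[d] = storage
        ks_trace[d] = ks

        # --- growth ----------------------------------------------------
        if stage != STAGE_MATURE or maturity_day == d:
            interception = 1.0 - math.exp(-cum_total / config.interception_gdd)
            pen = 1.0
            if tavg > heat_onset:
                pen -= 0.025 * (tavg - heat_onset)
            elif tavg < config.t_low:
                pen -= 0.05 * (config.t_low - tavg)
            if pen < 0.0:
                pen = 0.0
            biomass += (
                config.rue
                * params.G3
                * forcing.srad[d]
                * interception
                * ks**config.canopy_ks_exponent
                * pen
            )

        if stage == STAGE_REPRO:
            ks_sens_sum += ks
            ks_sens_n += 1
        elif stage == STAGE_FILL:
            ks_fill_sum += ks
            ks_fill_n += 1

        if stage == STAGE_MATURE:
            # freeze remaining traces at the mature state and stop growing
            storage_trace[d + 1 :] = storage
            ks_trace[d + 1 :] = ks
            break

    if heading_day is None:
        raise TruncatedSeasonError("weather series ended before heading")
    if maturity_day is None and not config.allow_harvest_cap:
        raise TruncatedSeasonError("weather series ended before maturity")

    # --- yield formation ----------------------------------------------
    mean_ks_sens = ks_sens_sum / ks_sens_n if ks_sens_n else 1.0
    mean_ks_fill = ks_fill_sum / ks_fill_n if ks_fill_n else 1.0
    spikelets = (
        params.G1
        * config.spikelet_scale
        * (biomass_heading if biomass_heading is not None else biomass)
        * mean_ks_sens**config.sens_exponent
    )
    fill_completion = min(1.0, fill_gdd / params.P5)
    sink = spikelets * params.G2 * fill_completion * mean_ks_fill**config.fill_exponent
    source_limit = config.hi_max * biomass
    grain_g_m2 = min(sink, source_limit)
    yield_kg_ha = max(0.0, grain_g_m2 * 10.0)

    return SimulationResult(
        yield_kg_ha=yield_kg_ha,
        biomass_g_m2=biomass,
        pi_day=pi_day,
        heading_day=heading_day,
        maturity_day=maturity_day,
        storage=storage_trace,
        ks=ks_trace,
        irrigation_events=events,
        totals=totals,
        initial_storage=soil.start_storage,
    )
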
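"""Synthetic weather generation, gap repair and climate summaries."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from paddysim.exceptions import (
    ConfigurationError,
    UnrecoverableRecordError,
    WindowBoundsError,
)
from paddysim.io import read_weather_csv, read_wth, write_weather_csv, write_wth
from paddysim.weather import (
    AUTUMN_DEFAULT,
    SPRING_DEFAULT,
    DailyWeatherSeries,
    SeasonSpec,
    StageWindows,
    climate_summary,
    generate_season_weather,
    impute_missing,
)

from conftest import constant_weather


def degenerate_spec(**kw):
    base = SeasonSpec(
        season="spring",
        transplant_doy=61,
        n_days=30,
        rainfall_timing=None,
        target_precip_total=300.0,
        wet_prob=1.0,
        rain_shape=0.0,
        tmax_start=25.0,
        tmax_end=25.0,
        trange_mean=10.0,
        temp_noise_sd=0.0,
        srad_start=15.0,
        srad_end=15.0,
        srad_noise_sd=0.0,
    )
    return replace(base, **kw)


class TestGenerator:
    def test_zero_noise_flat_curves_every_day_identical(self):
        w = generate_season_weather(degenerate_spec(), seed=0).frame
        for col, expect in [("tmax", 25.0), ("tmin", 15.0), ("srad", 15.0), ("rain", 10.0)]:
            assert np.allclose(w[col], expect), col

    def test_same_seed_identical_series(self):
        spec = SPRING_DEFAULT.with_year(2003, 700.0)
        a = generate_season_weather(spec, seed=9)
        b = generate_season_weather(spec, seed=9)
        assert a.frame.equals(b.frame)
        c = generate_season_weather(spec, seed=10)
        assert not a.frame.equals(c.frame)

    def test_expected_precip_total_monte_carlo(self):
        # 1000 independent seasons: empirical mean of totals within 3 SE of
        # the configured 600 mm expectation
        spec = SPRING_DEFAULT.with_year(2001, 600.0)
        totals = np.array(
            [generate_season_weather(spec, seed=s).total_rain() for s in range(1000)]
        )
        se = totals.std(ddof=1) / np.sqrt(totals.size)
        assert abs(totals.mean() - 600.0) < 3 * se

    def test_heavy_events_respect_expected_total(self):
        spec = AUTUMN_DEFAULT.with_year(2001, 700.0)
        totals = np.array(
            [generate_season_weather(spec, seed=s).total_rain() for s in range(800)]
        )
        se = totals.std(ddof=1) / np.sqrt(totals.size)
        assert abs(totals.mean() - 700.0) < 3 * se

    def test_rainfall_timing_contrast(self):
        # spring mass concentrated late, autumn early (averaged over seeds)
        def centroid(spec):
            vals = []
            for s in range(50):
                f = generate_season_weather(spec, seed=s).frame
                pos = np.linspace(0, 1, len(f))
                if f["rain"].sum() > 0:
                    vals.append(np.average(pos, weights=f["rain"]))
            return np.mean(vals)

        assert centroid(SPRING_DEFAULT.with_year(2001, 600.0)) > 0.55
        assert centroid(AUTUMN_DEFAULT.with_year(2001, 600.0)) < 0.45

    def test_invalid_spec_rejected(self):
        with pytest.raises(ConfigurationError):
            SeasonSpec(season="winter", transplant_doy=1, n_days=10)
        with pytest.raises(ConfigurationError):
            SeasonSpec(season="spring", transplant_doy=1, n_days=0)
        with pytest.raises(ConfigurationError):
            SeasonSpec(season="spring", transplant_doy=1, n_days=10, wet_prob=1.5)
        with pytest.raises(ConfigurationError):
            SeasonSpec(season="spring", transplant_doy=1, n_days=10, target_precip_total=-5)

    def test_invariants_enforced_by_container(self):
        f = constant_weather(10).frame.copy()
        f.loc[3, "tmin"] = 40.0  # above tmax
        with pytest.raises(ConfigurationError):
            DailyWeatherSeries(f)
        f2 = constant_weather(10).frame.copy()
        f2.loc[2, "rain"] = -1.0
        with pytest.raises(ConfigurationError):
            DailyWeatherSeries(f2)


class TestImputation:
    def _with_gap(self, col, idx):
        w = constant_weather(40)
        f = w.frame.copy()
        f.loc[idx, col] = np.nan
        if col in ("tmax", "tmin"):
            f.loc[idx, "tavg"] = np.nan
        return DailyWeatherSeries(f)

    def test_temperature_gap_mean_of_adjacent_days(self):
        w = constant_weather(40)
        f = w.frame.copy()
        f.loc[10, ["tmax", "tmin", "tavg"]] = np.nan
        f.loc[9, ["tmax", "tmin", "tavg"]] = [25.0, 15.0, np.nan]  # tavg derives to 20
        f.loc[11, ["tmax", "tmin", "tavg"]] = [29.0, 19.0, np.nan]  # tavg derives to 24
        out = impute_missing(DailyWeatherSeries(f))
        assert out.frame.loc[10, "tavg"] == pytest.approx(22.0)
        assert not out.has_missing

    def test_rain_gap_monthly_mean(self):
        w = constant_weather(31, doy=60)  # all days in March
        f = w.frame.copy()
        f["rain"] = 0.0
        f.loc[1, "rain"] = 10.0
        f.loc[2, "rain"] = 20.0
        f.loc[3:27, "rain"] = np.nan
        f.loc[28:, "rain"] = 0.0
        # present values that month: {0, 10, 20, 0, 0, 0} -> mean 5
        out = impute_missing(DailyWeatherSeries(f))
        present_mean = np.nanmean(w.frame["rain"].to_numpy() * 0 + f["rain"].to_numpy())
        assert out.frame.loc[5, "rain"] == pytest.approx(present_mean)

    def test_rain_gap_uses_stated_monthly_mean_rule(self):
        # month whose present values are {0, 10, 20} -> gap filled with 10
        w = constant_weather(4, doy=91)  # April
        f = w.frame.copy()
        f["rain"] = [0.0, 10.0, 20.0, np.nan]
        out = impute_missing(DailyWeatherSeries(f))
        assert out.frame.loc[3, "rain"] == pytest.approx(10.0)

    def test_no_gaps_identity(self):
        w = constant_weather(30)
        out = impute_missing(w)
        filled = w.frame.copy()
        filled["tavg"] = (filled["tmax"] + filled["tmin"]) / 2
        assert out.frame.equals(impute_missing(out).frame)  # idempotent
        assert out.frame[["tmax", "tmin", "rain", "srad"]].equals(
            w.frame[["tmax", "tmin", "rain", "srad"]]
        )

    def test_neighbor_transfer_is_bias_corrected(self):
        w = constant_weather(30)
        f = w.frame.copy()
        f.loc[0, ["tmax", "tmin", "tavg"]] = np.nan  # boundary: only neighbor can fill
        nb = w.frame.copy()
        nb["tmax"] = nb["tmax"] - 2.0  # neighbor runs 2 degC cooler
        nb["tmin"] = nb["tmin"] - 2.0
        out = impute_missing(DailyWeatherSeries(f), neighbor=DailyWeatherSeries(nb))
        assert out.frame.loc[0, "tmax"] == pytest.approx(25.0)
        assert out.frame.loc[0, "tmin"] == pytest.approx(15.0)

    def test_boundary_gap_without_neighbor_unrecoverable(self):
        f = constant_weather(30).frame.copy()
        f.loc[0, ["tmax", "tmin", "tavg"]] = np.nan
        with pytest.raises(UnrecoverableRecordError):
            impute_missing(DailyWeatherSeries(f))

    def test_month_fully_missing_unrecoverable(self):
        f = constant_weather(20, doy=121).frame.copy()  # all May
        f["srad"] = np.nan
        with pytest.raises(UnrecoverableRecordError):
            impute_missing(DailyWeatherSeries(f))


class TestStageWindows:
    def test_seasonal_defaults(self):
        sp = StageWindows.for_season("spring", 119)
        assert sp.initial == (0, 20) and sp.vegetative == (21, 50) and sp.reproductive == (51, 119)
        au = StageWindows.for_season("autumn", 99)
        assert au.vegetative == (21, 40) and au.reproductive == (41, 99)

    def test_non_contiguous_rejected(self):
        with pytest.raises(ConfigurationError):
            StageWindows((0, 20), (22, 50), (51, 100))


class TestClimateSummary:
    def test_constant_series_closed_form(self):
        w = impute_missing(constant_weather(60))  # tavg 20
        cs = climate_summary(w, StageWindows((0, 4), (5, 9), (10, 59)), t_base=10.0)
        # 10 days at tavg 20, t_base 10 -> stage GDD 100, acc temp 200
        assert cs.gdd_initial + cs.gdd_vegetative == pytest.approx(100.0)
        assert cs.acc_temp_initial + cs.acc_temp_vegetative == pytest.approx(200.0)
        assert cs.gdd == pytest.approx(600.0)
        assert cs.acc_temp == pytest.approx(1200.0)

    def test_below_base_gdd_clamped(self):
        w = impute_missing(constant_weather(20, tmax=10.0, tmin=2.0))  # tavg 6
        cs = climate_summary(w, StageWindows((0, 4), (5, 9), (10, 19)), t_base=10.0)
        assert cs.gdd == 0.0
        assert cs.acc_temp > 0.0

    def test_stage_sums_match_brute_force(self, spring_weather):
        w = impute_missing(spring_weather)
        windows = StageWindows.for_season("spring", len(w) - 1)
        cs = climate_summary(w, windows, t_base=10.0)
        tavg = w.frame["tavg"].to_numpy()
        for (lo, hi), got_t, got_g in [
            (windows.initial, cs.acc_temp_initial, cs.gdd_initial),
            (windows.vegetative, cs.acc_temp_vegetative, cs.gdd_vegetative),
            (windows.reproductive, cs.acc_temp_reproductive, cs.gdd_reproductive),
        ]:
            t = g = 0.0
            for d in range(lo, hi + 1):
                t += tavg[d]
                g += max(0.0, tavg[d] - 10.0)
            assert got_t == pytest.approx(t, abs=1e-9)
            assert got_g == pytest.approx(g, abs=1e-9)
        # exact bookkeeping: whole season = stage sums (windows cover all days)
        assert cs.acc_temp == pytest.approx(
            cs.acc_temp_initial + cs.acc_temp_vegetative + cs.acc_temp_reproductive
        )
        assert cs.gdd == pytest.approx(cs.gdd_initial + cs.gdd_vegetative + cs.gdd_reproductive)

    def test_windows_beyond_series_rejected(self, spring_weather):
        w = impute_missing(spring_weather)
        with pytest.raises(WindowBoundsError):
            climate_summary(w, StageWindows((0, 20), (21, 50), (51, len(w) + 5)), 10.0)


class TestIO:
    def test_csv_roundtrip(self, tmp_path, spring_weather):
        path = tmp_path / "w.csv"
        write_weather_csv(spring_weather, path)
        back = read_weather_csv(path)
        for col in ("tmax", "tmin", "rain", "srad"):
            assert np.allclose(back.frame[col], spring_weather.frame[col], atol=5e-4)

    def test_csv_missing_cells(self, tmp_path):
        f = constant_weather(5).frame.copy()
        f.loc[2, ["rain"]] = np.nan
        path = tmp_path / "gap.csv"
        write_weather_csv(DailyWeatherSeries(f), path)
        back = read_weather_csv(path)
        assert np.isnan(back.frame.loc[2, "rain"])

    def test_wth_roundtrip(self, tmp_path, autumn_weather):
        path = tmp_path / "TDAR0101.WTH"
        write_wth(autumn_weather, path)
        text = path.read_text()
        assert text.startswith("*WEATHER DATA") and "@DATE  SRAD  TMAX  TMIN  RAIN" in text
        back = read_wth(path)
        assert (back.frame["date"] == autumn_weather.frame["date"]).all()
        for col in ("tmax", "tmin", "rain", "srad"):
            assert np.allclose(back.frame[col], autumn_weather.frame[col], atol=0.05 + 1e-9)
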
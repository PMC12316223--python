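"""Yield-response modelling: stratification, curve fits, AIC selection,
correction, prediction intervals and the retention inversion."""

import numpy as np
import pandas as pd
import pytest

from paddysim.exceptions import ConfigurationError, EmptySelectionError
from paddysim.response import (
    FORMS,
    SubsetKey,
    YieldResponseModel,
    aic,
    correction_term,
    fit_candidate,
    prediction_interval,
    recommend_saving,
    select_best,
    stratify,
)
from paddysim.synthetic import DEFAULT_TRUTHS, KnownResponse, synthetic_response_records


def make_subset(x, y):
    return pd.DataFrame({"saving": np.asarray(x, float), "ratio": np.asarray(y, float)})


class TestStratify:
    def test_standard_grid_yields_24_subsets(self):
        records = synthetic_response_records(seed=1)
        assert len(stratify(records)) == 24

    def test_all_above_cutoff_empty(self):
        records = synthetic_response_records(seed=1).assign(acc_precip_mm=1500.0)
        assert stratify(records) == {}

    def test_boundary_500_goes_to_mid_stratum(self):
        records = synthetic_response_records(seed=1, cultivars=("TK9",), seasons=("spring",))
        records["acc_precip_mm"] = 500.0
        out = stratify(records)
        assert all(k.stratum == "mid" for k in out)

    def test_above_1000_dropped_before_split(self):
        records = synthetic_response_records(seed=1, cultivars=("TK9",), seasons=("spring",))
        records.loc[records.index[:30], "acc_precip_mm"] = 1000.5
        out = stratify(records)
        total = sum(len(v) for v in out.values())
        assert total == len(records) - 30


class TestFitCandidate:
    def test_exact_line_interpolated(self):
        x = np.linspace(0, 1, 12)
        fit = fit_candidate(make_subset(x, 1.0 - 0.2 * x), "linear")
        assert fit.coefficients[0] == pytest.approx(1.0, abs=1e-8)
        assert fit.coefficients[1] == pytest.approx(-0.2, abs=1e-8)
        assert fit.rss == pytest.approx(0.0, abs=1e-16)

    def test_parabola_nesting(self):
        x = np.linspace(0, 1, 15)
        y = 1.0 - 0.1 * x - 0.3 * x**2
        quad = fit_candidate(make_subset(x, y), "quadratic")
        cub = fit_candidate(make_subset(x, y), "cubic")
        assert quad.rss == pytest.approx(0.0, abs=1e-12)
        assert abs(cub.coefficients[3]) < 1e-6

    def test_logistic_recovery_at_n60(self):
        rng = np.random.default_rng(5)
        a, b, c = 1.0, 6.0, 0.55
        x = rng.uniform(0, 1, 60)
        y = a / (1.0 + np.exp(b * (x - c))) + rng.normal(0, 0.01, 60)
        fit = fit_candidate(make_subset(x, y), "logistic")
        rel = np.abs(fit.coefficients - np.array([a, b, c])) / np.array([a, b, c])
        assert np.all(rel < 0.05)

    def test_parameter_count_convention(self):
        x = np.linspace(0, 1, 20)
        y = 1.0 - 0.2 * x
        expected_p = {"linear": 3, "quadratic": 4, "cubic": 5, "logistic": 4}
        for form in FORMS:
            assert fit_candidate(make_subset(x, y), form).p == expected_p[form]

    def test_too_few_points_rejected(self):
        x = np.array([0.0, 0.5, 1.0])
        with pytest.raises(ConfigurationError):
            fit_candidate(make_subset(x, 1 - x), "cubic")

    def test_unknown_form_rejected(self):
        with pytest.raises(ConfigurationError):
            fit_candidate(make_subset([0, 1], [1, 0]), "quartic")


class TestAic:
    def test_formula_identity(self):
        x = np.linspace(0, 1, 25)
        rng = np.random.default_rng(2)
        y = 1.0 - 0.3 * x + rng.normal(0, 0.05, 25)
        for form in ("linear", "quadratic", "cubic"):
            fit = fit_candidate(make_subset(x, y), form)
            assert fit.aic == pytest.approx(-2.0 * fit.loglik + 2.0 * fit.p)
            assert aic(fit) == pytest.approx(fit.aic)

    def test_matches_closed_form_gaussian_oracle(self):
        x = np.linspace(0, 1, 30)
        rng = np.random.default_rng(3)
        y = 1.0 - 0.25 * x + rng.normal(0, 0.04, 30)
        fit = fit_candidate(make_subset(x, y), "linear")
        n = 30
        sigma2 = fit.rss / n
        oracle_loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
        assert fit.loglik == pytest.approx(oracle_loglik, abs=1e-9)
        assert fit.aic == pytest.approx(-2 * oracle_loglik + 2 * 3, abs=1e-9)

    def test_equal_loglik_p_gap_of_one_gives_aic_gap_of_two(self):
        import dataclasses

        x = np.linspace(0, 1, 20)
        rng = np.random.default_rng(8)
        fit = fit_candidate(make_subset(x, 1.0 - 0.2 * x + rng.normal(0, 0.03, 20)), "linear")
        richer = dataclasses.replace(fit, p=fit.p + 1)
        assert aic(richer) - aic(fit) == pytest.approx(2.0)

    def test_loglik_zero_p3_gives_aic_6(self):
        import dataclasses

        x = np.linspace(0, 1, 20)
        fit = fit_candidate(make_subset(x, 1.0 - 0.2 * x), "linear")
        zeroed = dataclasses.replace(fit, loglik=0.0, p=3)
        assert aic(zeroed) == pytest.approx(6.0)

    def test_nested_rss_ordering(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            x = rng.uniform(0, 1, 18)
            y = 1.0 - 0.3 * x - 0.2 * x**2 + rng.normal(0, 0.03, 18)
            sub = make_subset(x, y)
            rss = {f: fit_candidate(sub, f).rss for f in ("linear", "quadratic", "cubic")}
            assert rss["cubic"] <= rss["quadratic"] + 1e-12 <= rss["linear"] + 1e-12


class TestSelectBest:
    def test_single_plausible_candidate_returned(self):
        x = np.linspace(0, 1, 12)
        fit = fit_candidate(make_subset(x, 1.0 - 0.2 * x), "linear")
        chosen, fallback = select_best([fit])
        assert chosen is fit and not fallback

    def test_intercept_excess_overridden(self):
        # linear fit starting well above 1 loses to a plausible quadratic
        # despite a better AIC
        rng = np.random.default_rng(11)
        x = np.tile(np.linspace(0, 1, 6), 5)
        y = 1.0 - 0.02 * x - 0.5 * x**2 + rng.normal(0, 0.02, x.size)
        sub = make_subset(x, y)
        lin = fit_candidate(sub, "linear")
        quad = fit_candidate(sub, "quadratic")
        assert lin.intercept_excess  # strongly curved data pushes intercept up
        chosen, fallback = select_best([lin, quad])
        assert chosen.form == "quadratic" and not fallback

    def test_non_monotone_candidate_overridden(self):
        rng = np.random.default_rng(12)
        x = np.tile(np.linspace(0, 1, 6), 4)
        y = 1.0 - 0.25 * x + rng.normal(0, 0.01, x.size)
        sub = make_subset(x, y)
        quad = fit_candidate(sub, "quadratic")
        cub = fit_candidate(sub, "cubic")
        cub.non_monotone = True  # S-shaped upward mid-section
        cub.aic = quad.aic - 5.0
        chosen, _ = select_best([cub, quad])
        assert chosen.form == "quadratic"

    def test_all_disqualified_falls_back_with_flag(self):
        x = np.linspace(0, 1, 12)
        fit = fit_candidate(make_subset(x, 1.0 - 0.2 * x), "linear")
        fit.non_monotone = True
        with pytest.warns(UserWarning):
            chosen, fallback = select_best([fit])
        assert fallback

    def test_empty_selection_rejected(self):
        with pytest.raises(EmptySelectionError):
            select_best([])


class TestCorrection:
    def test_identity_gives_zero(self):
        assert correction_term([5000.0, 6000.0], [5000.0, 6000.0]) == 0.0

    def test_uniform_shift(self):
        sim = [5000.0, 6000.0, 5500.0]
        obs = [v + 500.0 for v in sim]
        assert correction_term(sim, obs) == pytest.approx(500.0)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(13)
        sim = rng.uniform(3000, 7000, 20)
        obs = rng.uniform(3000, 7000, 20)
        acc = 0.0
        for o, s in zip(obs, sim):
            acc += o - s
        assert correction_term(sim, obs) == pytest.approx(acc / 20.0)

    def test_empty_pairing_rejected(self):
        with pytest.raises(ConfigurationError):
            correction_term([], [])


class TestPredictionInterval:
    def test_zero_residual_zero_width(self):
        x = np.linspace(0, 1, 12)
        fit = fit_candidate(make_subset(x, 1.0 - 0.2 * x), "linear")
        band = prediction_interval(fit, np.linspace(0, 1, 11))
        assert np.allclose(band["upper"] - band["lower"], 0.0, atol=1e-6)

    @pytest.mark.parametrize("form", ["linear", "quadratic", "logistic"])
    def test_band_contains_point_curve(self, form):
        rng = np.random.default_rng(14)
        x = rng.uniform(0, 1, 30)
        y = 1.0 / (1.0 + np.exp(5 * (x - 0.5))) + rng.normal(0, 0.02, 30)
        fit = fit_candidate(make_subset(x, y), form)
        grid = np.linspace(0, 1, 21)
        band = prediction_interval(fit, grid)
        assert (band["lower"] <= band["fit"] + 1e-12).all()
        assert (band["fit"] <= band["upper"] + 1e-12).all()
        assert np.allclose(band["fit"], fit.predict(grid))

    def test_coverage_calibrated(self):
        # empirical coverage of new observations from a known linear model
        rng = np.random.default_rng(15)
        hits = 0
        n_rep = 2000
        for _ in range(n_rep):
            x = rng.uniform(0, 1, 15)
            y = 1.0 - 0.25 * x + rng.normal(0, 0.03, 15)
            fit = fit_candidate(make_subset(x, y), "linear")
            xn = float(rng.uniform(0, 1))
            yn = 1.0 - 0.25 * xn + float(rng.normal(0, 0.03))
            band = prediction_interval(fit, [xn])
            if band["lower"][0] <= yn <= band["upper"][0]:
                hits += 1
        assert 0.92 <= hits / n_rep <= 0.98


class TestRecommendSaving:
    def _fit(self, x, y, form="linear"):
        return fit_candidate(make_subset(x, y), form)

    def test_linear_closed_form(self):
        x = np.linspace(0, 1, 12)
        fit = self._fit(x, 1.0 - 0.2 * x)
        assert recommend_saving(fit, 0.90) == pytest.approx(50.0, abs=1e-3)

    def test_saturating_curve_returns_100(self):
        x = np.linspace(0, 1, 12)
        fit = self._fit(x, 1.0 - 0.05 * x)
        assert recommend_saving(fit, 0.90) == 100.0

    def test_infeasible_reported_as_nan(self):
        x = np.linspace(0, 1, 12)
        fit = self._fit(x, 0.85 - 0.2 * x)
        assert np.isnan(recommend_saving(fit, 0.90))

    def test_bisection_matches_grid_oracle(self):
        rng = np.random.default_rng(16)
        for _ in range(5):
            b2 = -float(rng.uniform(0.1, 0.4))
            b1 = -float(rng.uniform(0.0, 0.1))
            x = np.linspace(0, 1, 24)
            fit = self._fit(x, 1.0 + b1 * x + b2 * x**2, "quadratic")
            got = recommend_saving(fit, 0.90)
            grid = np.linspace(0.0, 1.0, 10**6)
            vals = fit.predict(grid)
            oracle = 100.0 * grid[vals >= 0.90][-1]
            assert got == pytest.approx(oracle, abs=1e-4 * 100)

    def test_monotone_in_curve_level(self):
        x = np.linspace(0, 1, 12)
        low = self._fit(x, 0.97 - 0.2 * x)
        high = self._fit(x, 1.0 - 0.2 * x)
        assert recommend_saving(high, 0.90) >= recommend_saving(low, 0.90)

    def test_non_monotone_fit_rejected(self):
        x = np.linspace(0, 1, 12)
        fit = self._fit(x, 1.0 - 0.2 * x)
        fit.non_monotone = True
        with pytest.raises(ConfigurationError):
            recommend_saving(fit)


class TestEndToEnd:
    def test_known_response_recovered_within_five_points(self):
        records = synthetic_response_records(seed=7)
        results = YieldResponseModel(records).fit()
        assert len(results.selected) == 24
        for key, rec in results.recommendations().items():
            truth = DEFAULT_TRUTHS[(key.treatment, key.stratum)].retention_point()
            assert rec.feasible
            assert abs(rec.percentage - truth) <= 5.0, key

    def test_summary_and_bands_consistent(self):
        records = synthetic_response_records(seed=3)
        obs = records[records["saving"] == 0.0][
            ["cultivar", "season", "year", "yield_kg_ha"]
        ].copy()
        obs["yield_kg_ha"] += 400.0  # observations run 400 kg/ha above simulation
        results = YieldResponseModel(records, observed_yields=obs).fit()
        tab = results.summary()
        assert len(tab) == 24
        key = next(iter(results.selected))
        rec = results.recommendation(key)
        assert rec.delta_kg_ha == pytest.approx(400.0, abs=1e-6)
        band = results.band(key)
        assert (band["lower_kg_ha"] <= band["fit_kg_ha"] + 1e-9).all()
        # corrected curve is the ratio curve scaled and shifted by delta
        assert band["fit_kg_ha"][0] == pytest.approx(
            band["fit"][0] * rec.mean_full_yield_kg_ha + 400.0
        )

    def test_known_truth_inversion_closed_form(self):
        kr = KnownResponse(b1=-0.2, b2=0.0)
        assert kr.retention_point(0.90) == pytest.approx(50.0)
        kr2 = KnownResponse(b1=0.0, b2=-0.1)
        assert kr2.retention_point(0.90) == 100.0
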
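"""Yield-response modelling: stratified curve fits, AIC selection with
plausibility overrides, observed-scale correction, prediction intervals and
inversion for the recommended water-saving percentage.

The response variable is the yield *ratio* y (deficit over fully-irrigated
yield) against the water-saving proportion s in [0, 1].  Records are
stratified by seasonal accumulated precipitation: years above 1000 mm are
removed first (rainfall alone prevents any yield loss there), the remainder
split at 500 mm — a record at exactly 500 mm falls in the 500-1000 mm
stratum.  Within each (cultivar, season, treatment, stratum) subset four
candidate curves are fitted by least squares:

* linear, quadratic, cubic polynomials;
* a decreasing 3-parameter logistic ``y = a / (1 + exp(b (s - c)))``.

Candidates are ranked by AIC = -2 logL + 2 p with a Gaussian likelihood
(p counts the curve coefficients plus one residual-variance term, so
comparisons are internally consistent across forms).  Two plausibility
overrides mirror how a practitioner reads the scatter plots: a curve whose
value at s = 0 exceeds 1 + 0.02 overstates losses under mild deficit and is
disqualified, as is a curve that increases anywhere on [0, 1] (yield cannot
rise with less water).  The best surviving candidate is selected; if none
survives, the best-AIC fit is returned flagged as an implausible fallback.

The selected ratio curve is inverted by bisection for the largest saving s
with predicted retention >= 90%; the kg/ha-scale report applies a
correction term (mean observed yield minus mean simulated fully-irrigated
yield) and carries a 95% prediction band (classical t-based intervals for
the polynomial forms, delta-method plus residual variance for the
logistic).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
import statsmodels.api as sm

from .exceptions import ConfigurationError, EmptySelectionError, FitFailureError

__all__ = [
    "SubsetKey",
    "CurveFit",
    "Recommendation",
    "stratify",
    "fit_candidate",
    "aic",
    "select_best",
    "correction_term",
    "prediction_interval",
    "recommend_saving",
    "YieldResponseModel",
    "YieldResponseResults",
]

FORMS = ("linear", "quadratic", "cubic", "logistic")
_POLY_DEGREE = {"linear": 1, "quadratic": 2, "cubic": 3}

STRATA = ("lt500", "mid")  # <500 mm and 500-1000 mm accumulated precipitation
PRECIP_SPLIT = 500.0
PRECIP_CUTOFF = 1000.0


@dataclass(frozen=True, order=True)
class SubsetKey:
    cultivar: str
    season: str
    treatment: str
    stratum: str  # "lt500" | "mid"


def stratify(
    records: pd.DataFrame,
    split: float = PRECIP_SPLIT,
    cutoff: float = PRECIP_CUTOFF,
) -> dict[SubsetKey, pd.DataFrame]:
    """Split yield-ratio records by precipitation stratum.

    Records with accumulated precipitation strictly above ``cutoff`` are
    dropped; the rest split at ``split`` (boundary value goes to the upper,
    500-1000 mm stratum).
    """
    kept = records[records["acc_precip_mm"] <= cutoff]
    out: dict[SubsetKey, pd.DataFrame] = {}
    for (cultivar, season, treatment), sub in kept.groupby(["cultivar", "season", "treatment"]):
        for stratum in STRATA:
            mask = sub["acc_precip_mm"] < split if stratum == "lt500" else sub["acc_precip_mm"] >= split
            part = sub[mask]
            if len(part):
                out[SubsetKey(cultivar, season, treatment, stratum)] = part.reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Candidate curves
# ---------------------------------------------------------------------------


@dataclass
class CurveFit:
    """One fitted candidate curve on a subset."""

    form: str
    coefficients: np.ndarray  # polynomials: ascending powers; logistic: (a, b, c)
    n: int
    p: int  # curve coefficients + 1 residual-variance term
    rss: float
    loglik: float
    aic: float
    predict: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    intercept_excess: bool = False
    non_monotone: bool = False
    _ols: object = field(default=None, repr=False)  # statsmodels results, polynomials only
    _cov: Optional[np.ndarray] = field(default=None, repr=False)  # logistic coefficient covariance

    @property
    def plausible(self) -> bool:
        return not (self.intercept_excess or self.non_monotone)

    @property
    def k_curve(self) -> int:
        return self.p - 1


def _gaussian_loglik(rss: float, n: int) -> float:
    """Maximised Gaussian log-likelihood with sigma^2 at its MLE rss/n."""
    sigma2 = max(rss / n, 1e-300)
    return -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)


def _logistic(x: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    return a / (1.0 + np.exp(np.clip(b * (x - c), -500, 500)))


def _fit_logistic(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Iterative NLS with documented starts a = max y, b = 5, c = 0.5 and a
    bounded grid of restarts; returns (params, covariance, rss)."""
    starts = [(float(y.max()), b0, c0) for b0 in (5.0, 2.0, 10.0) for c0 in (0.5, 0.3, 0.8)]
    best = None
    for p0 in starts:
        try:
            res = scipy.optimize.least_squares(
                lambda p: _logistic(x, *p) - y,
                x0=p0,
                bounds=([0.0, 0.01, -1.0], [2.0, 100.0, 2.0]),
                max_nfev=2000,
            )
        except Exception:
            continue
        if not res.success and not np.isfinite(res.cost):
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitFailureError("logistic fit did not converge from any start")
    rss = float(2.0 * best.cost)
    n, k = x.size, 3
    dof = max(n - k, 1)
    jtj = best.jac.T @ best.jac
    try:
        cov = np.linalg.inv(jtj) * (rss / dof)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(jtj) * (rss / dof)
    return best.x, cov, rss


def fit_candidate(subset: pd.DataFrame, form: str) -> CurveFit:
    """Least-squares fit of one candidate form to a subset.

    ``subset`` must carry columns ``saving`` (x, in [0, 1]) and ``ratio``
    (y).  Raises :class:`FitFailureError` for a non-converged logistic fit
    and :class:`ConfigurationError` when the subset is too small for the
    form (fewer than k_curve + 2 points).
    """
    if form not in FORMS:
        raise ConfigurationError(f"unknown form {form!r}")
    x = subset["saving"].to_numpy(float)
    y = subset["ratio"].to_numpy(float)
    n = x.size
    k = _POLY_DEGREE[form] + 1 if form in _POLY_DEGREE else 3
    if n < k + 2:
        raise ConfigurationError(f"{form} fit needs at least {k + 2} points, got {n}")

    if form in _POLY_DEGREE:
        deg = _POLY_DEGREE[form]
        exog = np.vander(x, deg + 1, increasing=True)
        ols = sm.OLS(y, exog).fit()
        coeffs = np.asarray(ols.params, float)
        rss = float(ols.ssr)

        def predict(xs, _c=coeffs, _d=deg):
            xs = np.asarray(xs, float)
            return np.vander(np.atleast_1d(xs), _d + 1, increasing=True) @ _c

        cov = None
    else:
        coeffs, cov, rss = _fit_logistic(x, y)
        ols = None

        def predict(xs, _c=coeffs):
            return _logistic(np.atleast_1d(np.asarray(xs, float)), *_c)

    loglik = _gaussian_loglik(rss, n)
    p = k + 1
    fit = CurveFit(
        form=form,
        coefficients=coeffs,
        n=n,
        p=p,
        rss=rss,
        loglik=loglik,
        aic=-2.0 * loglik + 2.0 * p,
        predict=predict,
        _ols=ols,
        _cov=cov,
    )
    _flag_plausibility(fit)
    return fit


def aic(fit: CurveFit) -> float:
    """AIC = -2 logL + 2 p."""
    return -2.0 * fit.loglik + 2.0 * fit.p


_GRID = np.linspace(0.0, 1.0, 1001)


def _flag_plausibility(fit: CurveFit, eps: float = 0.02) -> None:
    vals = fit.predict(_GRID)
    fit.intercept_excess = bool(vals[0] > 1.0 + eps)
    fit.non_monotone = bool(np.any(np.diff(vals) > 1e-9))


def select_best(fits: Sequence[CurveFit]) -> tuple[CurveFit, bool]:
    """Choose the candidate with the smallest AIC among plausible fits.

    Ranking is by AIC ascending with ties broken toward fewer parameters.
    A fit whose value at s = 0 exceeds 1.02, or that increases anywhere on
    [0, 1], is disqualified.  If every candidate is disqualified, the
    best-AIC fit is returned with the fallback flag set.

    Returns ``(chosen fit, implausible_fallback)``.
    """
    fits = list(fits)
    if not fits:
        raise EmptySelectionError("no candidate fits to select among")
    ranked = sorted(fits, key=lambda f: (f.aic, f.p))
    for f in ranked:
        if f.plausible:
            return f, False
    warnings.warn("all candidate curves implausible; falling back to best AIC", stacklevel=2)
    return ranked[0], True


def correction_term(simulated_full: Sequence[float], observed: Sequence[float]) -> float:
    """Observed-scale shift: mean(observed) - mean(simulated fully irrigated)."""
    sim = np.asarray(simulated_full, float)
    obs = np.asarray(observed, float)
    if sim.size == 0 or obs.size == 0:
        raise ConfigurationError("correction term needs non-empty pairing")
    return float(obs.mean() - sim.mean())


def prediction_interval(fit: CurveFit, x_grid: Sequence[float], level: float = 0.95) -> pd.DataFrame:
    """95% prediction band for a *new observation* of the yield ratio.

    Polynomial forms use the classical t-based OLS interval; the logistic
    uses the delta-method variance of the mean curve plus the residual
    variance, with a t quantile on n - 3 degrees of freedom.
    """
    xs = np.atleast_1d(np.asarray(x_grid, float))
    if fit.n <= fit.k_curve:
        raise ConfigurationError("prediction interval needs n > number of curve coefficients")
    if fit._ols is not None:
        deg = _POLY_DEGREE[fit.form]
        exog = np.vander(xs, deg + 1, increasing=True)
        sf = fit._ols.get_prediction(exog).summary_frame(alpha=1.0 - level)
        lower, upper, mean = sf["obs_ci_lower"].to_numpy(), sf["obs_ci_upper"].to_numpy(), sf["mean"].to_numpy()
    else:
        a, b, c = fit.coefficients
        mean = _logistic(xs, a, b, c)
        z = np.exp(np.clip(b * (xs - c), -500, 500))
        denom = (1.0 + z) ** 2
        # d/da, d/db, d/dc of a / (1 + exp(b (x - c)))
        J = np.column_stack(
            [1.0 / (1.0 + z), -a * (xs - c) * z / denom, a * b * z / denom]
        )
        dof = max(fit.n - fit.k_curve, 1)
        sigma2 = fit.rss / dof
        var_mean = np.einsum("ij,jk,ik->i", J, fit._cov, J)
        se = np.sqrt(np.maximum(var_mean + sigma2, 0.0))
        tq = scipy.stats.t.ppf(0.5 + level / 2.0, dof)
        lower, upper = mean - tq * se, mean + tq * se
    return pd.DataFrame({"saving": xs, "fit": mean, "lower": lower, "upper": upper})


def recommend_saving(fit: CurveFit, retention: float = 0.90, tol: float = 1e-6) -> float:
    """Largest saving percentage whose predicted ratio stays >= ``retention``.

    Requires a non-increasing fitted curve.  Returns 100.0 when the curve
    never drops below the retention floor, and ``nan`` when even full
    irrigation (s = 0) is predicted below it (an infeasible subset, reported
    rather than raised).  Otherwise the crossing is located by bisection to
    ``tol`` on the saving scale.
    """
    if fit.non_monotone:
        raise ConfigurationError("recommendation requires a non-increasing fitted curve")
    f0 = float(fit.predict(0.0)[0])
    f1 = float(fit.predict(1.0)[0])
    if f1 >= retention:
        return 100.0
    if f0 < retention:
        return float("nan")
    lo, hi = 0.0, 1.0  # invariant: f(lo) >= retention > f(hi)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if float(fit.predict(mid)[0]) >= retention:
            lo = mid
        else:
            hi = mid
    return 100.0 * lo


# ---------------------------------------------------------------------------
# Model / Results wrappers
# ---------------------------------------------------------------------------


@dataclass
class Recommendation:
    key: SubsetKey
    form: str
    percentage: float  # water-saving % at 90% retention; nan if infeasible
    feasible: bool
    implausible_fallback: bool
    delta_kg_ha: Optional[float]  # observed-scale correction; None if no observations
    mean_full_yield_kg_ha: float


class YieldResponseModel:
    """Stratified yield-response model over a long table of yield-ratio records.

    Parameters
    ----------
    records : pandas.DataFrame
        Output of :func:`paddysim.scenarios.run_grid` (or any frame with
        columns ``cultivar``, ``season``, ``year``, ``treatment``,
        ``saving``, ``ratio``, ``full_yield_kg_ha``, ``acc_precip_mm``).
        Yearly records, not across-year means, are fitted.
    observed_yields : pandas.DataFrame, optional
        Long table (cultivar, season, year, yield_kg_ha) used for the
        per-(cultivar, season) observed-scale correction term.
    retention : float
        Yield-retention floor for the recommendation (default 0.90).
    """

    def __init__(
        self,
        records: pd.DataFrame,
        observed_yields: Optional[pd.DataFrame] = None,
        retention: float = 0.90,
        forms: Sequence[str] = FORMS,
    ):
        required = {"cultivar", "season", "treatment", "saving", "ratio", "acc_precip_mm"}
        missing = required - set(records.columns)
        if missing:
            raise ConfigurationError(f"records missing columns {sorted(missing)}")
        if not 0.0 < retention <= 1.0:
            raise ConfigurationError("retention must lie in (0, 1]")
        self.records = records
        self.observed_yields = observed_yields
        self.retention = retention
        self.forms = tuple(forms)

    @classmethod
    def from_dataframe(cls, records: pd.DataFrame, **kwargs) -> "YieldResponseModel":
        return cls(records, **kwargs)

    def fit(self) -> "YieldResponseResults":
        subsets = stratify(self.records)
        fits: dict[SubsetKey, dict[str, CurveFit]] = {}
        failures: list[tuple[SubsetKey, str, str]] = []
        selected: dict[SubsetKey, CurveFit] = {}
        fallback: dict[SubsetKey, bool] = {}
        for key, sub in subsets.items():
            per_form = {}
            for form in self.forms:
                try:
                    per_form[form] = fit_candidate(sub, form)
                except (FitFailureError, ConfigurationError) as exc:
                    failures.append((key, form, str(exc)))
            if not per_form:
                failures.append((key, "<all>", "no form could be fitted"))
                continue
            fits[key] = per_form
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                selected[key], fallback[key] = select_best(list(per_form.values()))
        return YieldResponseResults(self, subsets, fits, selected, fallback, failures)


class YieldResponseResults:
    """Fitted curves, selections, recommendations and bands per subset."""

    def __init__(self, model, subsets, fits, selected, fallback, failures):
        self.model = model
        self.subsets = subsets
        self.fits = fits
        self.selected = selected
        self.fallback = fallback
        self.failures = failures
        self._corrections = self._compute_corrections()

    def _compute_corrections(self) -> dict[tuple[str, str], float]:
        obs = self.model.observed_yields
        if obs is None:
            return {}
        out = {}
        recs = self.model.records
        full = recs[recs["saving"] == 0.0]
        for (cultivar, season), sub in full.groupby(["cultivar", "season"]):
            sim_by_year = sub.groupby("year")["full_yield_kg_ha"].first()
            o = obs[(obs["cultivar"] == cultivar) & (obs["season"] == season)]
            paired = sim_by_year.index.intersection(o["year"])
            if len(paired) == 0:
                continue
            sim_vals = sim_by_year.loc[paired].to_numpy()
            obs_vals = o.set_index("year").loc[paired, "yield_kg_ha"].to_numpy()
            out[(cultivar, season)] = correction_term(sim_vals, obs_vals)
        return out

    def correction(self, cultivar: str, season: str) -> Optional[float]:
        return self._corrections.get((cultivar, season))

    def recommendation(self, key: SubsetKey) -> Recommendation:
        fit = self.selected[key]
        if self.fallback[key]:
            pct, feasible = float("nan"), False
        else:
            pct = recommend_saving(fit, self.model.retention)
            feasible = not np.isnan(pct)
        sub = self.subsets[key]
        mean_full = float(sub["full_yield_kg_ha"].mean())
        return Recommendation(
            key=key,
            form=fit.form,
            percentage=pct,
            feasible=feasible,
            implausible_fallback=self.fallback[key],
            delta_kg_ha=self.correction(key.cultivar, key.season),
            mean_full_yield_kg_ha=mean_full,
        )

    def recommendations(self) -> dict[SubsetKey, Recommendation]:
        return {key: self.recommendation(key) for key in sorted(self.selected)}

    def band(self, key: SubsetKey, n_points: int = 51, level: float = 0.95) -> pd.DataFrame:
        """Ratio-scale prediction band plus the corrected kg/ha scale."""
        fit = self.selected[key]
        grid = np.linspace(0.0, 1.0, n_points)
        band = prediction_interval(fit, grid, level)
        rec = self.recommendation(key)
        scale = rec.mean_full_yield_kg_ha
        delta = rec.delta_kg_ha or 0.0
        for col in ("fit", "lower", "upper"):
            band[f"{col}_kg_ha"] = band[col] * scale + delta
        return band

    def aic_table(self) -> pd.DataFrame:
        rows = []
        for key, per_form in sorted(self.fits.items()):
            for form, f in per_form.items():
                rows.append(
                    {
                        **key.__dict__,
                        "form": form,
                        "n": f.n,
                        "p": f.p,
                        "rss": f.rss,
                        "loglik": f.loglik,
                        "aic": f.aic,
                        "plausible": f.plausible,
                        "selected": self.selected[key].form == form,
                    }
                )
        return pd.DataFrame(rows)

    def summary(self) -> pd.DataFrame:
        """Table of recommended water-saving percentages per subset."""
        rows = []
        for key, rec in self.recommendations().items():
            rows.append(
                {
                    "cultivar": key.cultivar,
                    "season": key.season,
                    "treatment": key.treatment,
                    "stratum": key.stratum,
                    "form": rec.form,
                    "saving_pct_at_90": round(rec.percentage, 2) if rec.feasible else float("nan"),
                    "feasible": rec.feasible,
                    "fallback": rec.implausible_fallback,
                    "delta_kg_ha": rec.delta_kg_ha,
                }
            )
        return pd.DataFrame(rows)
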
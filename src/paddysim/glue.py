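"""Generalized Likelihood Uncertainty Estimation (GLUE) of genotype coefficients.

GLUE is a Monte-Carlo Bayesian calibration: parameter sets are drawn from
independent uniform priors, each set is pushed through the forward crop
model, and a Gaussian likelihood of the observed-vs-simulated yield
mismatch

    L(theta_i | O) = prod_j (2 pi sigma0^2)^(-1/2)
                     exp(-(O_j - S_j(theta_i))^2 / (2 sigma0^2))

is converted to normalised weights p(theta_i) = L_i / sum_i L_i.  The
calibrated estimate is the weighted posterior mean sum_i p(theta_i) theta_i.
All weight arithmetic happens in log space (log-sum-exp), so the procedure
is stable for log-likelihood spreads of 1e4 and more.

Calibration is two-stage, following DSSAT-GLUE practice: the first stage
calibrates the phenology coefficients (P1, P2O, P2R, P5) with the growth
coefficients held at their defaults; the second fixes the stage-1 posterior
means and calibrates the growth coefficients (G1, G2, G3, G4).  Each stage
draws its own pool (default 10,000 sets).

The model-error variance sigma0^2 is not prescribed by the method; the
default here is the sample variance of the observed yields (a
scale-matching convention), and a constant override is accepted — see
``docs/methods.md`` for the discussion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .cultivars import GROWTH_PARAMS, PHENOLOGY_PARAMS, GenotypeParams
from .exceptions import ConfigurationError, DegenerateCalibrationError, PaddysimError

__all__ = [
    "PriorSpec",
    "sample_prior",
    "glue_log_likelihood",
    "glue_likelihood",
    "posterior_weights",
    "posterior_mean",
    "GlueCalibration",
    "GlueStage",
    "GlueResults",
]


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform prior bounds per parameter."""

    bounds: dict  # name -> (low, high)

    def __post_init__(self):
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                if lo == hi:
                    continue  # point prior is allowed
                raise ConfigurationError(f"prior for {name}: low {lo} must not exceed high {hi}")

    @property
    def names(self) -> tuple:
        return tuple(self.bounds)

    @classmethod
    def around(cls, center: GenotypeParams, names: Sequence[str], frac: float = 0.5) -> "PriorSpec":
        """Bounds at +/- ``frac`` of a reference coefficient set (clipped to
        keep P2O inside its physical (0, 24) h range)."""
        b = {}
        for n in names:
            c = getattr(center, n)
            lo, hi = c * (1 - frac), c * (1 + frac)
            if n == "P2O":
                lo, hi = max(lo, 1e-6), min(hi, 23.999)
            b[n] = (lo, hi)
        return cls(b)


def sample_prior(prior: PriorSpec, n: int, seed: Optional[int] = None) -> pd.DataFrame:
    """Draw ``n`` i.i.d. uniform parameter sets; reproducible by seed."""
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    cols = {}
    for name, (lo, hi) in prior.bounds.items():
        cols[name] = rng.uniform(lo, hi, n) if lo < hi else np.full(n, lo)
    return pd.DataFrame(cols)


def glue_log_likelihood(
    observed: Sequence[float], simulated: Sequence[float], sigma0_sq: float
) -> float:
    """Gaussian log-likelihood of the observation-simulation residuals."""
    obs = np.asarray(observed, float)
    sim = np.asarray(simulated, float)
    if obs.shape != sim.shape or obs.size < 1:
        raise ConfigurationError("observed and simulated must be equal-length, non-empty")
    if not sigma0_sq > 0:
        raise ConfigurationError("sigma0_sq must be strictly positive")
    resid = obs - sim
    m = obs.size
    return float(-0.5 * m * np.log(2.0 * np.pi * sigma0_sq) - np.sum(resid**2) / (2.0 * sigma0_sq))


def glue_likelihood(observed, simulated, sigma0_sq: float) -> float:
    """The likelihood itself; prefer the log form for any arithmetic."""
    return float(np.exp(glue_log_likelihood(observed, simulated, sigma0_sq)))


def posterior_weights(log_likelihoods: Sequence[float]) -> np.ndarray:
    """Normalise log-likelihoods to weights via log-sum-exp.

    Entries of -inf (failed simulations) receive exactly zero weight.  All
    entries -inf is a degenerate calibration and raises.
    """
    ll = np.asarray(log_likelihoods, float)
    if ll.size == 0 or np.all(np.isneginf(ll)):
        raise DegenerateCalibrationError("no draw achieved non-zero likelihood")
    if np.any(np.isnan(ll)) or np.any(np.isposinf(ll)):
        raise ConfigurationError("log-likelihoods must be finite or -inf")
    log_z = logsumexp(ll)
    w = np.exp(ll - log_z)
    return w / w.sum()  # guard the last 1e-16 of normalisation


def posterior_mean(weights: np.ndarray, draws: pd.DataFrame) -> dict:
    """Coordinate-wise weighted average of the draws."""
    w = np.asarray(weights, float)
    if w.shape[0] != len(draws):
        raise ConfigurationError("weights and draws must align")
    out = {}
    for c in draws.columns:
        v = draws[c].to_numpy()
        # a degenerate (point-prior) coordinate averages to itself exactly
        out[c] = float(v[0]) if v.min() == v.max() else float(np.dot(w, v))
    return out


@dataclass
class GlueStage:
    """One calibration stage: the draw pool, weights and posterior summary."""

    names: tuple
    draws: pd.DataFrame
    log_likelihoods: np.ndarray
    weights: np.ndarray
    posterior: dict
    n_failed: int
    sigma0_sq: float
    seed: int

    def effective_sample_size(self) -> float:
        return float(1.0 / np.sum(self.weights**2))

    def to_frame(self) -> pd.DataFrame:
        out = self.draws.copy()
        out["log_likelihood"] = self.log_likelihoods
        out["weight"] = self.weights
        return out


class GlueResults:
    """Combined two-stage calibration result."""

    def __init__(self, stage1: GlueStage, stage2: GlueStage, estimate: GenotypeParams):
        self.stage1 = stage1
        self.stage2 = stage2
        self.estimate = estimate

    def summary(self) -> pd.DataFrame:
        rows = []
        for stage_no, st in ((1, self.stage1), (2, self.stage2)):
            for name in st.names:
                lo, hi = st.draws[name].min(), st.draws[name].max()
                rows.append(
                    {
                        "stage": stage_no,
                        "parameter": name,
                        "estimate": st.posterior[name],
                        "prior_low": float(lo),
                        "prior_high": float(hi),
                        "ess": st.effective_sample_size(),
                        "n_failed": st.n_failed,
                    }
                )
        return pd.DataFrame(rows)

    def summary_dict(self) -> dict:
        return {
            "estimate": self.estimate.as_dict(),
            "stage1": {"ess": self.stage1.effective_sample_size(), "n_failed": self.stage1.n_failed},
            "stage2": {"ess": self.stage2.effective_sample_size(), "n_failed": self.stage2.n_failed},
        }


class GlueCalibration:
    """Two-stage GLUE calibration model.

    Parameters
    ----------
    forward : callable
        ``forward(params: GenotypeParams) -> sequence of simulated yields``
        aligned with ``observed``.  Must be deterministic in ``params``.
        A draw on which it raises a package error is assigned zero weight.
    observed : sequence of float
        Observed seasonal yields (kg/ha); at least 3.
    defaults : GenotypeParams
        Starting coefficient set; growth coefficients are held at these
        values during stage 1, and the non-calibrated coordinates of the
        final estimate come from here.
    priors_phenology, priors_growth : PriorSpec, optional
        Default: +/-50% around ``defaults``.
    sigma0_sq : float, optional
        Model-error variance; default: sample variance of ``observed``.
    """

    def __init__(
        self,
        forward: Callable[[GenotypeParams], Sequence[float]],
        observed: Sequence[float],
        defaults: GenotypeParams,
        priors_phenology: Optional[PriorSpec] = None,
        priors_growth: Optional[PriorSpec] = None,
        sigma0_sq: Optional[float] = None,
    ):
        self.forward = forward
        self.observed = np.asarray(observed, float)
        if self.observed.size < 3:
            raise ConfigurationError("calibration needs at least 3 observations")
        self.defaults = defaults
        self.priors_phenology = priors_phenology or PriorSpec.around(defaults, PHENOLOGY_PARAMS)
        self.priors_growth = priors_growth or PriorSpec.around(defaults, GROWTH_PARAMS)
        if set(self.priors_phenology.names) != set(PHENOLOGY_PARAMS):
            raise ConfigurationError("phenology priors must cover exactly P1, P2O, P2R, P5")
        if set(self.priors_growth.names) != set(GROWTH_PARAMS):
            raise ConfigurationError("growth priors must cover exactly G1, G2, G3, G4")
        if sigma0_sq is None:
            sigma0_sq = float(np.var(self.observed, ddof=1))
            if not sigma0_sq > 0:
                raise ConfigurationError(
                    "observed yields have zero variance; pass sigma0_sq explicitly"
                )
        self.sigma0_sq = float(sigma0_sq)

    def _run_stage(self, prior: PriorSpec, base: GenotypeParams, n: int, seed: int) -> GlueStage:
        draws = sample_prior(prior, n, seed)
        ll = np.empty(n)
        n_failed = 0
        for i in range(n):
            theta = base.replace(**{k: float(draws.iloc[i][k]) for k in prior.names})
            try:
                sim = self.forward(theta)
                ll[i] = glue_log_likelihood(self.observed, sim, self.sigma0_sq)
            except PaddysimError:
                ll[i] = -np.inf
                n_failed += 1
        w = posterior_weights(ll)
        post = posterior_mean(w, draws)
        return GlueStage(
            names=prior.names,
            draws=draws,
            log_likelihoods=ll,
            weights=w,
            posterior=post,
            n_failed=n_failed,
            sigma0_sq=self.sigma0_sq,
            seed=seed,
        )

    def fit(self, n_draws: int = 10000, seed: int = 0) -> GlueResults:
        if n_draws < 1:
            raise ConfigurationError("n_draws must be >= 1")
        stage1 = self._run_stage(self.priors_phenology, self.defaults, n_draws, seed)
        mid = self.defaults.replace(**stage1.posterior)
        # a distinct but seed-derived stream for the second pool
        stage2 = self._run_stage(self.priors_growth, mid, n_draws, seed + 1)
        estimate = mid.replace(**stage2.posterior)
        return GlueResults(stage1, stage2, estimate)
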
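"""Uncertainty propagation: Wald intervals and Monte Carlo trajectory bands.

Confidence intervals are computed on the log-parameter scale,
exp(log theta_hat +- z * SE_log), which respects positivity of rate
constants.  Trajectory bands follow the parametric Monte Carlo recipe:
draw parameter sets around the fitted values, re-integrate the ODE
system for each draw, and take pointwise 2.5th/97.5th percentiles.

Two sampling scales are offered.  The default draws normally in
log-parameters (consistent with the log-scale intervals and positivity);
``scale="natural"`` draws normally on the original scale with truncation
at zero, the literal textbook procedure.  Draws are independent per
parameter by default; ``correlated=True`` uses the full fitted
covariance instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import BandFailure, InvalidInputError, IntegrationFailure
from .model_core import SPECIES, ExperimentDescriptor, RateConstants
from .fitting import FitResult
from .simulator import Trajectory, default_grid, integrate


@dataclass(frozen=True)
class ParameterInterval:
    name: str
    estimate: float
    lower: float
    upper: float
    unbounded: bool = False


def wald_ci(fit: FitResult, level: float = 0.95) -> Dict[str, ParameterInterval]:
    """Back-transformed log-scale Wald intervals for every fitted constant.

    A non-finite standard error yields the whole positive axis with the
    ``unbounded`` flag set rather than an error, since that is exactly
    the "data carry no information" outcome the diagnostics report on.
    """
    if not fit.converged:
        raise InvalidInputError("Wald intervals require a converged fit")
    if not 0 < level < 1:
        raise InvalidInputError("level must be in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    out: Dict[str, ParameterInterval] = {}
    for name, est, se in zip(fit.param_names, fit.estimates.as_array(), fit.log_se):
        with np.errstate(over="ignore", under="ignore"):
            lower = float(est * np.exp(-z * se)) if np.isfinite(se) else 0.0
            upper = float(est * np.exp(z * se)) if np.isfinite(se) else np.inf
        # an SE so large that the bounds overflow/underflow carries no
        # information either: flag the whole positive axis
        if not np.isfinite(se) or lower <= 0.0 or not np.isfinite(upper):
            out[name] = ParameterInterval(name, float(est), 0.0, np.inf,
                                          unbounded=True)
        else:
            out[name] = ParameterInterval(name, float(est), lower, upper)
    return out


@dataclass(frozen=True)
class MonteCarloBands:
    """Pointwise 95% envelopes of simulated trajectories, per species."""

    times: np.ndarray
    lower: np.ndarray  # (n_times, n_species)
    upper: np.ndarray
    n_draws: int
    seed: int
    n_failed: int
    best_fit: Trajectory

    def band(self, species: str) -> Tuple[np.ndarray, np.ndarray]:
        idx = SPECIES.index(species)
        return self.lower[:, idx], self.upper[:, idx]

    def to_frame(self) -> pd.DataFrame:
        n = len(self.times)
        return pd.DataFrame({
            "time_s": np.repeat(self.times, len(SPECIES)),
            "species": np.tile(SPECIES, n),
            "lower": self.lower.reshape(-1),
            "upper": self.upper.reshape(-1),
        })


def _draw_parameters(
    fit: FitResult,
    n_draws: int,
    rng: np.random.Generator,
    scale: str,
    correlated: bool,
) -> np.ndarray:
    est = fit.estimates.as_array()
    log_est = np.log(est)
    if scale == "log":
        if correlated:
            draws = rng.multivariate_normal(log_est, fit.covariance, size=n_draws)
        else:
            draws = rng.normal(log_est, fit.log_se, size=(n_draws, len(est)))
        return np.exp(draws)
    if scale == "natural":
        se_nat = est * fit.log_se  # delta-method SE on the original scale
        if correlated:
            cov_nat = fit.covariance * np.outer(est, est)
            draws = rng.multivariate_normal(est, cov_nat, size=n_draws)
        else:
            draws = rng.normal(est, se_nat, size=(n_draws, len(est)))
        return np.clip(draws, 0.0, None)
    raise InvalidInputError(f"unknown sampling scale {scale!r}")


def monte_carlo_bands(
    fit: FitResult,
    descriptor: Optional[ExperimentDescriptor] = None,
    n_draws: int = 100,
    seed: int = 0,
    grid: Optional[np.ndarray] = None,
    scale: str = "log",
    correlated: bool = False,
    rtol: float = 1e-7,
    atol: float = 1e-11,
) -> MonteCarloBands:
    """Parametric Monte Carlo 95% bands around the fitted trajectory.

    Draws that fail to integrate are dropped and counted in
    ``n_failed``; more than 50% failures raises :class:`BandFailure`.
    Deterministic for a given ``seed``.
    """
    if n_draws < 1:
        raise InvalidInputError("n_draws must be >= 1")
    if not np.all(np.isfinite(fit.log_se)):
        raise InvalidInputError("Monte Carlo bands require finite standard errors")
    if descriptor is None:
        descriptor = fit.descriptor
    if grid is None:
        grid = default_grid(descriptor)
    rng = np.random.default_rng(seed)
    draws = _draw_parameters(fit, n_draws, rng, scale, correlated)

    best = integrate(fit.estimates, descriptor, grid=grid, rtol=rtol, atol=atol)
    sims = []
    n_failed = 0
    for row in draws:
        try:
            params = RateConstants.from_array(row, variant=fit.variant)
            sims.append(integrate(params, descriptor, grid=grid,
                                  rtol=rtol, atol=atol).states)
        except (IntegrationFailure, InvalidInputError):
            n_failed += 1
    if n_failed > 0.5 * n_draws:
        raise BandFailure(f"{n_failed}/{n_draws} Monte Carlo draws failed to integrate")
    stack = np.asarray(sims)
    lower = np.percentile(stack, 2.5, axis=0)
    upper = np.percentile(stack, 97.5, axis=0)
    return MonteCarloBands(times=np.asarray(grid, float), lower=lower, upper=upper,
                           n_draws=n_draws, seed=seed, n_failed=n_failed,
                           best_fit=best)


def write_bands(bands: MonteCarloBands, path) -> None:
    bands.to_frame().to_csv(path, index=False)
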
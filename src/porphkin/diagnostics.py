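"""Fit-quality and identifiability diagnostics, and model selection.

Standardised residuals (residual / pooled sigma-hat) are reported
against both time and fitted value; a positive slope of |residual|
versus fitted value is the signature of the multiplicative
(heteroscedastic) detector noise.  Parameter correlations above 0.9
flag practical-identifiability problems; the matrix is restricted to
k1–k3 so fits of both model variants remain comparable.  The choice
between the purely catalytic model and its extension with a direct
(non-catalytic) oxidation channel follows parsimony: the extra
parameter must both lower AIC by a margin and carry a non-negligible
share of the substrate flux.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .fitting import FitResult, objective
from .model_core import EXTENDED, STANDARD
from .simulator import integrate
from .synthetic_data import KineticDataset

#: AIC sentinel for a perfect (zero-SSR) fit
AIC_PERFECT = -math.inf

CORE_PARAMS = ("k1", "k2", "k3")


def standardized_residuals(fit: FitResult, dataset: KineticDataset) -> pd.DataFrame:
    """Residual table with residual / sigma-hat per observation.

    Columns: replicate, time_min, observed, fitted, residual,
    std_residual.  sigma-hat is the pooled sqrt(ssr / (n_obs - n_params)).
    """
    if fit.n_obs <= fit.n_params:
        raise InvalidInputError("sigma-hat undefined: n_obs <= n_params")
    tab = dataset.channel("substrate")
    resid = objective(np.log(fit.estimates.as_array()), dataset,
                      variant=fit.variant, s0_area=fit.s0_refined)
    fitted = tab["peak_area"].to_numpy(float) - resid
    sigma = fit.residual_sd
    return pd.DataFrame({
        "replicate": tab["replicate"],
        "time_min": tab["time_min"],
        "observed": tab["peak_area"],
        "fitted": fitted,
        "residual": resid,
        "std_residual": resid / sigma if sigma > 0 else np.zeros_like(resid),
    })


def heteroscedasticity_slope(residual_table: pd.DataFrame) -> float:
    """OLS slope of |residual| on fitted value (area units per area unit)."""
    x = residual_table["fitted"].to_numpy(float)
    y = np.abs(residual_table["residual"].to_numpy(float))
    if np.ptp(x) == 0:
        return 0.0
    return float(np.polyfit(x, y, 1)[0])


def parameter_correlation(
    fit: FitResult, threshold: float = 0.9
) -> Tuple[pd.DataFrame, List[Tuple[str, str, float]]]:
    """Correlation matrix of the fitted log-parameters, restricted to
    k1–k3, plus the pairs whose |r| exceeds ``threshold``.

    Parameters whose covariance diagonal is zero (a direction the data
    do not constrain at all, e.g. after a pseudo-inverse) get NaN
    correlations and are reported as undefined rather than flagged.
    """
    names = list(fit.param_names)
    cov = np.asarray(fit.covariance, dtype=float)
    keep = [i for i, n in enumerate(names) if n in CORE_PARAMS]
    cov = cov[np.ix_(keep, keep)]
    names = [names[i] for i in keep]
    d = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = cov / np.outer(d, d)
    corr[~np.isfinite(corr)] = np.nan
    np.fill_diagonal(corr, 1.0)
    corr = np.clip(corr, -1.0, 1.0)
    flagged = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            r = corr[i, j]
            if np.isfinite(r) and abs(r) > threshold:
                flagged.append((names[i], names[j], float(r)))
    return pd.DataFrame(corr, index=names, columns=names), flagged


def aic(fit: FitResult) -> float:
    """Gaussian AIC with additive constants dropped:
    n * ln(ssr/n) + 2 * n_params.  Only differences between fits of the
    same data are meaningful."""
    if fit.ssr <= 0:
        return AIC_PERFECT
    return fit.n_obs * math.log(fit.ssr / fit.n_obs) + 2 * fit.n_params


def adjusted_r2(fit: FitResult, dataset: KineticDataset) -> float:
    """1 - [ssr/(n-p)] / [tss/(n-1)] with tss about the observed mean."""
    obs = dataset.channel("substrate")["peak_area"].to_numpy(float)
    if len(obs) != fit.n_obs:
        raise InvalidInputError("fit and dataset observation counts differ")
    tss = float(np.sum((obs - obs.mean()) ** 2))
    if tss == 0:
        raise InvalidInputError("zero total sum of squares")
    return 1.0 - (fit.ssr / (fit.n_obs - fit.n_params)) / (tss / (fit.n_obs - 1))


@dataclass(frozen=True)
class DiagnosticsReport:
    residual_table: pd.DataFrame
    correlation: pd.DataFrame
    high_corr_pairs: List[Tuple[str, str, float]]
    aic: float
    r2_adj: float
    heteroscedasticity_slope: float
    identifiability_warning: bool

    def to_dict(self) -> dict:
        return {
            "aic": self.aic,
            "r2_adj": self.r2_adj,
            "heteroscedasticity_slope": self.heteroscedasticity_slope,
            "high_corr_pairs": [
                {"pair": [a, b], "r": r} for a, b, r in self.high_corr_pairs
            ],
            "correlation": self.correlation.to_dict(),
            "identifiability_warning": self.identifiability_warning,
        }


def diagnostics_report(
    fit: FitResult, dataset: KineticDataset, corr_threshold: float = 0.9
) -> DiagnosticsReport:
    resid = standardized_residuals(fit, dataset)
    corr, flagged = parameter_correlation(fit, corr_threshold)
    return DiagnosticsReport(
        residual_table=resid,
        correlation=corr,
        high_corr_pairs=flagged,
        aic=aic(fit),
        r2_adj=adjusted_r2(fit, dataset),
        heteroscedasticity_slope=heteroscedasticity_slope(resid),
        identifiability_warning=fit.identifiability_warning or bool(flagged),
    )


@dataclass(frozen=True)
class ModelSelection:
    chosen: Optional[str]  # None when deferred
    rationale: str
    aic_standard: float
    aic_extended: float
    k4_flux_fraction: Optional[float] = None


def select_model(
    fit_standard: FitResult,
    fit_extended: FitResult,
    delta_aic_min: float = 2.0,
    flux_fraction_min: float = 0.05,
) -> ModelSelection:
    """Parsimony rule between the catalytic and extended models.

    The extended model is adopted only if (a) its AIC beats the standard
    model by at least ``delta_aic_min`` AND (b) the direct-oxidation
    channel is non-negligible: k4 * max([S][tBuOOH]) along the fitted
    extended trajectory exceeds ``flux_fraction_min`` of
    k2 * max([S][FeTPPS*]).  Ties and negligible k4 keep the standard
    model; an unconverged fit defers the decision.
    """
    if fit_standard.variant != STANDARD or fit_extended.variant != EXTENDED:
        raise InvalidInputError("pass (standard fit, extended fit) in that order")
    if fit_standard.n_obs != fit_extended.n_obs or \
            fit_standard.descriptor != fit_extended.descriptor:
        raise InvalidInputError("model selection requires fits of the same dataset")
    a_std, a_ext = aic(fit_standard), aic(fit_extended)
    if not (fit_standard.converged and fit_extended.converged):
        return ModelSelection(None, "selection deferred: a fit did not converge",
                              a_std, a_ext)

    est = fit_extended.estimates
    traj = integrate(est, fit_extended.descriptor)
    s = traj.species("substrate")
    flux_cat = est.k2 * float(np.max(s * traj.species("fetpps_star")))
    flux_direct = float(est.k4) * float(np.max(s * traj.species("tbuooh")))
    if flux_direct == 0.0:
        frac = 0.0
    elif flux_cat == 0.0:
        frac = math.inf
    else:
        frac = flux_direct / flux_cat

    if a_ext <= a_std - delta_aic_min and frac > flux_fraction_min:
        return ModelSelection(
            EXTENDED,
            f"extended model: dAIC = {a_std - a_ext:.2f} >= {delta_aic_min} and "
            f"non-catalytic flux share {frac:.3f} > {flux_fraction_min}",
            a_std, a_ext, frac)
    return ModelSelection(
        STANDARD,
        f"standard model retained (parsimony): dAIC = {a_std - a_ext:.2f}, "
        f"non-catalytic flux share {frac:.3f}",
        a_std, a_ext, frac)
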
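"""Residual diagnostics, correlation flags, AIC/R2 and model selection."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

from porphkin.diagnostics import (
    adjusted_r2,
    aic,
    diagnostics_report,
    heteroscedasticity_slope,
    parameter_correlation,
    select_model,
    standardized_residuals,
)
from porphkin.errors import InvalidInputError
from porphkin.fitting import FitOptions, fit_model, fit_nested_pair
from porphkin.synthetic_data import (
    DEFAULT_TRUTH,
    NoiseModel,
    default_design,
    generate_dataset,
)


class TestStandardizedResiduals:
    def test_noiseless_fit_residuals_are_tiny(self, noiseless_fit, noiseless_dataset):
        tab = standardized_residuals(noiseless_fit, noiseless_dataset)
        # sigma-hat is itself tiny, so compare raw residuals to the scale
        assert np.max(np.abs(tab["residual"])) < 1e-6 * 5e-4

    def test_sum_of_squares_normalisation(self, noisy_fit, noisy_dataset):
        """By construction sum(std_residual^2) = n_obs - n_params at the
        least-squares optimum."""
        tab = standardized_residuals(noisy_fit, noisy_dataset)
        assert np.sum(tab["std_residual"] ** 2) == pytest.approx(
            noisy_fit.n_obs - noisy_fit.n_params)

    def test_heteroscedastic_noise_shows_positive_slope(self, noisy_fit, noisy_dataset):
        tab = standardized_residuals(noisy_fit, noisy_dataset)
        assert heteroscedasticity_slope(tab) > 0


class TestParameterCorrelation:
    def test_diagonal_covariance_flags_nothing(self, noiseless_fit):
        fit = dataclasses.replace(noiseless_fit, covariance=np.diag([1.0, 2.0, 3.0]))
        corr, flagged = parameter_correlation(fit)
        np.testing.assert_allclose(np.diag(corr), 1.0)
        assert flagged == []

    def test_high_correlation_is_flagged(self, noiseless_fit):
        cov = np.array([[1.0, 0.95, 0.0], [0.95, 1.0, 0.0], [0.0, 0.0, 1.0]])
        fit = dataclasses.replace(noiseless_fit, covariance=cov)
        corr, flagged = parameter_correlation(fit, threshold=0.9)
        assert corr.loc["k1", "k2"] == pytest.approx(0.95)
        assert ("k1", "k2", pytest.approx(0.95)) in [
            (a, b, pytest.approx(r)) for a, b, r in flagged]

    def test_matrix_restricted_to_core_constants(self, quick_options, noiseless_dataset):
        _, fit_ext = fit_nested_pair(noiseless_dataset, quick_options)
        corr, _ = parameter_correlation(fit_ext)
        assert list(corr.columns) == ["k1", "k2", "k3"]

    def test_truncated_early_sampling_degrades_identifiability(self):
        """Dropping every sample before 10 min removes the early kinetic
        phase; |r| > 0.9 pairs should be at least as frequent as on the
        full design (over a batch of seeds)."""
        full_design = default_design()
        late = tuple(t for t in full_design.sample_times if t >= 10)
        truncated = full_design.replace(sample_times=late)
        n_full = n_trunc = 0
        for seed in range(12):
            noise = NoiseModel(cv=0.05, seed=seed)
            f_full = fit_model(generate_dataset(DEFAULT_TRUTH, full_design, noise),
                               FitOptions(n_starts=2, seed=seed))
            f_trunc = fit_model(generate_dataset(DEFAULT_TRUTH, truncated, noise),
                                FitOptions(n_starts=2, seed=seed))
            n_full += bool(parameter_correlation(f_full)[1])
            n_trunc += bool(parameter_correlation(f_trunc)[1])
        assert n_trunc >= n_full


class TestFitStatistics:
    def test_aic_formula(self, noisy_fit):
        expected = noisy_fit.n_obs * math.log(noisy_fit.ssr / noisy_fit.n_obs) \
            + 2 * noisy_fit.n_params
        assert aic(noisy_fit) == pytest.approx(expected)

    def test_extra_parameter_without_improvement_costs_two(self, noisy_fit):
        bloated = dataclasses.replace(noisy_fit, n_params=noisy_fit.n_params + 1)
        assert aic(bloated) == pytest.approx(aic(noisy_fit) + 2)

    def test_perfect_fit_aic_sentinel(self, noisy_fit):
        perfect = dataclasses.replace(noisy_fit, ssr=0.0)
        assert aic(perfect) == -math.inf

    def test_r2_adj_near_one_for_noiseless_fit(self, noiseless_fit, noiseless_dataset):
        assert adjusted_r2(noiseless_fit, noiseless_dataset) > 1 - 1e-9

    def test_r2_adj_below_plain_r2(self, noisy_fit, noisy_dataset):
        obs = noisy_dataset.channel("substrate")["peak_area"].to_numpy()
        tss = np.sum((obs - obs.mean()) ** 2)
        r2 = 1 - noisy_fit.ssr / tss
        assert adjusted_r2(noisy_fit, noisy_dataset) <= r2

    def test_report_bundles_all_diagnostics(self, noisy_fit, noisy_dataset):
        rep = diagnostics_report(noisy_fit, noisy_dataset)
        assert rep.aic == pytest.approx(aic(noisy_fit))
        assert {"aic", "r2_adj", "heteroscedasticity_slope"} <= set(rep.to_dict())


@pytest.fixture(scope="module")
def nested_fits(noisy_dataset):
    return fit_nested_pair(noisy_dataset, FitOptions(n_starts=3, seed=0))


class TestSelectModel:
    def test_requires_same_dataset(self, nested_fits, quick_options):
        fit_std, _ = nested_fits
        other = generate_dataset(
            DEFAULT_TRUTH,
            default_design().replace(sample_times=(2, 4, 6, 8, 10, 15, 20, 25)),
            NoiseModel(cv=0.05, seed=0))
        _, fit_ext_other = fit_nested_pair(other, FitOptions(n_starts=2, seed=0))
        with pytest.raises(InvalidInputError):
            select_model(fit_std, fit_ext_other)

    def test_identical_aic_retains_standard(self, nested_fits):
        fit_std, fit_ext = nested_fits
        tied = dataclasses.replace(fit_ext, ssr=fit_std.ssr * (1 + 1e-12))
        sel = select_model(fit_std, dataclasses.replace(
            tied, n_params=fit_std.n_params))  # same complexity -> same AIC
        assert sel.chosen == "standard"

    def test_never_extended_when_k4_is_zero(self, nested_fits):
        fit_std, fit_ext = nested_fits
        k4_zero = dataclasses.replace(
            fit_ext,
            estimates=dataclasses.replace(fit_ext.estimates, k4=0.0),
            ssr=fit_std.ssr * 0.1)  # even with a big apparent improvement
        sel = select_model(fit_std, k4_zero)
        assert sel.chosen == "standard"

    def test_unconverged_fit_defers(self, nested_fits):
        fit_std, fit_ext = nested_fits
        sel = select_model(fit_std, dataclasses.replace(fit_ext, converged=False))
        assert sel.chosen is None
        assert "defer" in sel.rationale
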
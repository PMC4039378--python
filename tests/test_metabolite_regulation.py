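"""Substrate exponent lambda and the combined coefficient rho_es."""

import numpy as np
import pytest

from regflux.enzyme_inference import center_log
from regflux.metabolite_regulation import (
    SubstrateUninformativeError,
    fit_lambda,
    fit_rho_es,
)
from regflux.pairing import FitTask
from regflux.regulatory_fit import ResampleConfig, fit_rho


def _task(x, y, cv=0.05, task_id="t"):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    return FitTask(
        task_id=task_id,
        condition_ids=[f"c{i}" for i in range(x.size)],
        x=x, x_sd=x * cv, y=y, y_sd=y * cv,
    )


class TestFitLambda:
    def test_exact_quadratic_relation(self):
        log_s = np.array([-1.0, 0.0, 1.0])
        assert fit_lambda(2 * log_s, np.zeros(3), log_s) == pytest.approx(2.0)

    def test_substrate_irrelevant_gives_zero(self):
        log_j = np.array([-1.0, 0.0, 1.0])
        log_s = np.array([0.5, -1.0, 0.5])
        assert fit_lambda(log_j, log_j, log_s) == 0.0

    def test_constant_substrate_raises(self):
        with pytest.raises(SubstrateUninformativeError):
            fit_lambda(np.array([1.0, 2, 3]), np.zeros(3), np.zeros(3))

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            log_j = rng.normal(0, 1, 7)
            log_e = rng.normal(0, 1, 7)
            log_s = rng.normal(0, 1, 7)
            lam = fit_lambda(log_j, log_e, log_s)
            # 1-D grid refinement of the least-squares objective
            grid = np.linspace(lam - 2, lam + 2, 20001)
            sse = ((log_j - log_e)[None, :] - grid[:, None] * log_s[None, :]) ** 2
            best = grid[sse.sum(axis=1).argmin()]
            assert lam == pytest.approx(best, abs=2e-4)

    def test_sign_equivariance(self):
        rng = np.random.default_rng(3)
        log_j, log_e, log_s = rng.normal(0, 1, (3, 6))
        lam = fit_lambda(log_j, log_e, log_s)
        assert fit_lambda(log_j, log_e, -log_s) == pytest.approx(-lam)
        # the combined predictor is unchanged under (s, lambda) -> (-s, -lambda)
        assert np.allclose(log_e + lam * log_s, log_e + (-lam) * (-log_s))


class TestFitRhoEs:
    def test_constant_substrate_reduces_to_rho_h_exactly(self):
        task = _task([1.0, 2, 4, 8, 16, 32], [1.0, 1.9, 4.1, 8.4, 15.2, 33.0])
        cfg = ResampleConfig(n_iter=300, seed=5)
        sf = fit_rho_es(task, np.full(6, 2.5), np.full(6, 0.1), cfg)
        base = fit_rho(task, cfg)
        assert sf.lambda_ == 0.0
        assert sf.delta == 0.0
        assert sf.fit.rho == base.rho
        assert (sf.fit.ci_low, sf.fit.ci_high, sf.fit.p_value) == (
            base.ci_low, base.ci_high, base.p_value,
        )

    def test_substrate_driven_flux_eno_pattern(self):
        """Constant enzyme, substrate tracking flux: rho_h ~ 0 but rho_es ~ 1."""
        rng = np.random.default_rng(21)
        log_j = rng.normal(0, 1.2, 8)
        log_j -= log_j.mean()
        flux = 2.0**log_j
        enzyme = np.full(8, 1.0) * np.exp(0.02 * rng.normal(size=8))
        substrate = 2.0**log_j  # lambda = 1 relation, S follows J
        task = _task(flux, enzyme, cv=0.03)
        cfg = ResampleConfig(n_iter=1000, seed=9)
        sf = fit_rho_es(task, substrate, substrate * 0.03, cfg)
        assert abs(sf.rho_h) < 0.15
        assert sf.fit.ci_low <= 1.0 <= sf.fit.ci_high
        assert sf.lambda_ == pytest.approx(1.0, abs=0.2)
        assert sf.delta > 0.5

    def test_equal_enzyme_substrate_drivers_recovered(self):
        """Flux built as J = E * S (lambda = 1, combined slope 1)."""
        rng = np.random.default_rng(30)
        log_e = rng.normal(0, 0.8, 8)
        log_s = rng.normal(0, 0.8, 8)
        flux = 2.0 ** (log_e + log_s)
        task = _task(flux, 2.0**log_e, cv=0.03)
        cfg = ResampleConfig(n_iter=1000, seed=13)
        sf = fit_rho_es(task, 2.0**log_s, (2.0**log_s) * 0.03, cfg)
        assert sf.lambda_ == pytest.approx(1.0, abs=0.2)
        assert sf.fit.ci_low <= 1.0 <= sf.fit.ci_high

    def test_missing_substrate_conditions_dropped(self):
        task = _task([1.0, 2, 4, 8, 16], [1.0, 2.1, 3.9, 8.1, 16.5])
        substrate = np.array([1.0, np.nan, 2.0, 4.0, 8.0])
        cfg = ResampleConfig(n_iter=100, seed=1, min_subset=3)
        sf = fit_rho_es(task, substrate, substrate * 0.1, cfg)
        assert sf.fit.n_points == 4

    def test_all_substrate_missing_rejected(self):
        task = _task([1.0, 2, 4], [1.0, 2, 4])
        with pytest.raises(ValueError):
            fit_rho_es(
                task, np.full(3, np.nan), np.full(3, np.nan),
                ResampleConfig(n_iter=10, seed=0),
            )

    def test_fixed_lambda_mode(self):
        rng = np.random.default_rng(2)
        log_e = rng.normal(0, 1, 6)
        log_s = rng.normal(0, 1, 6)
        flux = 2.0 ** (log_e + 0.5 * log_s)
        task = _task(flux, 2.0**log_e, cv=0.0)
        cfg = ResampleConfig(n_iter=20, subset_fraction=1.0, min_subset=6, noise=False)
        sf = fit_rho_es(task, 2.0**log_s, np.zeros(6), cfg, fix_lambda=True)
        assert sf.lambda_ == pytest.approx(0.5, abs=1e-10)
        assert sf.fit.rho == pytest.approx(1.0, abs=1e-10)
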
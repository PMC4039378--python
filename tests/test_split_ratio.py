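"""Branch-series assembly, rho_hr fitting, isozyme combination scan."""

import numpy as np
import pytest

from regflux.branch_kinetics import BranchParams
from regflux.enzyme_inference import infer_enzymes
from regflux.io_model import BranchDef, ReactionEntry
from regflux.regulatory_fit import ResampleConfig
from regflux.split_ratio import (
    BranchSeries,
    build_branch_series,
    fit_rho_hr,
    isozyme_scan,
)
from regflux.synthetic_data import generate_branch_series

from conftest import make_dataset

EXACT_CFG = ResampleConfig(n_iter=20, subset_fraction=1.0, min_subset=8, noise=False)


def _series(flux_a, flux_b, enzyme_a, enzyme_b, cv=0.05):
    n = len(flux_a)
    arr = lambda v: np.asarray(v, dtype=float)
    return BranchSeries(
        branch_id="bp",
        condition_ids=[f"c{i}" for i in range(n)],
        flux_a=arr(flux_a), flux_a_sd=arr(flux_a) * cv,
        flux_b=arr(flux_b), flux_b_sd=arr(flux_b) * cv,
        enzyme_a=arr(enzyme_a), enzyme_a_sd=arr(enzyme_a) * cv,
        enzyme_b=arr(enzyme_b), enzyme_b_sd=arr(enzyme_b) * cv,
    )


class TestBuildBranchSeries:
    def _dataset(self, active_conditions):
        n = 8
        conditions = [(f"c{i}", 0.2 + 0.07 * i, 0.01) for i in range(n)]
        flux_rows = []
        for i in range(n):
            va = 1.0 + 0.2 * i if i in active_conditions else 0.01
            flux_rows.append(("Ra", f"c{i}", va, 0.05))
            flux_rows.append(("Rb", f"c{i}", 0.8, 0.05))
        transcript_rows = [
            (g, f"c{i}", 1.0 + 0.1 * i, 0.05) for g in ("ga", "gb") for i in range(n)
        ]
        return make_dataset(
            conditions=conditions,
            flux_rows=flux_rows,
            transcript_rows=transcript_rows,
            reactions=[ReactionEntry("Ra", ("ga",)), ReactionEntry("Rb", ("gb",))],
            branches=[BranchDef("bp1", "Ra", "Rb")],
        )

    def test_joint_active_conditions_retained(self):
        ds = self._dataset(active_conditions=set(range(6)))
        enz = infer_enzymes(ds.transcripts, ds.conditions)
        (series,) = build_branch_series(ds, enz)
        assert series.n_points == 6

    def test_too_few_joint_conditions_drops_branch(self):
        ds = self._dataset(active_conditions={0, 1, 2, 3})
        enz = infer_enzymes(ds.transcripts, ds.conditions)
        assert build_branch_series(ds, enz, min_points=5) == []

    def test_exclusion_list(self):
        ds = self._dataset(active_conditions=set(range(8)))
        enz = infer_enzymes(ds.transcripts, ds.conditions)
        assert build_branch_series(ds, enz, exclude=["bp1"]) == []


class TestFitRhoHr:
    def test_matching_ratio_series_gives_unit_slope(self):
        rng = np.random.default_rng(0)
        ratio = 2.0 ** rng.normal(0, 1, 6)
        s = _series(ratio * 2.0, np.full(6, 2.0), ratio * 0.3, np.full(6, 0.3))
        fit = fit_rho_hr(s, EXACT_CFG)
        assert fit.rho == pytest.approx(1.0, abs=1e-10)
        assert fit.r2 == pytest.approx(1.0, abs=1e-10)

    def test_constant_enzyme_ratio_gives_zero(self):
        flux_a = np.array([1.0, 2, 4, 8, 16, 32])
        s = _series(flux_a, np.full(6, 4.0), np.full(6, 1.0), np.full(6, 2.0))
        assert fit_rho_hr(s, EXACT_CFG).rho == pytest.approx(0.0, abs=1e-12)

    def test_noise_free_log_ratio_slope_recovered_exactly(self):
        rng = np.random.default_rng(3)
        log_er = rng.normal(0, 1, 7)
        for true_slope in (0.4, 1.0, 1.7):
            # log flux ratio = log enzyme ratio / slope (fit has enzyme on y)
            er = 2.0**log_er
            fr = 2.0 ** (log_er / true_slope)
            s = _series(fr, np.ones(7), er, np.ones(7))
            cfg = ResampleConfig(n_iter=10, subset_fraction=1.0, min_subset=7, noise=False)
            assert fit_rho_hr(s, cfg).rho == pytest.approx(true_slope, abs=1e-10)

    def test_arm_swap_leaves_rho_hr_unchanged(self):
        rng = np.random.default_rng(5)
        s = _series(
            2.0 ** rng.normal(0, 1, 6), 2.0 ** rng.normal(0, 1, 6),
            2.0 ** rng.normal(0, 1, 6), 2.0 ** rng.normal(0, 1, 6),
        )
        f1 = fit_rho_hr(s, EXACT_CFG)
        f2 = fit_rho_hr(s.swapped(), EXACT_CFG)
        assert f1.rho == pytest.approx(f2.rho, abs=1e-10)

    def test_too_short_series_rejected(self):
        s = _series([1.0, 2, 3], [1.0, 1, 1], [1.0, 2, 3], [1.0, 1, 1])
        with pytest.raises(ValueError):
            fit_rho_hr(s, EXACT_CFG)

    def test_kinetic_simulation_unsaturated_regime_covers_one(self):
        # forward-simulated branch deep in the first-order regime
        base = BranchParams(
            kcat1=1e6, km1=5.0, e1=1.0, kcat2=1e6, km2=2.0, e2=1.0, j_in=1.0
        )
        rng = np.random.default_rng(8)
        series, _ = generate_branch_series(
            base, 2.0 ** rng.normal(0, 0.8, 8), 2.0 ** rng.normal(0, 0.8, 8),
            cv=0.03, seed=1,
        )
        fit = fit_rho_hr(series, ResampleConfig(n_iter=500, seed=2))
        assert fit.ci_low <= 1.0 <= fit.ci_high

    def test_saturated_arm_flattens_the_slope(self):
        base = BranchParams(
            kcat1=2.0, km1=1e-4, e1=1.0, kcat2=2.0, km2=5.0, e2=1.0, j_in=1.5
        )
        rng = np.random.default_rng(8)
        series, _ = generate_branch_series(
            base, 2.0 ** rng.normal(0, 0.8, 8), 2.0 ** rng.normal(0, 0.8, 8)
        )
        cfg = ResampleConfig(n_iter=10, subset_fraction=1.0, min_subset=8, noise=False)
        assert fit_rho_hr(series, cfg).rho < 0.7


class TestIsozymeScan:
    def test_identical_isozymes_flat_scan(self):
        rng = np.random.default_rng(1)
        e = 2.0 ** rng.normal(0, 1, 6)
        s = _series(2.0 ** rng.normal(0, 1, 6), np.ones(6), e, np.ones(6))
        table, _ = isozyme_scan(s, e, e * 0.05, e, e * 0.05, EXACT_CFG)
        assert np.allclose(table["rho_hr"], table["rho_hr"].iloc[0])
        assert np.allclose(table["r2"], table["r2"].iloc[0])

    def test_w0_endpoint_equals_plain_fit_with_g1(self):
        rng = np.random.default_rng(2)
        e1 = 2.0 ** rng.normal(0, 1, 6)
        e2 = 2.0 ** rng.normal(0, 1, 6)
        s = _series(2.0 ** rng.normal(0, 1, 6), np.ones(6), e1, np.ones(6))
        table, _ = isozyme_scan(
            s, e1, e1 * 0.05, e2, e2 * 0.05, EXACT_CFG, weights=[0.0]
        )
        plain = fit_rho_hr(s, EXACT_CFG)
        assert table["rho_hr"].iloc[0] == pytest.approx(plain.rho, abs=1e-10)

    def test_recovers_true_mixing_weight(self):
        rng = np.random.default_rng(7)
        e1 = 2.0 ** rng.normal(0, 1.0, 8)
        e2 = 2.0 ** rng.normal(0, 1.0, 8)
        true_mix = 0.7 * e1 + 0.3 * e2
        eb = np.ones(8)
        # unsaturated branch: flux ratio proportional to effective enzyme ratio
        flux_a = true_mix * np.exp(0.01 * rng.normal(size=8))
        s = _series(flux_a, np.ones(8), true_mix, eb)
        table, best = isozyme_scan(s, e1, e1 * 0.01, e2, e2 * 0.01, EXACT_CFG)
        assert abs(best["w"] - 0.3) <= 0.1
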
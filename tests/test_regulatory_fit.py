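"""Weighted Theil-Sen estimator, resampling inference, and classification."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from regflux.pairing import FitTask
from regflux.regulatory_fit import (
    DegenerateDataError,
    RegulatoryFit,
    ResampleConfig,
    classify_fit,
    fit_rho,
    goodness_of_fit,
    pairwise_slopes,
    theil_sen,
    weighted_median,
)

from conftest import oracle_weighted_median, oracle_weighted_theil_sen


class TestPairwiseSlopes:
    def test_single_pair(self):
        assert pairwise_slopes([0, 1], [0, 2]) == [(2.0, 1.0)]

    def test_collinear_weights(self):
        sw = pairwise_slopes([0, 1, 2], [0, 1, 2])
        assert [s for s, _ in sw] == [1.0, 1.0, 1.0]
        assert [w for _, w in sw] == [1.0, 4.0, 1.0]

    def test_vertical_pair_excluded(self):
        sw = pairwise_slopes([0, 0, 1], [0, 5, 1])
        # (x0,x1) coincide; only the two pairs involving x=1 survive
        assert len(sw) == 2

    def test_all_x_equal_raises(self):
        with pytest.raises(DegenerateDataError):
            pairwise_slopes([1, 1, 1], [0, 1, 2])


class TestWeightedMedian:
    def test_equal_weights_is_plain_median(self):
        assert weighted_median(np.array([1.0, 2, 3]), np.ones(3)) == 2.0

    def test_heavy_low_value_wins(self):
        assert weighted_median(np.array([1.0, 10.0]), np.array([3.0, 1.0])) == 1.0

    def test_single_value(self):
        assert weighted_median(np.array([7.0]), np.array([2.0])) == 7.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            weighted_median(np.array([]), np.array([]))

    @given(
        st.lists(
            st.tuples(
                st.floats(-50, 50, allow_nan=False),
                st.floats(0.01, 10, allow_nan=False),
            ),
            min_size=1,
            max_size=12,
        )
    )
    def test_matches_cumulative_scan_oracle(self, pairs):
        values = np.array([v for v, _ in pairs])
        weights = np.array([w for _, w in pairs])
        assert weighted_median(values, weights) == oracle_weighted_median(
            values.tolist(), weights.tolist()
        )


class TestTheilSen:
    def test_collinear_recovers_any_slope(self):
        x = np.array([0.0, 1, 2, 5])
        for s in (-3.2, 0.0, 0.7, 12.0):
            assert theil_sen(x, s * x + 1) == pytest.approx(s, abs=1e-12)

    def test_hand_worked_weighted_median(self):
        # slopes (1,2,3) with weights (1,4,1): cumulative 1,5,6 -> median 2
        assert theil_sen(np.array([0.0, 1, 2]), np.array([0.0, 1, 4])) == 2.0

    def test_matches_exhaustive_oracle_on_random_sets(self):
        rng = np.random.default_rng(42)
        for _ in range(400):
            n = rng.integers(2, 9)
            x = rng.normal(size=n)
            if rng.random() < 0.3:  # force some ties in x
                x[rng.integers(0, n)] = x[0]
            y = rng.normal(size=n)
            if np.unique(x).size < 2:
                continue
            assert theil_sen(x, y) == pytest.approx(
                oracle_weighted_theil_sen(x, y), abs=1e-12
            )

    def test_shift_equivariance_and_x_scaling(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=6), rng.normal(size=6)
        s = theil_sen(x, y)
        assert theil_sen(x + 3.7, y - 1.2) == pytest.approx(s, abs=1e-12)
        assert theil_sen(2.5 * x, y) == pytest.approx(s / 2.5, abs=1e-12)

    def test_robust_to_single_corrupted_point(self):
        x = np.arange(8.0)
        y = 1.5 * x
        y[3] += 40.0  # gross outlier
        ts = theil_sen(x - x.mean(), y - y.mean())
        xc, yc = x - x.mean(), y - y.mean()
        ls = float((xc * yc).sum() / (xc**2).sum())
        assert abs(ts - 1.5) < abs(ls - 1.5)


class TestGoodnessOfFit:
    def test_perfect_fit(self):
        x = np.array([-1.0, 0, 1])
        r2, mar = goodness_of_fit(x, 2 * x, 2.0)
        assert r2 == 1.0 and mar == 0.0

    def test_zero_slope_gives_zero_r2(self):
        y = np.array([-1.0, 0, 1])
        r2, _ = goodness_of_fit(np.array([-2.0, 0, 2]), y, 0.0)
        assert r2 == 0.0

    def test_worse_than_mean_fit_negative(self):
        x = np.array([-1.0, 0, 1])
        r2, _ = goodness_of_fit(x, -x, 2.0)  # badly wrong slope
        assert r2 < 0

    def test_flat_y_r2_missing(self):
        r2, mar = goodness_of_fit(np.array([-1.0, 1]), np.zeros(2), 0.5)
        assert r2 is None and mar == 0.5


def _task(x, y, task_id="t", x_cv=0.05, y_cv=0.05):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    return FitTask(
        task_id=task_id,
        condition_ids=[f"c{i}" for i in range(x.size)],
        x=x, x_sd=x * x_cv, y=y, y_sd=y * y_cv,
    )


class TestFitRho:
    def test_degenerate_resampling_equals_point_estimate(self):
        """noise off + full subset -> every draw is the same fit."""
        x = np.array([1.0, 2, 4, 8, 16])
        y = np.array([1.0, 1.9, 4.2, 7.5, 17.0])
        task = _task(x, y)
        cfg = ResampleConfig(n_iter=50, subset_fraction=1.0, min_subset=5, noise=False)
        fit = fit_rho(task, cfg)
        from regflux.enzyme_inference import center_log

        assert fit.rho == pytest.approx(
            theil_sen(center_log(x), center_log(y)), abs=1e-12
        )
        assert fit.ci_low == fit.ci_high == fit.rho
        assert fit.rho_m == pytest.approx(1 - fit.rho)

    def test_deterministic_given_seed(self):
        task = _task([1.0, 3, 5, 9, 2, 7], [1.2, 2.8, 5.5, 8.1, 2.2, 6.3])
        cfg = ResampleConfig(n_iter=300, seed=7)
        a, b = fit_rho(task, cfg), fit_rho(task, cfg)
        assert (a.rho, a.ci_low, a.ci_high, a.p_value) == (
            b.rho, b.ci_low, b.ci_high, b.p_value,
        )

    def test_p_value_zero_when_all_slopes_below_one(self):
        # flat y: every resampled slope is ~0, far below 1
        task = _task([1.0, 2, 4, 8, 16, 32], [1.0, 1.01, 0.99, 1.0, 1.02, 0.98])
        fit = fit_rho(task, ResampleConfig(n_iter=200, seed=3))
        assert fit.p_value == 0.0

    def test_ci_ordering_invariant(self):
        task = _task([1.0, 2, 4, 8, 16], [1.0, 2.1, 3.9, 8.3, 15.0])
        fit = fit_rho(task, ResampleConfig(n_iter=500, seed=11))
        assert fit.ci_low <= fit.rho <= fit.ci_high

    def test_null_calibration_small(self):
        """With true rho=1, the 95% CI should cover 1 in most replicates."""
        from regflux.enzyme_inference import center_log

        rng = np.random.default_rng(0)
        miss = 0
        n_rep = 40
        for rep in range(n_rep):
            logj = rng.normal(0, 1.5, 8)
            x = 2.0 ** (logj - logj.mean())
            y = x * np.exp(0.05 * rng.normal(size=8))  # true slope 1 + 5% noise
            x_meas = x * np.exp(0.05 * rng.normal(size=8))
            fit = fit_rho(_task(x_meas, y), ResampleConfig(n_iter=500, seed=rep))
            if not (fit.ci_low <= 1.0 <= fit.ci_high):
                miss += 1
        assert miss / n_rep <= 0.10


class TestClassify:
    def _fit(self, rho, ci, resid, outlier=False):
        f = RegulatoryFit(
            task_id="t", rho=rho, ci_low=ci[0], ci_high=ci[1],
            p_value=0.5, r2=0.9, mean_abs_residual=resid, n_points=8,
        )
        f.outlier_driven = outlier
        return f

    @pytest.mark.parametrize(
        "rho,ci,resid,expected",
        [
            (0.98, (0.8, 1.2), 0.1, "full_hierarchical"),  # SucC-like pattern
            (0.3, (0.2, 0.45), 0.2, "partial"),  # Pgm-like pattern
            (0.05, (-0.1, 0.2), 0.6, "metabolic"),  # flat enzyme, Zwf-like
            (0.6, (0.3, 0.9), 0.7, "incoherent"),
        ],
    )
    def test_patterns(self, rho, ci, resid, expected):
        assert classify_fit(self._fit(rho, ci, resid)) == expected

    def test_outlier_driven_flag(self):
        assert classify_fit(self._fit(0.6, (0.3, 0.9), 0.7, outlier=True)) == (
            "outlier_driven"
        )
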
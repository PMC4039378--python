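"""Weighted Theil-Sen regression and resampling inference for rho_h.

The hierarchical regulation coefficient rho_h of a reaction is the slope of
centered log2 enzyme concentration against centered log2 flux magnitude
across conditions: rho_h = 1 means flux changes are fully matched by enzyme
(transcriptional) changes, rho_h = 0 means the enzyme level is flat and the
metabolic state does all the work.  The complementary metabolic coefficient
is rho_m = 1 - rho_h.

The point estimator is the *weighted* Theil-Sen slope: the weighted median
of all pairwise slopes (y_j - y_i)/(x_j - x_i) with weights (x_j - x_i)^2,
which down-weights slope estimates from nearly coincident x values and
resists outliers.  Uncertainty comes from a resampling scheme: N draws each
take a random condition subset and perturb every retained log2 value by
Gaussian noise with SD equal to the measurement's relative SD / ln 2; the
reported rho is the median of the resulting slope distribution, the 95% CI
its empirical 2.5/97.5 percentiles, and the P-value for the hypothesis
rho > 1 the fraction of draws with slope >= 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .enzyme_inference import LN2, center_log
from .pairing import FitTask

__all__ = [
    "RegulatoryFit",
    "ResampleConfig",
    "pairwise_slopes",
    "weighted_median",
    "theil_sen",
    "goodness_of_fit",
    "fit_rho",
    "classify_fit",
    "DegenerateDataError",
]

log = logging.getLogger(__name__)

CLASSES = ("full_hierarchical", "partial", "metabolic", "incoherent", "outlier_driven")


class DegenerateDataError(ValueError):
    """No informative pairs: all x values coincide."""


@dataclass
class ResampleConfig:
    """Configuration of the subset-plus-noise resampling scheme.

    ``n_iter`` defaults to 2000 draws.  Subset size is
    max(min_subset, round(subset_fraction * n)) conditions drawn without
    replacement; ``noise`` toggles the measurement-error perturbation.
    """

    n_iter: int = 2000
    subset_fraction: float = 0.8
    min_subset: int = 4
    seed: int = 0
    noise: bool = True

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        if not 0 < self.subset_fraction <= 1:
            raise ValueError("subset_fraction must be in (0, 1]")

    def subset_size(self, n: int) -> int:
        k = max(self.min_subset, int(round(self.subset_fraction * n)))
        k = min(k, n)
        if k < 3:
            raise ValueError(f"resampling subset of {k} < 3 points")
        return k


@dataclass
class RegulatoryFit:
    """One reaction-enzyme fit: slope, interval, P-value and diagnostics."""

    task_id: str
    rho: float
    ci_low: float
    ci_high: float
    p_value: float
    r2: Optional[float]
    mean_abs_residual: float
    n_points: int
    rho_m: float = field(init=False)
    fit_class: Optional[str] = None
    outlier_driven: bool = False

    def __post_init__(self) -> None:
        self.rho_m = 1.0 - self.rho
        if not (self.ci_low <= self.rho <= self.ci_high):
            raise ValueError(
                f"{self.task_id}: rho {self.rho} outside CI "
                f"[{self.ci_low}, {self.ci_high}]"
            )


def pairwise_slopes(x: np.ndarray, y: np.ndarray) -> list[tuple[float, float]]:
    """All pairwise (slope, weight) tuples with weight (x_j - x_i)^2.

    Pairs with identical x are excluded (their slope is undefined and their
    weight would be zero anyway).  Raises if no informative pair remains.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be aligned 1-D vectors")
    if x.size < 2:
        raise ValueError("need at least 2 points")
    iu, ju = np.triu_indices(x.size, k=1)
    dx = x[ju] - x[iu]
    dy = y[ju] - y[iu]
    keep = dx != 0
    if not keep.any():
        raise DegenerateDataError("no informative pairs: all x values equal")
    return list(zip((dy[keep] / dx[keep]).tolist(), (dx[keep] ** 2).tolist()))


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Lower weighted median: smallest v with cumulative weight >= total/2."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0:
        raise ValueError("weighted_median: empty input")
    if values.shape != weights.shape:
        raise ValueError("values and weights must be aligned")
    if (weights < 0).any() or not weights.sum() > 0:
        raise ValueError("weights must be >= 0 with positive total")
    order = np.argsort(values, kind="stable")
    v = values[order]
    cw = np.cumsum(weights[order])
    idx = int(np.searchsorted(cw, cw[-1] / 2.0))
    return float(v[idx])


def theil_sen(x: np.ndarray, y: np.ndarray) -> float:
    """Weighted Theil-Sen slope: weighted median of pairwise slopes."""
    sw = pairwise_slopes(x, y)
    slopes = np.array([s for s, _ in sw])
    weights = np.array([w for _, w in sw])
    return weighted_median(slopes, weights)


def goodness_of_fit(
    x: np.ndarray, y: np.ndarray, slope: float
) -> tuple[Optional[float], float]:
    """Through-origin R^2 and mean absolute residual of y ~ slope*x.

    ``x`` and ``y`` are centered (mean zero), so the fitted line passes
    through the origin and R^2 = 1 - SS_res/SS_y may be negative for fits
    worse than the mean.  Returns (None, mar) when y has no variation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    r = y - slope * x
    mar = float(np.abs(r).mean())
    ss_y = float((y**2).sum())
    if ss_y == 0:
        return None, mar
    return 1.0 - float((r**2).sum()) / ss_y, mar


# ---------------------------------------------------------------------------
# vectorized resampling engine (shared with the rho_es fit)


def _batch_weighted_ts(xs: np.ndarray, ys: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weighted Theil-Sen slope for each row of (m, k) point batches.

    Returns (slopes, ok) where ok marks rows with at least one informative
    pair; slopes of bad rows are NaN.
    """
    m, k = xs.shape
    iu, ju = np.triu_indices(k, k=1)
    dx = xs[:, ju] - xs[:, iu]
    dy = ys[:, ju] - ys[:, iu]
    valid = dx != 0
    w = np.where(valid, dx * dx, 0.0)
    slopes_p = np.where(valid, dy / np.where(valid, dx, 1.0), np.inf)
    total = w.sum(axis=1)
    ok = total > 0
    order = np.argsort(slopes_p, axis=1, kind="stable")
    sv = np.take_along_axis(slopes_p, order, axis=1)
    cw = np.cumsum(np.take_along_axis(w, order, axis=1), axis=1)
    half = total / 2.0
    idx = (cw >= half[:, None]).argmax(axis=1)
    out = sv[np.arange(m), idx]
    out[~ok] = np.nan
    return out, ok


def _draw_subsets(rng: np.random.Generator, m: int, n: int, k: int) -> np.ndarray:
    if k == n:
        return np.broadcast_to(np.arange(n), (m, n)).copy()
    return np.argsort(rng.random((m, n)), axis=1)[:, :k]


def resample_slopes(
    x_log: np.ndarray,
    y_log: np.ndarray,
    x_sd_log: np.ndarray,
    y_sd_log: np.ndarray,
    cfg: ResampleConfig,
    s_log: np.ndarray | None = None,
    s_sd_log: np.ndarray | None = None,
    fixed_lambda: float | None = None,
    lambda_clamp: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Distribution of weighted Theil-Sen slopes under subset+noise draws.

    When ``s_log`` (centered log2 substrate) is given, each draw refits the
    substrate exponent lambda by through-origin least squares within the
    drawn subset and regresses the combined predictor y + lambda*s on x
    (unless ``fixed_lambda`` pins it).  Returns (slopes, lambdas); lambdas
    is None in the plain enzyme-only mode.

    Degenerate draws (no informative pair after subsetting) are redrawn,
    with a hard cap of 10 * n_iter total attempts.
    """
    rng = np.random.default_rng(cfg.seed)
    n = x_log.size
    k = cfg.subset_size(n)
    slopes = np.full(cfg.n_iter, np.nan)
    lambdas = np.full(cfg.n_iter, np.nan) if s_log is not None else None
    need = np.arange(cfg.n_iter)
    attempts = 0
    while need.size:
        attempts += need.size
        if attempts > 10 * cfg.n_iter:
            raise DegenerateDataError(
                "resampling: too many degenerate subset draws (all x equal)"
            )
        m = need.size
        idx = _draw_subsets(rng, m, n, k)
        xs = x_log[idx]
        ys = y_log[idx]
        if cfg.noise:
            xs = xs + rng.standard_normal((m, k)) * x_sd_log[idx]
            ys = ys + rng.standard_normal((m, k)) * y_sd_log[idx]
        lam = None
        if s_log is not None:
            ss = s_log[idx]
            if cfg.noise and s_sd_log is not None:
                ss = ss + rng.standard_normal((m, k)) * s_sd_log[idx]
            # recenter within the draw so the through-origin fits are valid
            xs = xs - xs.mean(axis=1, keepdims=True)
            ys = ys - ys.mean(axis=1, keepdims=True)
            ss = ss - ss.mean(axis=1, keepdims=True)
            if fixed_lambda is not None:
                lam = np.full(m, float(fixed_lambda))
            else:
                denom = (ss**2).sum(axis=1)
                num = (ss * (xs - ys)).sum(axis=1)
                lam = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
            if lambda_clamp is not None:
                lam = np.clip(lam, *lambda_clamp)
            ys = ys + lam[:, None] * ss
        batch, ok = _batch_weighted_ts(xs, ys)
        filled = need[ok]
        slopes[filled] = batch[ok]
        if lambdas is not None and lam is not None:
            lambdas[filled] = lam[ok]
        need = need[~ok]
    return slopes, lambdas


def _leave_one_out_shift(x: np.ndarray, y: np.ndarray) -> float:
    """Largest |slope change| when any single point is removed."""
    if x.size < 4:
        return 0.0
    base = theil_sen(x, y)
    shift = 0.0
    for i in range(x.size):
        mask = np.arange(x.size) != i
        try:
            s = theil_sen(x[mask], y[mask])
        except DegenerateDataError:
            continue
        shift = max(shift, abs(s - base))
    return shift


def fit_rho(
    task: FitTask,
    cfg: ResampleConfig,
    p_thresh: float = 0.05,
    resid_thresh: float = 0.4,
    outlier_shift_thresh: float = 0.3,
) -> RegulatoryFit:
    """Estimate rho_h for one flux-enzyme task with CI and P-value.

    Flux magnitudes go on x and enzyme levels on y, both centered-log2, so
    the slope reads directly as the share of the log flux change carried by
    the enzyme concentration.  R^2 and the mean |residual| are evaluated on
    the unperturbed full data at the reported rho.  Deterministic given
    ``cfg.seed``.
    """
    if task.n_points < 3:
        raise ValueError(f"task {task.task_id}: need >= 3 points")
    x_log = center_log(task.x)
    y_log = center_log(task.y)
    x_sd_log = task.rel_x_sd() / LN2
    y_sd_log = task.rel_y_sd() / LN2
    slopes, _ = resample_slopes(x_log, y_log, x_sd_log, y_sd_log, cfg)
    rho = float(np.median(slopes))
    ci_low, ci_high = np.percentile(slopes, [2.5, 97.5])
    p_value = float(np.mean(slopes >= 1.0))
    r2, mar = goodness_of_fit(x_log, y_log, rho)
    fit = RegulatoryFit(
        task_id=task.task_id,
        rho=rho,
        ci_low=float(min(ci_low, rho)),
        ci_high=float(max(ci_high, rho)),
        p_value=p_value,
        r2=r2,
        mean_abs_residual=mar,
        n_points=task.n_points,
    )
    fit.outlier_driven = _leave_one_out_shift(x_log, y_log) > outlier_shift_thresh
    fit.fit_class = classify_fit(fit, p_thresh=p_thresh, resid_thresh=resid_thresh)
    return fit


def classify_fit(
    fit: RegulatoryFit,
    p_thresh: float = 0.05,
    resid_thresh: float = 0.4,
    flat_rho: float = 0.2,
) -> str:
    """Assign the qualitative regulation pattern of a fit.

    * ``full_hierarchical`` — good fit (mean |residual| < 0.4 log2 units)
      and rho = 1 not excluded by the 95% CI: enzyme changes alone can
      account for the flux changes.
    * ``partial`` — good fit but the CI sits strictly below 1 with rho > 0:
      enzymes contribute, yet cannot explain the flux changes alone.
    * ``metabolic`` — slope near zero (|rho| < 0.2): the enzyme level is
      essentially flat while the flux moves; regulation is metabolic.
    * ``outlier_driven`` — otherwise-incoherent fit whose slope moves by
      more than 0.3 when a single condition is dropped (one condition
      reaches a distinct metabolic state).
    * ``incoherent`` — none of the above.
    """
    good = fit.mean_abs_residual < resid_thresh
    if good and fit.ci_low <= 1.0 <= fit.ci_high:
        return "full_hierarchical"
    if good and fit.ci_high < 1.0 and fit.rho > 0:
        return "partial"
    if abs(fit.rho) < flat_rho:
        return "metabolic"
    if fit.outlier_driven:
        return "outlier_driven"
    return "incoherent"
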
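"""Combined enzyme + substrate contribution to flux changes (rho_es).

The flux-enzyme analysis treats everything beyond enzyme concentration as
an opaque metabolic term.  Here the substrate's share is made explicit via
the power-law (S-system) form

    Delta J = Delta E * Delta S ** lambda

whose exponent lambda captures saturation (lambda < 1) or cooperativity
(lambda > 1).  On centered log2 data lambda is the through-origin least-
squares slope of log J - log E against log S.  The combined predictor
log E + lambda*log S is then regressed on log J exactly as in the rho_h
fit; the resulting slope rho_es measures how much of the flux change enzyme
and substrate changes explain together, and delta = rho_es - rho_h is the
additional contribution of the substrate information.

lambda is refit inside every resampling draw by default so its estimation
uncertainty propagates into the rho_es interval; ``fix_lambda=True`` pins
it at the full-data value instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .enzyme_inference import LN2, center_log
from .pairing import FitTask
from .regulatory_fit import (
    RegulatoryFit,
    ResampleConfig,
    classify_fit,
    fit_rho,
    goodness_of_fit,
    resample_slopes,
)

__all__ = ["SubstrateFit", "SubstrateUninformativeError", "fit_lambda", "fit_rho_es"]

log = logging.getLogger(__name__)


class SubstrateUninformativeError(ValueError):
    """The substrate series has no variation: lambda is unidentifiable."""


@dataclass
class SubstrateFit:
    """lambda plus the combined-predictor fit and its gain over rho_h alone."""

    lambda_: float
    fit: RegulatoryFit  # fit.rho is rho_es
    rho_h: float
    delta: float  # rho_es - rho_h on identical conditions


def fit_lambda(
    log_j: np.ndarray, log_e: np.ndarray, log_s: np.ndarray
) -> float:
    """Substrate exponent by through-origin least squares on centered logs.

    lambda = sum(logS * (logJ - logE)) / sum(logS^2).
    """
    log_j = np.asarray(log_j, dtype=float)
    log_e = np.asarray(log_e, dtype=float)
    log_s = np.asarray(log_s, dtype=float)
    if not (log_j.size == log_e.size == log_s.size) or log_j.size < 3:
        raise ValueError("need >= 3 aligned points")
    denom = float((log_s**2).sum())
    if denom == 0:
        raise SubstrateUninformativeError("log substrate has no variation")
    return float((log_s * (log_j - log_e)).sum() / denom)


def fit_rho_es(
    task: FitTask,
    substrate: np.ndarray,
    substrate_sd: np.ndarray,
    cfg: ResampleConfig,
    fix_lambda: bool = False,
    lambda_clamp: tuple[float, float] | None = None,
) -> SubstrateFit:
    """rho_es for one task given the reaction's substrate concentrations.

    ``substrate``/``substrate_sd`` are aligned with the task's conditions;
    conditions with missing (NaN) or non-positive substrate are dropped
    from both fits so delta compares like with like.  If the substrate is
    exactly constant the combined predictor degenerates to the enzyme alone
    and the plain rho_h fit is returned with lambda = 0 and delta = 0
    (identical RNG stream, hence bit-identical to fit_rho).
    """
    substrate = np.asarray(substrate, dtype=float)
    substrate_sd = np.asarray(substrate_sd, dtype=float)
    if substrate.size != task.n_points:
        raise ValueError("substrate series must align with task conditions")
    ok = np.isfinite(substrate) & (substrate > 0)
    if not ok.all():
        dropped = [c for c, m in zip(task.condition_ids, ok) if not m]
        log.info("task %s: dropping conditions without substrate: %s", task.task_id, dropped)
        task = task.restrict([c for c, m in zip(task.condition_ids, ok) if m])
        substrate = substrate[ok]
        substrate_sd = substrate_sd[ok]
    if task.n_points < 3:
        raise ValueError(f"task {task.task_id}: fewer than 3 conditions with substrate")

    base = fit_rho(task, cfg)
    log_j = center_log(task.x)
    log_e = center_log(task.y)
    log_s = center_log(substrate)
    try:
        lam = fit_lambda(log_j, log_e, log_s)
    except SubstrateUninformativeError:
        return SubstrateFit(lambda_=0.0, fit=base, rho_h=base.rho, delta=0.0)
    if lambda_clamp is not None:
        lam = float(np.clip(lam, *lambda_clamp))

    slopes, _ = resample_slopes(
        log_j,
        log_e,
        task.rel_x_sd() / LN2,
        task.rel_y_sd() / LN2,
        cfg,
        s_log=log_s,
        s_sd_log=(substrate_sd / substrate) / LN2,
        fixed_lambda=lam if fix_lambda else None,
        lambda_clamp=lambda_clamp,
    )
    rho_es = float(np.median(slopes))
    ci_low, ci_high = np.percentile(slopes, [2.5, 97.5])
    y_combined = log_e + lam * log_s
    y_combined = y_combined - y_combined.mean()
    r2, mar = goodness_of_fit(log_j, y_combined, rho_es)
    fit = RegulatoryFit(
        task_id=task.task_id,
        rho=rho_es,
        ci_low=float(min(ci_low, rho_es)),
        ci_high=float(max(ci_high, rho_es)),
        p_value=float(np.mean(slopes >= 1.0)),
        r2=r2,
        mean_abs_residual=mar,
        n_points=task.n_points,
    )
    fit.fit_class = classify_fit(fit)
    return SubstrateFit(
        lambda_=lam, fit=fit, rho_h=base.rho, delta=fit.rho - base.rho
    )
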
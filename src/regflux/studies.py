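"""Self-contained validation studies of the estimation machinery.

Each study regenerates its inputs from scratch (random instances or the
synthetic-data generator), runs the package's estimators, and returns
summary numbers.  They are the package's own correctness evidence:

* estimator agreement against an independent brute-force weighted
  Theil-Sen reference,
* parameter recovery and confidence-interval coverage over replicate
  synthetic datasets,
* the branch-point one-for-one law in the unsaturated regime and its
  breakdown under extreme affinity/Vmax compensation,
* the closure of rho_es onto rho_h when the substrate carries no
  information, and the substrate-driven (enzyme-flat) pattern.

All randomness derives from the single ``seed`` argument.
"""

from __future__ import annotations

import numpy as np

from .branch_kinetics import BranchParams, ratio_sensitivity_scan, ratio_slope, unsaturated_grid
from .enzyme_inference import infer_enzymes
from .metabolite_regulation import fit_rho_es
from .pairing import FitTask, build_fit_tasks
from .regulatory_fit import ResampleConfig, fit_rho, theil_sen
from .synthetic_data import ReactionSpec, SyntheticSpec, generate_dataset

__all__ = [
    "theil_sen_agreement_study",
    "rho_recovery_study",
    "branch_law_study",
    "rho_es_closure_study",
]


def _reference_weighted_ts(x: np.ndarray, y: np.ndarray) -> float | None:
    """Plain-loop weighted Theil-Sen, independent of the vectorized path.

    Enumerates every pair, accumulates (slope, weight), and scans the
    sorted slopes for the lower weighted median.  Kept deliberately naive
    so it can serve as a reference for the production estimator.
    """
    pairs = []
    n = len(x)
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[j] - x[i]
            if dx == 0:
                continue
            pairs.append(((y[j] - y[i]) / dx, dx * dx))
    if not pairs:
        return None
    pairs.sort()
    total = sum(w for _, w in pairs)
    acc = 0.0
    for s, w in pairs:
        acc += w
        if acc >= total / 2.0:
            return s
    return pairs[-1][0]


def theil_sen_agreement_study(n_instances: int = 10_000, seed: int = 0) -> dict:
    """Fraction of random instances (n <= 8) where the production estimator
    equals the brute-force reference exactly (to 1e-12)."""
    rng = np.random.default_rng([seed, 101])
    agree = 0
    checked = 0
    for _ in range(n_instances):
        n = int(rng.integers(2, 9))
        x = rng.normal(size=n)
        if rng.random() < 0.25 and n >= 3:  # exercise tied-x handling
            x[int(rng.integers(1, n))] = x[0]
        y = rng.normal(size=n)
        ref = _reference_weighted_ts(x, y)
        if ref is None:
            continue
        checked += 1
        if abs(theil_sen(x, y) - ref) <= 1e-12:
            agree += 1
    return {"agreement_rate": agree / checked, "n": checked}


def rho_recovery_study(
    true_rhos: tuple[float, ...] = (0.0, 0.3, 0.7, 1.0),
    n_datasets: int = 200,
    cv: float = 0.05,
    n_iter: int = 2000,
    seed: int = 0,
) -> dict:
    """Recovery of rho_h over replicate synthetic datasets.

    Per true rho: ``n_datasets`` independent 8-condition datasets at the
    given measurement CV, each fit with the full resampling scheme.
    Reports the mean recovered rho, its bias, and the fraction of
    replicates whose 95% CI covers the truth.
    """
    out = {}
    for ti, true_rho in enumerate(true_rhos):
        rhos = np.empty(n_datasets)
        covered = 0
        for rep in range(n_datasets):
            data_seed = int((seed + 1_000_003 * (ti * n_datasets + rep + 1)) % 2**31)
            spec = SyntheticSpec(
                reactions=[ReactionSpec("R", true_rho=true_rho)],
                flux_cv=cv, transcript_cv=cv, seed=data_seed,
            )
            ds, _ = generate_dataset(spec)
            enz = infer_enzymes(ds.transcripts, ds.conditions)
            (task,) = build_fit_tasks(ds, enz)
            fit = fit_rho(task, ResampleConfig(n_iter=n_iter, seed=data_seed))
            rhos[rep] = fit.rho
            covered += fit.ci_low <= true_rho <= fit.ci_high
        out[true_rho] = {
            "mean_rho": float(rhos.mean()),
            "bias": float(rhos.mean() - true_rho),
            "coverage": covered / n_datasets,
            "n": n_datasets,
        }
    return out


def branch_law_study(fold: float = 2.0) -> dict:
    """The split-ratio law at low load, and its breakdown regime.

    Low load: J_in/Vmax_tot = 1e-8 over a grid of K_m and Vmax asymmetries
    (first-order kinetics; the log flux ratio must track the log enzyme
    ratio one-for-one).  Breakdown: one arm with 1e4-fold lower affinity
    compensated by 1e4-fold higher Vmax at J_in twice the weak arm's Vmax.
    """
    table = ratio_sensitivity_scan(unsaturated_grid(load=1e-8), fold=fold)
    extreme = BranchParams(
        kcat1=1e4, km1=1e4, e1=1.0, kcat2=1.0, km2=1.0, e2=1.0, j_in=2.0
    )
    return {
        "unsaturated_max_abs_dev": float(np.abs(table["slope"] - 1.0).max()),
        "n_grid": int(len(table)),
        "breakdown_slope": float(ratio_slope(extreme, fold=fold)),
        "breakdown_abs_dev": float(abs(ratio_slope(extreme, fold=fold) - 1.0)),
    }


def rho_es_closure_study(seed: int = 0, n_iter: int = 2000) -> dict:
    """rho_es behaviour in the two analytically known limits.

    (1) Constant substrate: the combined fit must collapse onto the plain
    rho_h fit exactly (identical resampling stream).  (2) Substrate-driven
    flux with a flat enzyme (the pattern of a fully metabolically regulated
    reaction): rho_h near 0 while the combined coefficient is compatible
    with 1.
    """
    rng = np.random.default_rng([seed, 202])

    def _task(x, y, cv=0.03):
        return FitTask(
            task_id="t",
            condition_ids=[f"c{i}" for i in range(x.size)],
            x=x, x_sd=x * cv, y=y, y_sd=y * cv,
        )

    # constant substrate
    log_j = rng.normal(0, 1.2, 8)
    flux = 2.0 ** (log_j - log_j.mean())
    enzyme = flux ** 0.6 * np.exp(0.02 * rng.normal(size=8))
    task = _task(flux, enzyme)
    cfg = ResampleConfig(n_iter=n_iter, seed=seed + 7)
    sf_const = fit_rho_es(task, np.full(8, 3.0), np.full(8, 0.3), cfg)
    base = fit_rho(task, cfg)
    const_delta = abs(sf_const.fit.rho - base.rho) + abs(sf_const.delta)

    # substrate-driven, enzyme-flat
    log_j2 = rng.normal(0, 1.2, 8)
    log_j2 -= log_j2.mean()
    flux2 = 2.0**log_j2
    enzyme2 = np.exp(0.02 * rng.normal(size=8))
    substrate2 = 2.0**log_j2
    sf_driven = fit_rho_es(
        _task(flux2, enzyme2), substrate2, substrate2 * 0.03,
        ResampleConfig(n_iter=n_iter, seed=seed + 8),
    )
    return {
        "constant_substrate_abs_delta": float(const_delta),
        "driven_rho_h": float(sf_driven.rho_h),
        "driven_rho_es": float(sf_driven.fit.rho),
        "driven_lambda": float(sf_driven.lambda_),
        "driven_ci_covers_one": bool(
            sf_driven.fit.ci_low <= 1.0 <= sf_driven.fit.ci_high
        ),
    }
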
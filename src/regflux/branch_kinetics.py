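"""Mechanistic two-enzyme branch-point model (irreversible Michaelis-Menten).

One substrate pool S is fed at a fixed rate J_in and drained by two
irreversible Michaelis-Menten enzymes:

    v_i(S) = kcat_i * E_i * S / (K_i + S),   v_1(S) + v_2(S) = J_in.

Because the drain is strictly increasing in S, the steady state is unique
whenever J_in < Vmax_1 + Vmax_2.  The question the scan answers: when the
enzyme ratio E1/E2 is perturbed (total inflow held fixed, S re-solved), how
much does the flux split ratio J1/J2 move?  In the first-order (unsaturated)
regime the two log-ratios move one-for-one — the slope is exactly 1 — while
strong asymmetric saturation (one arm with orders-of-magnitude higher K_m
compensated by higher Vmax) breaks the law.

Note that at fixed J_in the fractional saturation at steady state is set by
the load J_in/Vmax_tot, not by K_m alone: raising both K_m values merely
raises S in proportion.  "Unsaturated" therefore means low load.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "BranchParams",
    "InfeasibleFluxError",
    "steady_state_substrate",
    "split_fluxes",
    "ratio_slope",
    "ratio_sensitivity_scan",
    "default_grid",
    "unsaturated_grid",
]

log = logging.getLogger(__name__)


class InfeasibleFluxError(ValueError):
    """J_in meets or exceeds the combined Vmax: no steady state exists."""


@dataclass(frozen=True)
class BranchParams:
    """Kinetic parameters of the two arms plus the input flux.

    kcat in 1/time, K_m in concentration units, E in concentration units
    (only kcat*E products matter), J_in in flux units.
    """

    kcat1: float
    km1: float
    e1: float
    kcat2: float
    km2: float
    e2: float
    j_in: float

    def __post_init__(self) -> None:
        vals = (self.kcat1, self.km1, self.e1, self.kcat2, self.km2, self.e2, self.j_in)
        if not all(v > 0 for v in vals):
            raise ValueError("all branch parameters must be > 0")
        if not self.j_in < self.vmax1 + self.vmax2:
            raise InfeasibleFluxError(
                f"J_in={self.j_in} >= total Vmax={self.vmax1 + self.vmax2}"
            )

    @property
    def vmax1(self) -> float:
        return self.kcat1 * self.e1

    @property
    def vmax2(self) -> float:
        return self.kcat2 * self.e2


def steady_state_substrate(p: BranchParams) -> float:
    """Unique substrate concentration balancing the two drains against J_in.

    Solved with a bracketed root finder; the upper bracket
    S_max = max(K1, K2) * Vtot / (Vtot - J_in) is guaranteed to enclose the
    root because v(S) >= Vtot * S / (max K + S).
    """
    vtot = p.vmax1 + p.vmax2

    def balance(s: float) -> float:
        return (
            p.vmax1 * s / (p.km1 + s) + p.vmax2 * s / (p.km2 + s) - p.j_in
        )

    s_hi = max(p.km1, p.km2) * vtot / (vtot - p.j_in)
    # balance(0) = -j_in < 0 and balance(s_hi) >= 0 by the bracket bound
    return float(brentq(balance, 0.0, s_hi, xtol=1e-300, rtol=8.9e-16, maxiter=200))


def split_fluxes(p: BranchParams) -> tuple[float, float]:
    """Steady-state fluxes through the two arms (sum to J_in)."""
    s = steady_state_substrate(p)
    j1 = p.vmax1 * s / (p.km1 + s)
    j2 = p.vmax2 * s / (p.km2 + s)
    return j1, j2


def ratio_slope(p: BranchParams, fold: float = 2.0) -> float:
    """Two-point log-log sensitivity of the split ratio to the enzyme ratio.

    Multiplies E1/E2 by ``fold`` (symmetrically: E1 *= sqrt(fold),
    E2 /= sqrt(fold)), re-solves the steady state at fixed J_in, and returns
    delta log(J1/J2) / delta log(E1/E2).
    """
    if fold <= 0 or fold == 1.0:
        raise ValueError("perturbation fold must be > 0 and != 1")
    j1, j2 = split_fluxes(p)
    r = np.sqrt(fold)
    p2 = replace(p, e1=p.e1 * r, e2=p.e2 / r)
    j1b, j2b = split_fluxes(p2)
    return float((np.log(j1b / j2b) - np.log(j1 / j2)) / np.log(fold))


def default_grid(j_in: float = 1.0, s0: float = 1.0) -> list[BranchParams]:
    """Default scan grid: Vmax multipliers x log-spaced K_m values.

    Per-arm Vmax in {0.5, 1, 2, 5, 10} * J_in (feasible combinations only)
    and K_m / s0 log-spaced over 10^-2..10^4 (9 points, both arms).
    """
    vmults = [0.5, 1.0, 2.0, 5.0, 10.0]
    kms = np.logspace(-2, 4, 9) * s0
    grid = []
    for v1, v2, k1, k2 in itertools.product(vmults, vmults, kms, kms):
        if v1 + v2 <= 1.0:  # infeasible: total Vmax must exceed J_in
            continue
        grid.append(
            BranchParams(
                kcat1=v1 * j_in, km1=float(k1), e1=1.0,
                kcat2=v2 * j_in, km2=float(k2), e2=1.0,
                j_in=j_in,
            )
        )
    return grid


def unsaturated_grid(load: float = 1e-8, j_in: float = 1.0) -> list[BranchParams]:
    """Grid pinned to the first-order regime: J_in / Vmax_tot = ``load``.

    Varies the K_m ratio and the Vmax split while keeping the load tiny, so
    every point sits deep in the linear range of both arms.
    """
    grid = []
    vtot = j_in / load
    for vfrac in (0.2, 0.5, 0.8):
        for k1, k2 in itertools.product((0.1, 1.0, 100.0), repeat=2):
            grid.append(
                BranchParams(
                    kcat1=vfrac * vtot, km1=k1, e1=1.0,
                    kcat2=(1 - vfrac) * vtot, km2=k2, e2=1.0,
                    j_in=j_in,
                )
            )
    return grid


def ratio_sensitivity_scan(
    grid: list[BranchParams] | None = None,
    fold: float = 2.0,
    saturation_flag: float = 0.5,
) -> pd.DataFrame:
    """Scan the enzyme-ratio sensitivity of the flux split over a grid.

    Returns one row per feasible grid point with the kinetic parameters,
    the baseline steady state, the slope dlog(J1/J2)/dlog(E1/E2), and a
    ``breakdown`` flag for points where an arm is more than half saturated
    (the regime where the one-for-one law can fail).  Infeasible points are
    skipped with a log entry.
    """
    if grid is None:
        grid = default_grid()
    rows = []
    for p in grid:
        try:
            s = steady_state_substrate(p)
            slope = ratio_slope(p, fold=fold)
        except InfeasibleFluxError as exc:
            log.info("grid point skipped: %s", exc)
            continue
        sat1 = s / (p.km1 + s)
        sat2 = s / (p.km2 + s)
        rows.append(
            {
                "vmax1": p.vmax1,
                "vmax2": p.vmax2,
                "km1": p.km1,
                "km2": p.km2,
                "j_in": p.j_in,
                "s_steady": s,
                "saturation1": sat1,
                "saturation2": sat2,
                "slope": slope,
                "breakdown": max(sat1, sat2) > saturation_flag,
            }
        )
    return pd.DataFrame(rows)
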
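"""Branch-point regulation: flux split ratios vs enzyme concentration ratios.

At a metabolic branch point the fraction of flux entering each arm depends
only on the local kinetics (for irreversible arms without product
inhibition), so the slope rho_hr of centered log2(J_a/J_b) against centered
log2(E_a/E_b) is a direct test of transcriptional control of the split:
under first-order kinetics a change in the enzyme ratio moves the flux
ratio one-for-one (rho_hr = 1).

Fitting reuses the weighted Theil-Sen resampling machinery; ratio SDs are
combined in quadrature on the log scale.  For arms catalysed by two
isozymes with unknown relative activities, ``isozyme_scan`` refits over a
grid of linear combinations (1-w)*E_g1 + w*E_g2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_model import Dataset
from .pairing import FitTask
from .regulatory_fit import RegulatoryFit, ResampleConfig, fit_rho

__all__ = ["BranchSeries", "build_branch_series", "fit_rho_hr", "isozyme_scan"]

log = logging.getLogger(__name__)

DEFAULT_MIN_POINTS = 5


@dataclass
class BranchSeries:
    """Per-condition fluxes and enzyme levels of a branch point's two arms."""

    branch_id: str
    condition_ids: list[str]
    flux_a: np.ndarray
    flux_a_sd: np.ndarray
    flux_b: np.ndarray
    flux_b_sd: np.ndarray
    enzyme_a: np.ndarray
    enzyme_a_sd: np.ndarray
    enzyme_b: np.ndarray
    enzyme_b_sd: np.ndarray

    def __post_init__(self) -> None:
        for name in (
            "flux_a", "flux_a_sd", "flux_b", "flux_b_sd",
            "enzyme_a", "enzyme_a_sd", "enzyme_b", "enzyme_b_sd",
        ):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.condition_ids)
        if any(
            getattr(self, name).size != n
            for name in ("flux_a", "flux_b", "enzyme_a", "enzyme_b")
        ):
            raise ValueError(f"branch {self.branch_id}: misaligned series")

    @property
    def n_points(self) -> int:
        return len(self.condition_ids)

    def swapped(self) -> "BranchSeries":
        return BranchSeries(
            branch_id=self.branch_id,
            condition_ids=self.condition_ids,
            flux_a=self.flux_b, flux_a_sd=self.flux_b_sd,
            flux_b=self.flux_a, flux_b_sd=self.flux_a_sd,
            enzyme_a=self.enzyme_b, enzyme_a_sd=self.enzyme_b_sd,
            enzyme_b=self.enzyme_a, enzyme_b_sd=self.enzyme_a_sd,
        )


def _sum_arm_enzymes(
    enzymes: pd.DataFrame, gene_ids: tuple[str, ...], condition: str
) -> tuple[float, float] | None:
    """Summed enzyme level (SDs in quadrature) of an arm's isozymes."""
    total, var = 0.0, 0.0
    for g in gene_ids:
        row = enzymes[(enzymes["gene"] == g) & (enzymes["condition"] == condition)]
        if len(row) == 0:
            return None
        total += float(row["enzyme_rel"].iloc[0])
        var += float(row["enzyme_sd"].iloc[0]) ** 2
    if not total > 0:
        return None
    return total, float(np.sqrt(var))


def build_branch_series(
    dataset: Dataset,
    enzymes: pd.DataFrame,
    cutoff: float = 0.1,
    min_points: int = DEFAULT_MIN_POINTS,
    exclude: list[str] | None = None,
) -> list[BranchSeries]:
    """Assemble per-branch series from a dataset's branch definitions.

    Retains conditions where both arm fluxes exceed the cutoff in magnitude
    and both arms have positive enzyme levels; drops branches with fewer
    than ``min_points`` joint conditions or listed in ``exclude`` (used in
    practice for splits with unreliable flux estimates).
    """
    exclude = set(exclude or [])
    flux = dataset.fluxes.set_index(["reaction", "condition"])
    out = []
    for br in dataset.reaction_map.branches:
        if br.branch_id in exclude:
            continue
        genes_a = dataset.reaction_map.reactions[br.reaction_a].gene_ids
        genes_b = dataset.reaction_map.reactions[br.reaction_b].gene_ids
        rows = []
        for cond in dataset.condition_ids:
            try:
                fa = flux.loc[(br.reaction_a, cond)]
                fb = flux.loc[(br.reaction_b, cond)]
            except KeyError:
                continue
            if abs(fa["flux"]) <= cutoff or abs(fb["flux"]) <= cutoff:
                continue
            ea = _sum_arm_enzymes(enzymes, genes_a, cond)
            eb = _sum_arm_enzymes(enzymes, genes_b, cond)
            if ea is None or eb is None:
                continue
            rows.append(
                (cond, abs(fa["flux"]), fa["flux_sd"], abs(fb["flux"]), fb["flux_sd"],
                 ea[0], ea[1], eb[0], eb[1])
            )
        if len(rows) < min_points:
            if rows:
                log.info(
                    "branch %s: only %d joint conditions (< %d), dropped",
                    br.branch_id, len(rows), min_points,
                )
            continue
        cols = list(map(np.array, zip(*rows)))
        out.append(
            BranchSeries(
                branch_id=br.branch_id,
                condition_ids=list(cols[0]),
                flux_a=cols[1].astype(float), flux_a_sd=cols[2].astype(float),
                flux_b=cols[3].astype(float), flux_b_sd=cols[4].astype(float),
                enzyme_a=cols[5].astype(float), enzyme_a_sd=cols[6].astype(float),
                enzyme_b=cols[7].astype(float), enzyme_b_sd=cols[8].astype(float),
            )
        )
    return out


def _ratio_task(
    series: BranchSeries,
    enzyme_a: np.ndarray | None = None,
    enzyme_a_sd: np.ndarray | None = None,
    task_id: str | None = None,
) -> FitTask:
    ea = series.enzyme_a if enzyme_a is None else enzyme_a
    ea_sd = series.enzyme_a_sd if enzyme_a_sd is None else enzyme_a_sd
    x = series.flux_a / series.flux_b
    y = ea / series.enzyme_b
    # relative SDs of the two factors combine in quadrature on the log scale
    x_rel = np.sqrt(
        (series.flux_a_sd / series.flux_a) ** 2
        + (series.flux_b_sd / series.flux_b) ** 2
    )
    y_rel = np.sqrt(
        (ea_sd / ea) ** 2 + (series.enzyme_b_sd / series.enzyme_b) ** 2
    )
    return FitTask(
        task_id=task_id or series.branch_id,
        condition_ids=list(series.condition_ids),
        x=x,
        x_sd=x * x_rel,
        y=y,
        y_sd=y * y_rel,
    )


def fit_rho_hr(
    series: BranchSeries, cfg: ResampleConfig, min_points: int = DEFAULT_MIN_POINTS
) -> RegulatoryFit:
    """rho_hr for one branch: slope of log enzyme ratio vs log flux ratio."""
    if series.n_points < min_points:
        raise ValueError(
            f"branch {series.branch_id}: {series.n_points} < {min_points} points"
        )
    return fit_rho(_ratio_task(series), cfg)


def isozyme_scan(
    series: BranchSeries,
    e_g1: np.ndarray,
    e_g1_sd: np.ndarray,
    e_g2: np.ndarray,
    e_g2_sd: np.ndarray,
    cfg: ResampleConfig,
    weights: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Refit rho_hr over linear combinations of two arm-a isozymes.

    For each mixing weight w the arm-a enzyme level is
    (1-w)*E_g1 + w*E_g2 (SDs combined in quadrature).  Returns the full
    (w, rho_hr, r2) table and the row with the best R^2.
    """
    if weights is None:
        weights = np.arange(0.0, 1.0001, 0.05)
    weights = np.asarray(weights, dtype=float)
    if weights.size == 0:
        raise ValueError("isozyme scan: empty weight grid")
    rows = []
    for w in weights:
        ea = (1 - w) * np.asarray(e_g1, float) + w * np.asarray(e_g2, float)
        ea_sd = np.sqrt(
            ((1 - w) * np.asarray(e_g1_sd, float)) ** 2
            + (w * np.asarray(e_g2_sd, float)) ** 2
        )
        fit = fit_rho(
            _ratio_task(series, ea, ea_sd, task_id=f"{series.branch_id}[w={w:.2f}]"),
            cfg,
        )
        rows.append({"w": float(w), "rho_hr": fit.rho, "r2": fit.r2})
    table = pd.DataFrame(rows)
    best = table.loc[table["r2"].idxmax()]
    return table, best
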
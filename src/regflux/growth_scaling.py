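"""Growth-rate scaling of biosynthetic enzyme expression.

Fluxes through biomass-component biosynthesis pathways (amino acids,
nucleotides, cell wall) are proportional to the growth rate, so if any such
enzyme were expression-limited its level would have to track mu.  This
module fits centered log2 expression against centered log2 growth rate at
two levels: the raw mRNA signal (fraction of total mRNA) and the inferred
protein concentration (signal scaled by total mRNA and diluted by growth).
With a constant total-mRNA model the protein-level slope equals the mRNA
slope minus exactly 1 — the dilution term — which is why good mRNA-level
proportionality does not imply protein-level proportionality.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Optional

import numpy as np
import pandas as pd

from .enzyme_inference import TotalMrnaModel, center_log, total_mrna
from .regulatory_fit import goodness_of_fit, theil_sen

__all__ = ["GrowthScalingResult", "fit_growth_scaling", "summarize_growth_scaling"]

log = logging.getLogger(__name__)

Level = Literal["mrna", "protein"]


@dataclass
class GrowthScalingResult:
    gene_id: str
    level: Level
    rho: float
    r2: Optional[float]
    r: float  # signed Pearson correlation
    n_points: int


def fit_growth_scaling(
    gene_id: str,
    signals: np.ndarray,
    growth_rates: np.ndarray,
    level: Level = "mrna",
    model: TotalMrnaModel | None = None,
    least_squares: bool = False,
) -> GrowthScalingResult | None:
    """Slope of centered log2 expression against centered log2 growth rate.

    ``level="protein"`` first converts the signal with the dilution model
    E = m * T(mu) / mu.  Non-positive values are dropped; fewer than three
    remaining points skips the gene (returns None with a warning).  The
    slope uses the weighted Theil-Sen estimator for consistency with the
    flux-enzyme fits; ``least_squares=True`` switches to the through-origin
    OLS slope.
    """
    signals = np.asarray(signals, dtype=float)
    growth_rates = np.asarray(growth_rates, dtype=float)
    keep = signals > 0
    if keep.sum() < 3:
        log.warning("gene %s: <3 positive values, growth-scaling fit skipped", gene_id)
        return None
    v = signals[keep]
    mu = growth_rates[keep]
    if level == "protein":
        model = model or TotalMrnaModel()
        v = v * np.array([total_mrna(m, model) for m in mu]) / mu
    x = center_log(mu)
    y = center_log(v)
    if least_squares:
        rho = float((x * y).sum() / (x**2).sum())
    else:
        rho = theil_sen(x, y)
    r2, _ = goodness_of_fit(x, y, rho)
    denom = np.sqrt((x**2).sum() * (y**2).sum())
    r = float((x * y).sum() / denom) if denom > 0 else 0.0
    return GrowthScalingResult(
        gene_id=gene_id, level=level, rho=rho, r2=r2, r=r, n_points=int(keep.sum())
    )


def summarize_growth_scaling(
    results: Iterable[GrowthScalingResult],
    r2_thresh: float = 0.65,
    rho_window: tuple[float, float] = (0.8, 1.2),
    r_thresh: float = 0.8,
) -> pd.DataFrame:
    """Count genes meeting the published growth-proportionality criteria.

    mRNA level: R^2 > ``r2_thresh``, and of those, slope within
    ``rho_window``.  Protein level: signed correlation r > ``r_thresh`` and
    slope within the window (the criterion asymmetry between the levels is
    deliberate and matches how the counts are reported).  Returns a tidy
    per-level table with counts and the underlying gene lists.
    """
    results = list(results)
    if not results:
        raise ValueError("no growth-scaling results to summarize")
    rows = []
    for level in ("mrna", "protein"):
        sub = [res for res in results if res.level == level]
        if not sub:
            continue
        lo, hi = rho_window
        if level == "mrna":
            passing = [res for res in sub if res.r2 is not None and res.r2 > r2_thresh]
        else:
            passing = [res for res in sub if res.r > r_thresh]
        in_window = [res for res in passing if lo <= res.rho <= hi]
        rows.append(
            {
                "level": level,
                "n_genes": len(sub),
                "n_correlated": len(passing),
                "n_proportional": len(in_window),
                "correlated_genes": ";".join(sorted(r.gene_id for r in passing)),
                "proportional_genes": ";".join(sorted(r.gene_id for r in in_window)),
            }
        )
    return pd.DataFrame(rows)
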
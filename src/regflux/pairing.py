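"""Selection of analyzable flux-enzyme pairs.

A reaction enters the analysis only where its flux is meaningfully non-zero:
|flux| must exceed a cutoff (default 0.1 mmol gcdw^-1 h^-1) in at least
``min_conditions`` conditions (default 3), and within a kept reaction only
the above-cutoff conditions are retained.  Each kept reaction is paired with
every enzyme that can catalyse it (one task per isozyme).  Reversible
reactions whose flux changes sign across conditions are split into one task
per direction, each re-checked against the minimum; the fits then use the
flux magnitude, with the direction kept as metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_model import Dataset

__all__ = ["FitTask", "select_fluxes", "build_fit_tasks"]

log = logging.getLogger(__name__)

DEFAULT_CUTOFF = 0.1  # mmol gcdw^-1 h^-1
DEFAULT_MIN_CONDITIONS = 3


@dataclass
class FitTask:
    """Aligned positive x (flux magnitude) and y (predictor) series with SDs."""

    task_id: str
    condition_ids: list[str]
    x: np.ndarray
    x_sd: np.ndarray
    y: np.ndarray
    y_sd: np.ndarray
    reaction_id: str | None = None
    gene_id: str | None = None
    direction_label: str | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.x_sd = np.asarray(self.x_sd, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.y_sd = np.asarray(self.y_sd, dtype=float)
        n = len(self.condition_ids)
        if not (self.x.size == self.x_sd.size == self.y.size == self.y_sd.size == n):
            raise ValueError(f"task {self.task_id}: misaligned series")
        if not ((self.x > 0).all() and (self.y > 0).all()):
            raise ValueError(f"task {self.task_id}: x and y must be positive")

    @property
    def n_points(self) -> int:
        return len(self.condition_ids)

    def rel_x_sd(self) -> np.ndarray:
        return self.x_sd / self.x

    def rel_y_sd(self) -> np.ndarray:
        return self.y_sd / self.y

    def restrict(self, condition_ids: list[str]) -> "FitTask":
        """Sub-task over a condition subset (order preserved)."""
        keep = [i for i, c in enumerate(self.condition_ids) if c in set(condition_ids)]
        return FitTask(
            task_id=self.task_id,
            condition_ids=[self.condition_ids[i] for i in keep],
            x=self.x[keep],
            x_sd=self.x_sd[keep],
            y=self.y[keep],
            y_sd=self.y_sd[keep],
            reaction_id=self.reaction_id,
            gene_id=self.gene_id,
            direction_label=self.direction_label,
        )


def select_fluxes(
    fluxes: pd.DataFrame,
    cutoff: float = DEFAULT_CUTOFF,
    min_conditions: int = DEFAULT_MIN_CONDITIONS,
) -> pd.DataFrame:
    """Filter the flux table to analyzable reactions and conditions.

    Keeps reactions with |flux| > cutoff in at least ``min_conditions``
    conditions, and within those reactions drops the below-cutoff rows.
    """
    if cutoff < 0:
        raise ValueError("cutoff must be >= 0")
    above = fluxes["flux"].abs() > cutoff
    counts = fluxes.loc[above].groupby("reaction", sort=False).size()
    keep_rxns = set(counts[counts >= min_conditions].index)
    mask = above & fluxes["reaction"].isin(keep_rxns)
    return fluxes.loc[mask].reset_index(drop=True)


def build_fit_tasks(
    dataset: Dataset,
    enzymes: pd.DataFrame,
    cutoff: float = DEFAULT_CUTOFF,
    min_conditions: int = DEFAULT_MIN_CONDITIONS,
) -> list[FitTask]:
    """Enumerate flux-enzyme fit tasks for a dataset.

    One task per (kept reaction or direction, catalysing gene).  A condition
    lacking a positive enzyme measurement for the gene is dropped from that
    task only; genes entirely absent from the enzyme table are skipped with
    a warning.  Condition order follows the dataset's condition list.
    """
    kept = select_fluxes(dataset.fluxes, cutoff, min_conditions)
    order = {c: i for i, c in enumerate(dataset.condition_ids)}
    enz = enzymes.set_index(["gene", "condition"])
    tasks: list[FitTask] = []
    for reaction_id in kept["reaction"].drop_duplicates():
        sub = kept[kept["reaction"] == reaction_id]
        entry = dataset.reaction_map.reactions[reaction_id]
        signs = np.sign(sub["flux"].to_numpy())
        groups: list[tuple[str | None, pd.DataFrame]]
        if entry.reversible and len(set(signs[signs != 0])) > 1:
            groups = [
                ("+", sub[sub["flux"] > 0]),
                ("-", sub[sub["flux"] < 0]),
            ]
        else:
            groups = [(None, sub)]
        for label, g in groups:
            if len(g) < min_conditions:
                continue
            g = g.copy()
            g["__order"] = g["condition"].map(order)
            g = g.sort_values("__order")
            for gene in entry.gene_ids:
                if gene not in enz.index.get_level_values(0):
                    log.warning(
                        "reaction %s: gene %s absent from enzyme table, task skipped",
                        reaction_id,
                        gene,
                    )
                    continue
                rows = []
                for r in g.itertuples(index=False):
                    key = (gene, r.condition)
                    if key not in enz.index:
                        continue
                    e = enz.loc[key]
                    if not e["enzyme_rel"] > 0:
                        continue
                    rows.append(
                        (r.condition, abs(r.flux), r.flux_sd, e["enzyme_rel"], e["enzyme_sd"])
                    )
                if len(rows) < min_conditions:
                    continue
                conds, x, x_sd, y, y_sd = map(list, zip(*rows))
                suffix = label or ""
                tasks.append(
                    FitTask(
                        task_id=f"{reaction_id}{suffix}:{gene}",
                        condition_ids=conds,
                        x=np.array(x),
                        x_sd=np.array(x_sd),
                        y=np.array(y),
                        y_sd=np.array(y_sd),
                        reaction_id=reaction_id,
                        gene_id=gene,
                        direction_label=label,
                    )
                )
    return tasks
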
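"""Expression of enzymes whose flux switches between on and off states.

Uptake systems and a few central enzymes carry flux only under a subset of
conditions.  For each such gene this module partitions the conditions into
"on" (some linked reaction carries |flux| above the cutoff) and "off" (no
linked reaction does), normalizes the enzyme level to its mean across all
conditions, and reports the fold change between the geometric means of the
two groups.  Geometric means give the fold change its multiplicative
semantics; the per-gene normalization cancels in the ratio, so the fold
change is invariant to the arbitrary enzyme scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import Dataset

__all__ = ["OnOffSummary", "onoff_summary", "gene_reaction_links"]

log = logging.getLogger(__name__)


@dataclass
class OnOffSummary:
    gene_id: str
    on_conditions: list[str]
    off_conditions: list[str]
    mean_on: float  # geometric mean of mean-normalized enzyme, on conditions
    mean_off: float
    fold_change: float


def gene_reaction_links(dataset: Dataset) -> dict[str, list[str]]:
    """gene -> reactions it catalyses, from the reaction map."""
    links: dict[str, list[str]] = {}
    for entry in dataset.reaction_map.reactions.values():
        for g in entry.gene_ids:
            links.setdefault(g, []).append(entry.reaction_id)
    return links


def _gmean(v: np.ndarray) -> float:
    return float(np.exp(np.log(v).mean()))


def onoff_summary(
    dataset: Dataset,
    enzymes: pd.DataFrame,
    links: Mapping[str, Sequence[str]] | None = None,
    cutoff: float = 0.1,
    genes: Sequence[str] | None = None,
) -> list[OnOffSummary]:
    """Fold change of enzyme level between flux-carrying and zero-flux conditions.

    ``links`` defaults to the dataset's reaction map; ``genes`` restricts
    the analysis (default: every linked gene).  Genes whose on or off set is
    empty, or with a non-positive enzyme level in any condition, are
    excluded with a warning.
    """
    links = links or gene_reaction_links(dataset)
    flux = dataset.fluxes.set_index(["reaction", "condition"])
    enz = enzymes.set_index(["gene", "condition"])
    all_conditions = dataset.condition_ids
    out: list[OnOffSummary] = []
    for gene in genes if genes is not None else sorted(links):
        rxns = links.get(gene, [])
        levels, conds = [], []
        for c in all_conditions:
            if (gene, c) in enz.index:
                levels.append(float(enz.loc[(gene, c), "enzyme_rel"]))
                conds.append(c)
        if len(conds) < 2 or not all(v > 0 for v in levels):
            log.warning("gene %s: insufficient positive enzyme data, excluded", gene)
            continue
        on, off = [], []
        for c in conds:
            active = any(
                (r, c) in flux.index and abs(float(flux.loc[(r, c), "flux"])) > cutoff
                for r in rxns
            )
            (on if active else off).append(c)
        if not on or not off:
            log.warning("gene %s: empty on or off set, excluded", gene)
            continue
        v = np.array(levels) / np.mean(levels)  # relative to mean across conditions
        by_cond = dict(zip(conds, v))
        mean_on = _gmean(np.array([by_cond[c] for c in on]))
        mean_off = _gmean(np.array([by_cond[c] for c in off]))
        out.append(
            OnOffSummary(
                gene_id=gene,
                on_conditions=on,
                off_conditions=off,
                mean_on=mean_on,
                mean_off=mean_off,
                fold_change=mean_on / mean_off,
            )
        )
    return out
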
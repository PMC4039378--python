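"""Replicate-level transcript processing.

Expression arrays from independent replicate cultures are put on a common
scale by quantile normalization, the most discordant of three replicates is
discarded (largest summed Euclidean distance to the other two), and the
remainder is summarized to a per-gene mean and sample SD.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ReplicateSet",
    "quantile_normalize",
    "drop_outlier_replicate",
    "summarize_replicates",
    "process_replicates",
]

log = logging.getLogger(__name__)


@dataclass
class ReplicateSet:
    """Signal vectors over a common gene list for one condition's replicates."""

    condition_id: str
    gene_ids: list[str]
    signals: np.ndarray  # shape (n_replicates, n_genes)

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2 or self.signals.shape[1] != len(self.gene_ids):
            raise ValueError(
                "signals must be (n_replicates, n_genes) matching gene_ids"
            )
        if (self.signals < 0).any():
            raise ValueError("replicate signals must be >= 0")


def quantile_normalize(arrays: np.ndarray | list) -> np.ndarray:
    """Quantile-normalize signal vectors to a shared reference distribution.

    The reference is the per-rank mean of the sorted inputs; every output
    vector then carries the same multiset of values while preserving its own
    rank order.  Tied values receive the mean of the tied ranks' reference
    values, which makes the transform deterministic and idempotent.
    """
    X = np.asarray(arrays, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D array of shape (n_arrays, n_values)")
    if X.shape[0] < 2:
        raise ValueError("quantile normalization needs at least 2 arrays")
    reference = np.sort(X, axis=1).mean(axis=0)
    out = np.empty_like(X)
    for i, row in enumerate(X):
        order = np.argsort(row, kind="stable")
        assigned = reference.copy()
        vals = row[order]
        # average reference values over runs of tied input values
        boundaries = np.flatnonzero(np.diff(vals) != 0) + 1
        for lo, hi in zip(
            np.concatenate(([0], boundaries)),
            np.concatenate((boundaries, [len(vals)])),
        ):
            if hi - lo > 1:
                assigned[lo:hi] = assigned[lo:hi].mean()
        out[i, order] = assigned
    return out


def drop_outlier_replicate(reps: ReplicateSet) -> ReplicateSet:
    """Remove the replicate farthest (summed Euclidean distance) from the rest.

    Applies only to sets of exactly three replicates; anything else is passed
    through unchanged with a log notice.  Ties are broken toward the lowest
    replicate index.
    """
    n = reps.signals.shape[0]
    if n != 3:
        log.info(
            "condition %s: %d replicates, outlier removal skipped",
            reps.condition_id,
            n,
        )
        return reps
    X = reps.signals
    dist = np.linalg.norm(X[:, None, :] - X[None, :, :], axis=2)
    total = dist.sum(axis=1)
    drop = int(np.argmax(total))  # argmax takes the first maximum: lowest index
    keep = [i for i in range(3) if i != drop]
    return replace(reps, signals=X[keep])


def summarize_replicates(reps: ReplicateSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene sample mean and sample SD (n-1 denominator) over replicates."""
    if reps.signals.shape[0] < 2:
        raise ValueError("need at least 2 replicates to summarize")
    mean = reps.signals.mean(axis=0)
    sd = reps.signals.std(axis=0, ddof=1)
    return mean, sd


def process_replicates(
    reps: ReplicateSet, qq_normalize: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Full replicate workflow: normalize -> drop outlier -> summarize.

    Normalization is optional (``qq_normalize=False``); the downstream
    analysis is reported to be robust to it.
    """
    if qq_normalize:
        reps = replace(reps, signals=quantile_normalize(reps.signals))
    reps = drop_outlier_replicate(reps)
    return summarize_replicates(reps)
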
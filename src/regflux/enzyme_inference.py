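"""Relative enzyme concentrations from transcript signal and growth rate.

At balanced growth with a constant per-transcript translation rate and
protein loss dominated by dilution through cell division, the steady-state
protein level of gene *i* in condition *j* is

    E_ij = alpha * m_ij * T(mu_j) / mu_j

where ``m_ij`` is the transcript signal expressed as a fraction of total
mRNA, ``T(mu)`` is the total mRNA amount per unit biomass (modelled as an
affine function of the growth rate), ``mu_j`` the growth rate, and ``alpha``
an arbitrary global constant.  Only *relative* levels across conditions are
meaningful; the centered-log transform used downstream removes ``alpha``
(and any per-gene unit) entirely.

mRNA degradation is neglected: the balance uses growth dilution only, and
translation rates are assumed unaffected by the environmental shifts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .io_model import ConditionProfile

__all__ = [
    "TotalMrnaModel",
    "total_mrna",
    "infer_enzymes",
    "center_log",
]

LN2 = np.log(2.0)


class ModelError(ValueError):
    """The total-mRNA model produces a non-positive amount."""


@dataclass(frozen=True)
class TotalMrnaModel:
    """Affine total-mRNA-per-biomass model T(mu) = a + b*mu.

    Defaults (a=0.4, b=0.8 h) are normalized so that T(0.75 h^-1)=1; only
    the a/b ratio affects centered-log results, the overall scale folds
    into the arbitrary constant alpha.  Override with coefficients fitted
    to organism-specific RNA content data when available.
    """

    a: float = 0.4
    b: float = 0.8

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0 or (self.a == 0 and self.b == 0):
            raise ModelError("TotalMrnaModel needs a, b >= 0 and not both zero")

    def __call__(self, mu: float | np.ndarray) -> float | np.ndarray:
        return self.a + self.b * np.asarray(mu, dtype=float)


def total_mrna(mu: float, model: TotalMrnaModel) -> float:
    """Total mRNA per unit biomass at growth rate ``mu`` (h^-1)."""
    if not mu > 0:
        raise ValueError(f"growth rate must be > 0, got {mu}")
    t = float(model(mu))
    if not t > 0:
        raise ModelError(f"total mRNA model non-positive at mu={mu}: {t}")
    return t


def infer_enzymes(
    transcripts: pd.DataFrame,
    conditions: Iterable[ConditionProfile],
    model: TotalMrnaModel | None = None,
    alpha: float = 1.0,
    include_growth_sd: bool = False,
) -> pd.DataFrame:
    """Convert a transcript table into relative enzyme concentrations.

    Parameters
    ----------
    transcripts
        Long-format table with columns ``gene, condition, signal, signal_sd``.
    conditions
        Growth-rate profiles; every condition present in ``transcripts``
        must appear here.
    model, alpha
        Total-mRNA model and global scale constant.
    include_growth_sd
        Fold the relative growth-rate SD into the enzyme SD in quadrature
        (off by default; the transcript SD usually dominates).

    Returns
    -------
    DataFrame with columns ``gene, condition, enzyme_rel, enzyme_sd``.
    Relative errors are preserved: enzyme_sd/enzyme_rel = signal_sd/signal
    (plus the optional growth term); a zero signal yields a zero enzyme
    level with the SD propagated from ``signal_sd``.
    """
    model = model or TotalMrnaModel()
    mu_map = {c.condition_id: c.growth_rate for c in conditions}
    mu_sd_map = {c.condition_id: c.growth_rate_sd for c in conditions}
    missing = sorted(set(transcripts["condition"]) - set(mu_map))
    if missing:
        raise ValueError(f"no growth rate for condition(s): {missing}")

    mu = transcripts["condition"].map(mu_map).to_numpy(dtype=float)
    t_over_mu = np.array([total_mrna(m, model) / m for m in mu])
    signal = transcripts["signal"].to_numpy(dtype=float)
    signal_sd = transcripts["signal_sd"].to_numpy(dtype=float)

    enzyme = alpha * signal * t_over_mu
    enzyme_sd = alpha * signal_sd * t_over_mu
    if include_growth_sd:
        mu_sd = transcripts["condition"].map(mu_sd_map).to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.where(signal > 0, signal_sd / signal, 0.0)
        rel_total = np.sqrt(rel**2 + (mu_sd / mu) ** 2)
        enzyme_sd = np.where(enzyme > 0, enzyme * rel_total, enzyme_sd)

    return pd.DataFrame(
        {
            "gene": transcripts["gene"].to_numpy(),
            "condition": transcripts["condition"].to_numpy(),
            "enzyme_rel": enzyme,
            "enzyme_sd": enzyme_sd,
        }
    )


def center_log(values: np.ndarray | list) -> np.ndarray:
    """log2-transform and subtract the mean.

    Forces a subsequent through-origin fit and cancels any multiplicative
    constant (the alpha of the enzyme model, the beta of the flux-enzyme
    relation, per-gene units).  All inputs must be strictly positive;
    callers filter zeros beforehand.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("center_log: empty input")
    if not (v > 0).all():
        raise ValueError("center_log: all values must be > 0")
    lv = np.log2(v)
    return lv - lv.mean()
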
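"""Synthetic multi-omic datasets with known regulatory ground truth.

The generator emulates the statistical structure the regulatory analysis
assumes: for each reaction a centered log2 flux profile is drawn across
conditions with a configurable spread (up to ~20-fold condition-to-
condition variation by default), the enzyme profile is set to
log2 E = rho * log2 J (so the hierarchical share of the flux change is
exactly the requested true rho, the metabolic term being the remaining
(1 - rho) * log2 J), and for substrate-coupled reactions the substrate
profile satisfies log2 S = (log2 J - log2 E) / lambda.  Transcript signals
are obtained by inverting the enzyme dilution model, m = E * mu / (alpha *
T(mu)), so the full pipeline — enzyme inference included — recovers the
truth exactly in the noise-free limit.  Multiplicative lognormal
measurement noise is then applied per table at the configured relative SDs.

Branch-point series use the mechanistic Michaelis-Menten branch model as
the forward simulator; the generator shares no slope-estimation code with
the fitting machinery, so recovery tests are genuine round trips.

All randomness flows from one integer seed through per-table, per-reaction
substreams (``default_rng([seed, stream, index])``), so adding a reaction
or table does not shift existing streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .branch_kinetics import BranchParams, split_fluxes
from .enzyme_inference import TotalMrnaModel, total_mrna
from .io_model import (
    BranchDef,
    ConditionProfile,
    Dataset,
    ReactionEntry,
    ReactionMap,
)
from .split_ratio import BranchSeries

__all__ = [
    "ReactionSpec",
    "OnOffSpec",
    "BranchSpec",
    "SyntheticSpec",
    "SyntheticTruth",
    "generate_dataset",
    "generate_branch_series",
    "default_spec",
]

# fixed substream ids — never renumber, only append
_STREAM_FLUX = 0
_STREAM_RESIDUAL = 1
_STREAM_FLUX_NOISE = 2
_STREAM_TRANSCRIPT_NOISE = 3
_STREAM_METABOLITE_NOISE = 4
_STREAM_BRANCH = 5
_STREAM_ONOFF = 6


@dataclass(frozen=True)
class ReactionSpec:
    """Ground truth for one generated reaction.

    ``flux_log2_sd`` controls the condition-to-condition spread of the log2
    flux profile (1.5 gives up to ~20-fold ranges over 8 conditions);
    ``residual_log2_sd`` adds condition-specific scatter to the enzyme
    profile beyond the hierarchical share (default 0 so the noise-free
    dataset inverts exactly).
    """

    reaction_id: str
    true_rho: float
    gene_ids: tuple[str, ...] = ()
    flux_scale: float = 1.0  # mmol gcdw^-1 h^-1 at the profile center
    flux_log2_sd: float = 1.5
    true_lambda: Optional[float] = None
    substrate_id: Optional[str] = None
    residual_log2_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.substrate_id is not None and self.true_lambda == 0:
            raise ValueError(
                f"{self.reaction_id}: substrate coupling needs true_lambda != 0"
            )

    def genes(self) -> tuple[str, ...]:
        return self.gene_ids or (f"g_{self.reaction_id}",)


@dataclass(frozen=True)
class OnOffSpec:
    """An uptake-like gene induced only in the conditions where it is needed."""

    gene_id: str
    reaction_id: str
    on_condition_idx: tuple[int, ...]
    induction_fold: float = 30.0
    flux_on: float = 2.0
    baseline_enzyme: float = 1.0


@dataclass(frozen=True)
class BranchSpec:
    """A two-arm branch simulated with the mechanistic kinetic model."""

    branch_id: str
    params: BranchParams
    reaction_a: str = ""
    reaction_b: str = ""
    enzyme_log2_sd: float = 0.75  # per-arm condition-to-condition enzyme spread

    def rxn_a(self) -> str:
        return self.reaction_a or f"{self.branch_id}_a"

    def rxn_b(self) -> str:
        return self.reaction_b or f"{self.branch_id}_b"


@dataclass
class SyntheticSpec:
    """Study conditions of a generated dataset.

    Defaults mirror the experimental design the analysis targets: 8 carbon-
    source conditions spanning growth rates 0.22-0.75 h^-1, and relative
    measurement SDs of 10% (flux), 15% (transcript) and 10% (metabolite).
    """

    reactions: list[ReactionSpec]
    n_conditions: int = 8
    growth_rate_range: tuple[float, float] = (0.22, 0.75)
    growth_rate_cv: float = 0.0
    flux_cv: float = 0.10
    transcript_cv: float = 0.15
    metabolite_cv: float = 0.10
    onoff: list[OnOffSpec] = field(default_factory=list)
    branches: list[BranchSpec] = field(default_factory=list)
    mrna_model: TotalMrnaModel = field(default_factory=TotalMrnaModel)
    alpha: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for cv in (self.flux_cv, self.transcript_cv, self.metabolite_cv):
            if cv < 0:
                raise ValueError("measurement CVs must be >= 0")
        if self.n_conditions < 2:
            raise ValueError("need at least 2 conditions")


@dataclass
class SyntheticTruth:
    """Ground truth keyed the same way the pipeline keys its outputs."""

    rho_by_task: dict[str, float] = field(default_factory=dict)
    lambda_by_reaction: dict[str, float] = field(default_factory=dict)
    onoff_fold_by_gene: dict[str, float] = field(default_factory=dict)
    branch_params: dict[str, BranchParams] = field(default_factory=dict)


def _rng(seed: int, stream: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng([seed, stream, index])


def _noisy(
    values: np.ndarray, cv: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Multiplicative lognormal noise at relative SD ``cv``; returns (value, sd)."""
    v = np.asarray(values, dtype=float)
    if cv == 0:
        return v.copy(), np.zeros_like(v)
    noisy = v * np.exp(cv * rng.standard_normal(v.shape))
    return noisy, np.abs(noisy) * cv


def generate_dataset(spec: SyntheticSpec) -> tuple[Dataset, SyntheticTruth]:
    """Generate a validated Dataset plus its ground truth."""
    n = spec.n_conditions
    conditions = [f"c{i + 1}" for i in range(n)]
    mu = np.linspace(*spec.growth_rate_range, n)
    profiles = [
        ConditionProfile(c, float(m), float(m * spec.growth_rate_cv))
        for c, m in zip(conditions, mu)
    ]
    t_over_mu = np.array([total_mrna(m, spec.mrna_model) / m for m in mu])

    truth = SyntheticTruth()
    flux_rows, transcript_rows, metab_rows = [], [], []
    reactions: dict[str, ReactionEntry] = {}
    branches: list[BranchDef] = []

    for i, rx in enumerate(spec.reactions):
        z = _rng(spec.seed, _STREAM_FLUX, i).standard_normal(n) * rx.flux_log2_sd
        log_j = z - z.mean()
        log_e = rx.true_rho * log_j
        if rx.residual_log2_sd > 0:
            res = _rng(spec.seed, _STREAM_RESIDUAL, i).standard_normal(n)
            res = (res - res.mean()) * rx.residual_log2_sd
            log_e = log_e + res
        j_true = rx.flux_scale * 2.0**log_j
        e_true = 2.0**log_e
        # invert the dilution model: m = E*mu/(alpha*T(mu)) = E/(alpha*T/mu)
        m_true = e_true / (spec.alpha * t_over_mu)

        j_meas, j_sd = _noisy(j_true, spec.flux_cv, _rng(spec.seed, _STREAM_FLUX_NOISE, i))
        for gi, gene in enumerate(rx.genes()):
            m_meas, m_sd = _noisy(
                m_true, spec.transcript_cv,
                _rng(spec.seed, _STREAM_TRANSCRIPT_NOISE, i * 16 + gi),
            )
            transcript_rows += [
                (gene, c, m_meas[k], m_sd[k]) for k, c in enumerate(conditions)
            ]
            truth.rho_by_task[f"{rx.reaction_id}:{gene}"] = rx.true_rho
        flux_rows += [
            (rx.reaction_id, c, j_meas[k], j_sd[k]) for k, c in enumerate(conditions)
        ]
        substrates: tuple[str, ...] = ()
        if rx.substrate_id is not None:
            log_s = (log_j - log_e) / rx.true_lambda
            s_true = 2.0**log_s
            s_meas, s_sd = _noisy(
                s_true, spec.metabolite_cv, _rng(spec.seed, _STREAM_METABOLITE_NOISE, i)
            )
            metab_rows += [
                (rx.substrate_id, c, s_meas[k], s_sd[k])
                for k, c in enumerate(conditions)
            ]
            substrates = (rx.substrate_id,)
            truth.lambda_by_reaction[rx.reaction_id] = float(rx.true_lambda)
        reactions[rx.reaction_id] = ReactionEntry(
            reaction_id=rx.reaction_id, gene_ids=rx.genes(), substrate_ids=substrates
        )

    for i, bs in enumerate(spec.branches):
        rng = _rng(spec.seed, _STREAM_BRANCH, i)
        z1 = rng.standard_normal(n) * bs.enzyme_log2_sd
        z2 = rng.standard_normal(n) * bs.enzyme_log2_sd
        e1 = bs.params.e1 * 2.0 ** (z1 - z1.mean())
        e2 = bs.params.e2 * 2.0 ** (z2 - z2.mean())
        series, br_truth = generate_branch_series(
            bs.params, e1 / bs.params.e1, e2 / bs.params.e2,
            cv=0.0, branch_id=bs.branch_id,
        )
        ga, gb = f"g_{bs.rxn_a()}", f"g_{bs.rxn_b()}"
        j1_meas, j1_sd = _noisy(series.flux_a, spec.flux_cv, rng)
        j2_meas, j2_sd = _noisy(series.flux_b, spec.flux_cv, rng)
        m1_meas, m1_sd = _noisy(e1 / (spec.alpha * t_over_mu), spec.transcript_cv, rng)
        m2_meas, m2_sd = _noisy(e2 / (spec.alpha * t_over_mu), spec.transcript_cv, rng)
        for k, c in enumerate(conditions):
            flux_rows += [
                (bs.rxn_a(), c, j1_meas[k], j1_sd[k]),
                (bs.rxn_b(), c, j2_meas[k], j2_sd[k]),
            ]
            transcript_rows += [
                (ga, c, m1_meas[k], m1_sd[k]),
                (gb, c, m2_meas[k], m2_sd[k]),
            ]
        reactions[bs.rxn_a()] = ReactionEntry(bs.rxn_a(), (ga,))
        reactions[bs.rxn_b()] = ReactionEntry(bs.rxn_b(), (gb,))
        branches.append(BranchDef(bs.branch_id, bs.rxn_a(), bs.rxn_b()))
        truth.branch_params[bs.branch_id] = bs.params

    for i, oo in enumerate(spec.onoff):
        rng = _rng(spec.seed, _STREAM_ONOFF, i)
        on = set(oo.on_condition_idx)
        e_true = np.array(
            [
                oo.baseline_enzyme * (oo.induction_fold if k in on else 1.0)
                for k in range(n)
            ]
        )
        j_true = np.array([oo.flux_on if k in on else 0.0 for k in range(n)])
        m_meas, m_sd = _noisy(e_true / (spec.alpha * t_over_mu), spec.transcript_cv, rng)
        j_meas, j_sd = _noisy(j_true, spec.flux_cv, rng)  # zero stays exactly zero
        for k, c in enumerate(conditions):
            flux_rows.append((oo.reaction_id, c, j_meas[k], j_sd[k]))
            transcript_rows.append((oo.gene_id, c, m_meas[k], m_sd[k]))
        reactions[oo.reaction_id] = ReactionEntry(oo.reaction_id, (oo.gene_id,))
        truth.onoff_fold_by_gene[oo.gene_id] = oo.induction_fold

    dataset = Dataset(
        conditions=profiles,
        fluxes=pd.DataFrame(
            flux_rows, columns=["reaction", "condition", "flux", "flux_sd"]
        ),
        transcripts=pd.DataFrame(
            transcript_rows, columns=["gene", "condition", "signal", "signal_sd"]
        ),
        metabolites=pd.DataFrame(
            metab_rows,
            columns=["metabolite", "condition", "concentration", "concentration_sd"],
        ),
        reaction_map=ReactionMap(reactions=reactions, branches=branches),
    )
    return dataset.validate(), truth


def generate_branch_series(
    params: BranchParams,
    e1_factors: Sequence[float],
    e2_factors: Sequence[float],
    j_in_values: Sequence[float] | None = None,
    cv: float = 0.0,
    seed: int = 0,
    branch_id: str = "branch",
) -> tuple[BranchSeries, dict]:
    """Simulate a branch series across conditions from the kinetic model.

    Per condition, arm enzyme levels are the base levels multiplied by the
    given factors; the steady state is re-solved and the two fluxes
    recorded.  Infeasible schedule points raise with the condition named.
    Optional lognormal noise at relative SD ``cv`` applies to both fluxes
    and enzymes.
    """
    from dataclasses import replace

    e1f = np.asarray(e1_factors, dtype=float)
    e2f = np.asarray(e2_factors, dtype=float)
    if e1f.size != e2f.size:
        raise ValueError("enzyme factor schedules must align")
    n = e1f.size
    j_in = (
        np.full(n, params.j_in)
        if j_in_values is None
        else np.asarray(j_in_values, dtype=float)
    )
    conditions = [f"c{i + 1}" for i in range(n)]
    j1 = np.empty(n)
    j2 = np.empty(n)
    e1 = params.e1 * e1f
    e2 = params.e2 * e2f
    for k in range(n):
        try:
            p = replace(params, e1=e1[k], e2=e2[k], j_in=j_in[k])
        except Exception as exc:
            raise ValueError(f"condition {conditions[k]}: infeasible point ({exc})")
        j1[k], j2[k] = split_fluxes(p)
    rng = np.random.default_rng([seed, _STREAM_BRANCH, 0])
    j1m, j1sd = _noisy(j1, cv, rng)
    j2m, j2sd = _noisy(j2, cv, rng)
    e1m, e1sd = _noisy(e1, cv, rng)
    e2m, e2sd = _noisy(e2, cv, rng)
    series = BranchSeries(
        branch_id=branch_id,
        condition_ids=conditions,
        flux_a=j1m, flux_a_sd=j1sd,
        flux_b=j2m, flux_b_sd=j2sd,
        enzyme_a=e1m, enzyme_a_sd=e1sd,
        enzyme_b=e2m, enzyme_b_sd=e2sd,
    )
    truth = {"params": params, "e1": e1, "e2": e2, "j1": j1, "j2": j2}
    return series, truth


def default_spec(seed: int = 0, **overrides) -> SyntheticSpec:
    """A representative study-scale spec: 8 conditions, mixed regulation.

    Four central reactions spanning the regulatory spectrum (true rho 0,
    0.3, 0.7, 1.0), one substrate-driven reaction (flat enzyme, lambda = 1),
    one substrate-coupled reaction with partial hierarchical control, an
    isozyme pair, a kinetically simulated branch point in the low-load
    regime, and two uptake-like on/off genes with 10- and 100-fold
    induction.
    """
    reactions = [
        ReactionSpec("R_metabolic", true_rho=0.0),
        ReactionSpec("R_partial", true_rho=0.3),
        ReactionSpec("R_mixed", true_rho=0.7),
        ReactionSpec("R_hier", true_rho=1.0),
        ReactionSpec(
            "R_substrate", true_rho=0.0, true_lambda=1.0, substrate_id="S_substrate"
        ),
        ReactionSpec(
            "R_es", true_rho=0.5, true_lambda=1.0, substrate_id="S_es"
        ),
        ReactionSpec("R_iso", true_rho=0.7, gene_ids=("g_iso1", "g_iso2")),
    ]
    branch = BranchSpec(
        branch_id="bp1",
        params=BranchParams(
            kcat1=60.0, km1=5.0, e1=1.0, kcat2=40.0, km2=2.0, e2=1.0, j_in=2.0
        ),
    )
    onoff = [
        OnOffSpec("g_uptake1", "R_uptake1", (0, 1), induction_fold=100.0),
        OnOffSpec("g_uptake2", "R_uptake2", (5, 6, 7), induction_fold=10.0),
    ]
    kwargs = dict(
        reactions=reactions, onoff=onoff, branches=[branch], seed=seed
    )
    kwargs.update(overrides)
    return SyntheticSpec(**kwargs)
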
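"""Data model and tabular I/O for multi-condition flux-regulation datasets.

A :class:`Dataset` bundles everything the regulatory analysis needs for one
organism grown under several steady-state conditions:

* per-condition growth rates (h^-1),
* net reaction fluxes (mmol gcdw^-1 h^-1, signed) with measurement SDs,
* transcript signals (fraction of total mRNA) with SDs,
* intracellular metabolite concentrations with SDs,
* a reaction map linking reactions to catalysing genes (isozymes allowed)
  and substrate metabolites, plus two-arm branch-point definitions.

All tables are UTF-8 TSV with a single header row; missing values are
written as ``NA``.  Fluxes are kept signed here — direction handling
(splitting reversible reactions by flux sign) happens downstream in the
pairing module.  Condition order is the file order and is preserved in
every derived output.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "ConditionProfile",
    "ReactionEntry",
    "BranchDef",
    "ReactionMap",
    "Dataset",
    "read_dataset",
    "write_dataset",
    "write_results",
    "read_results",
]

CONDITION_COLS = ["condition", "growth_rate", "growth_rate_sd"]
FLUX_COLS = ["reaction", "condition", "flux", "flux_sd"]
TRANSCRIPT_COLS = ["gene", "condition", "signal", "signal_sd"]
METABOLITE_COLS = ["metabolite", "condition", "concentration", "concentration_sd"]
MAP_COLS = ["reaction", "genes", "substrates", "reversible"]
BRANCH_COLS = ["branch", "reaction_a", "reaction_b"]

RESULT_COLS = [
    "id",
    "rho",
    "ci_low",
    "ci_high",
    "p_value",
    "r2",
    "mean_abs_residual",
    "n_points",
    "class",
]

#: format used for every float written to disk; 12 significant digits are
#: enough to round-trip the quantities handled here.
FLOAT_FMT = "%.12g"


class FormatError(ValueError):
    """A file does not match the documented column contract."""


class ValidationError(ValueError):
    """A Dataset violates one of its stated invariants."""


@dataclass(frozen=True)
class ConditionProfile:
    """One growth condition: identifier and growth rate mu (h^-1) with SD."""

    condition_id: str
    growth_rate: float
    growth_rate_sd: float = 0.0

    def __post_init__(self) -> None:
        if not self.growth_rate > 0:
            raise ValidationError(
                f"condition {self.condition_id!r}: growth_rate must be > 0, "
                f"got {self.growth_rate}"
            )
        if self.growth_rate_sd < 0:
            raise ValidationError(
                f"condition {self.condition_id!r}: growth_rate_sd must be >= 0"
            )


@dataclass(frozen=True)
class ReactionEntry:
    """Map entry for one reaction: catalysing genes and substrate metabolites."""

    reaction_id: str
    gene_ids: tuple[str, ...]
    substrate_ids: tuple[str, ...] = ()
    reversible: bool = False

    def __post_init__(self) -> None:
        if len(self.gene_ids) < 1:
            raise ValidationError(
                f"reaction {self.reaction_id!r}: needs at least one gene"
            )


@dataclass(frozen=True)
class BranchDef:
    """A metabolic branch point: one substrate split between two reactions."""

    branch_id: str
    reaction_a: str
    reaction_b: str

    def __post_init__(self) -> None:
        if self.reaction_a == self.reaction_b:
            raise ValidationError(
                f"branch {self.branch_id!r}: the two arms must be distinct reactions"
            )


@dataclass
class ReactionMap:
    reactions: dict[str, ReactionEntry] = field(default_factory=dict)
    branches: list[BranchDef] = field(default_factory=list)

    def genes_for(self, reaction_id: str) -> tuple[str, ...]:
        return self.reactions[reaction_id].gene_ids


@dataclass
class Dataset:
    """The joined multi-omic bundle the pipeline operates on.

    ``fluxes``, ``transcripts`` and ``metabolites`` are long-format pandas
    DataFrames with the canonical columns defined at module level.
    """

    conditions: list[ConditionProfile]
    fluxes: pd.DataFrame
    transcripts: pd.DataFrame
    metabolites: pd.DataFrame
    reaction_map: ReactionMap

    @property
    def condition_ids(self) -> list[str]:
        return [c.condition_id for c in self.conditions]

    def growth_rate(self, condition_id: str) -> float:
        for c in self.conditions:
            if c.condition_id == condition_id:
                return c.growth_rate
        raise KeyError(condition_id)

    def validate(self) -> "Dataset":
        """Check every cross-reference and invariant; raise ValidationError."""
        ids = self.condition_ids
        if len(ids) < 2:
            raise ValidationError("a Dataset needs at least 2 conditions")
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise ValidationError(f"duplicate condition ids: {sorted(dup)}")
        known = set(ids)

        def _check_conditions(df: pd.DataFrame, name: str) -> None:
            bad = sorted(set(df["condition"]) - known)
            if bad:
                raise ValidationError(
                    f"{name} table references unknown conditions: {bad}"
                )

        _check_conditions(self.fluxes, "flux")
        _check_conditions(self.transcripts, "transcript")
        if len(self.metabolites):
            _check_conditions(self.metabolites, "metabolite")

        dups = self.fluxes.duplicated(subset=["reaction", "condition"])
        if dups.any():
            pairs = self.fluxes.loc[dups, ["reaction", "condition"]]
            raise ValidationError(
                "duplicate (reaction, condition) flux entries: "
                + ", ".join(f"({r}, {c})" for r, c in pairs.itertuples(index=False))
            )
        for df, keycol, name in [
            (self.transcripts, "gene", "transcript"),
            (self.metabolites, "metabolite", "metabolite"),
        ]:
            if len(df) == 0:
                continue
            d = df.duplicated(subset=[keycol, "condition"])
            if d.any():
                bad_ids = sorted(df.loc[d, keycol].unique())
                raise ValidationError(f"duplicate {name} entries for: {bad_ids}")

        if (self.fluxes["flux_sd"] < 0).any():
            bad_ids = sorted(self.fluxes.loc[self.fluxes["flux_sd"] < 0, "reaction"])
            raise ValidationError(f"negative flux_sd for reactions: {bad_ids}")
        neg = self.transcripts["signal"] < 0
        if neg.any():
            raise ValidationError(
                f"negative transcript signal for genes: "
                f"{sorted(self.transcripts.loc[neg, 'gene'].unique())}"
            )
        if len(self.metabolites):
            measured = self.metabolites["concentration"].notna()
            nonpos = measured & ~(self.metabolites["concentration"] > 0)
            if nonpos.any():
                raise ValidationError(
                    "non-positive measured concentration for metabolites: "
                    f"{sorted(self.metabolites.loc[nonpos, 'metabolite'].unique())}"
                )

        genes = set(self.transcripts["gene"])
        mets = set(self.metabolites["metabolite"]) if len(self.metabolites) else set()
        rxns = set(self.reaction_map.reactions)
        dangling_rxn = sorted(set(self.fluxes["reaction"]) - rxns)
        if dangling_rxn:
            raise ValidationError(
                f"flux table references reactions absent from the map: {dangling_rxn}"
            )
        for entry in self.reaction_map.reactions.values():
            missing_g = sorted(set(entry.gene_ids) - genes)
            if missing_g:
                raise ValidationError(
                    f"reaction {entry.reaction_id!r} references unknown genes: {missing_g}"
                )
            missing_s = sorted(set(entry.substrate_ids) - mets)
            if missing_s:
                raise ValidationError(
                    f"reaction {entry.reaction_id!r} references unknown "
                    f"metabolites: {missing_s}"
                )
        for br in self.reaction_map.branches:
            missing = sorted({br.reaction_a, br.reaction_b} - rxns)
            if missing:
                raise ValidationError(
                    f"branch {br.branch_id!r} references unknown reactions: {missing}"
                )
        return self


def _read_table(path: str | Path, required: Sequence[str], name: str) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype={c: str for c in ("condition",)}
    )
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{name} table {path}: missing column(s) {missing}")
    return df


def _split_list(cell: object) -> tuple[str, ...]:
    if cell is None or (isinstance(cell, float) and np.isnan(cell)) or cell == "":
        return ()
    return tuple(s for s in str(cell).split(";") if s)


def read_reaction_map(map_path: str | Path, branch_path: str | Path | None = None) -> ReactionMap:
    df = _read_table(map_path, MAP_COLS, "reaction map")
    reactions: dict[str, ReactionEntry] = {}
    for row in df.itertuples(index=False):
        rid = str(row.reaction)
        if rid in reactions:
            raise ValidationError(f"duplicate reaction {rid!r} in map")
        reactions[rid] = ReactionEntry(
            reaction_id=rid,
            gene_ids=_split_list(row.genes),
            substrate_ids=_split_list(row.substrates),
            reversible=bool(int(row.reversible)),
        )
    branches: list[BranchDef] = []
    if branch_path is not None:
        bdf = _read_table(branch_path, BRANCH_COLS, "branch")
        branches = [
            BranchDef(str(r.branch), str(r.reaction_a), str(r.reaction_b))
            for r in bdf.itertuples(index=False)
        ]
    return ReactionMap(reactions=reactions, branches=branches)


def read_dataset(paths: Mapping[str, str | Path], validate: bool = True) -> Dataset:
    """Read a Dataset from TSV files.

    Parameters
    ----------
    paths
        Mapping with keys ``conditions``, ``fluxes``, ``transcripts``,
        ``metabolites``, ``map`` and optionally ``branches``.
    validate
        Run :meth:`Dataset.validate` before returning (default).
    """
    cond_df = _read_table(paths["conditions"], CONDITION_COLS, "condition")
    conditions = [
        ConditionProfile(
            condition_id=str(r.condition),
            growth_rate=float(r.growth_rate),
            growth_rate_sd=float(r.growth_rate_sd),
        )
        for r in cond_df.itertuples(index=False)
    ]
    ds = Dataset(
        conditions=conditions,
        fluxes=_read_table(paths["fluxes"], FLUX_COLS, "flux"),
        transcripts=_read_table(paths["transcripts"], TRANSCRIPT_COLS, "transcript"),
        metabolites=_read_table(paths["metabolites"], METABOLITE_COLS, "metabolite"),
        reaction_map=read_reaction_map(paths["map"], paths.get("branches")),
    )
    return ds.validate() if validate else ds


def _write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT, na_rep="NA")


def write_dataset(dataset: Dataset, out_dir: str | Path) -> dict[str, Path]:
    """Write every table of a Dataset as TSV into ``out_dir``.

    Returns the mapping of table names to file paths (suitable for
    :func:`read_dataset`).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cond_df = pd.DataFrame(
        {
            "condition": [c.condition_id for c in dataset.conditions],
            "growth_rate": [c.growth_rate for c in dataset.conditions],
            "growth_rate_sd": [c.growth_rate_sd for c in dataset.conditions],
        }
    )
    map_df = pd.DataFrame(
        {
            "reaction": list(dataset.reaction_map.reactions),
            "genes": [
                ";".join(e.gene_ids) for e in dataset.reaction_map.reactions.values()
            ],
            "substrates": [
                ";".join(e.substrate_ids)
                for e in dataset.reaction_map.reactions.values()
            ],
            "reversible": [
                int(e.reversible) for e in dataset.reaction_map.reactions.values()
            ],
        }
    )
    branch_df = pd.DataFrame(
        {
            "branch": [b.branch_id for b in dataset.reaction_map.branches],
            "reaction_a": [b.reaction_a for b in dataset.reaction_map.branches],
            "reaction_b": [b.reaction_b for b in dataset.reaction_map.branches],
        },
        columns=BRANCH_COLS,
    )
    paths = {
        "conditions": out / "conditions.tsv",
        "fluxes": out / "fluxes.tsv",
        "transcripts": out / "transcripts.tsv",
        "metabolites": out / "metabolites.tsv",
        "map": out / "map.tsv",
        "branches": out / "branches.tsv",
    }
    _write_tsv(cond_df, paths["conditions"])
    _write_tsv(dataset.fluxes[FLUX_COLS], paths["fluxes"])
    _write_tsv(dataset.transcripts[TRANSCRIPT_COLS], paths["transcripts"])
    met = dataset.metabolites
    if len(met) == 0:
        met = pd.DataFrame(columns=METABOLITE_COLS)
    _write_tsv(met[METABOLITE_COLS], paths["metabolites"])
    _write_tsv(map_df, paths["map"])
    _write_tsv(branch_df, paths["branches"])
    return paths


def write_results(fits: Iterable, path: str | Path) -> None:
    """Write regulatory fits as a results TSV (one row per fit).

    ``fits`` are objects exposing the RegulatoryFit fields; an empty list is
    a precondition violation (an empty results file would be ambiguous).
    """
    fits = list(fits)
    if not fits:
        raise ValueError("write_results: no fits to write")
    df = pd.DataFrame(
        {
            "id": [f.task_id for f in fits],
            "rho": [f.rho for f in fits],
            "ci_low": [f.ci_low for f in fits],
            "ci_high": [f.ci_high for f in fits],
            "p_value": [f.p_value for f in fits],
            "r2": [f.r2 for f in fits],
            "mean_abs_residual": [f.mean_abs_residual for f in fits],
            "n_points": [f.n_points for f in fits],
            "class": [f.fit_class for f in fits],
        }
    )
    _write_tsv(df, path)


def read_results(path: str | Path) -> pd.DataFrame:
    return _read_table(path, RESULT_COLS, "results")
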
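"""End-to-end orchestration of the regulatory analysis.

Stage order: enzyme inference -> flux-enzyme pairing -> rho_h fits ->
branch-point rho_hr fits -> combined enzyme+substrate rho_es fits ->
growth-rate scaling -> on/off summary, followed by a consolidated text
report.  Transcript tables are expected to be replicate-summarized already
(the preprocess module handles replicate-level arrays).

Every run is deterministic given the configured seed: per-task resampling
seeds are derived from the base seed and the task's position in the stable
task ordering.  Each output TSV starts with a comment line recording the
seed, and an effective-config echo is written for provenance.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .enzyme_inference import TotalMrnaModel, infer_enzymes
from .growth_scaling import fit_growth_scaling, summarize_growth_scaling
from .io_model import FLOAT_FMT, Dataset, write_results
from .metabolite_regulation import fit_rho_es
from .onoff import onoff_summary
from .pairing import build_fit_tasks, select_fluxes
from .regulatory_fit import ResampleConfig, fit_rho
from .split_ratio import build_branch_series, fit_rho_hr

__all__ = ["PipelineConfig", "StageError", "run_pipeline", "flux_variability_summary"]

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    out_dir: str | Path = "regflux_out"
    cutoff: float = 0.1
    min_conditions: int = 3
    min_branch_points: int = 5
    resample: ResampleConfig = field(default_factory=ResampleConfig)
    mrna_model: TotalMrnaModel = field(default_factory=TotalMrnaModel)
    alpha: float = 1.0
    branch_exclude: list[str] = field(default_factory=list)
    biosynthetic_genes: Optional[list[str]] = None
    collinearity_groups: Optional[Mapping[str, Sequence[str]]] = None
    run_splits: bool = True
    run_es: bool = True
    run_growth: bool = True
    run_onoff: bool = True


def _task_seed(base: int, index: int) -> int:
    return int((base + 9973 * (index + 1)) % (2**31))


def _write_with_header(df: pd.DataFrame, path: Path, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"# regflux seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT, na_rep="NA")


def flux_variability_summary(
    fluxes: pd.DataFrame,
    groups: Mapping[str, Sequence[str]] | None = None,
    cutoff: float = 0.1,
) -> dict:
    """Fold-change summary of flux variability across conditions.

    ``groups`` maps collinearity-group labels to member reactions (members
    of a group carry proportional fluxes, so any member represents it; the
    group fold change is the max over members).  Without an annotation each
    reaction is its own group.  Only conditions with |flux| > cutoff enter
    the max/min ratio, and only groups non-zero in more than one condition
    are counted against the 2-fold and 5-fold thresholds.
    """
    if groups is None:
        groups = {r: [r] for r in fluxes["reaction"].drop_duplicates()}
    rows = []
    for label, members in groups.items():
        ratios = []
        n_active = 0
        for r in members:
            v = fluxes.loc[fluxes["reaction"] == r, "flux"].abs()
            v = v[v > cutoff]
            n_active = max(n_active, len(v))
            if len(v) >= 2:
                ratios.append(v.max() / v.min())
        rows.append(
            {
                "group": label,
                "n_active_conditions": n_active,
                "fold_range": max(ratios) if ratios else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    multi = table[table["n_active_conditions"] > 1].dropna(subset=["fold_range"])
    return {
        "table": table,
        "n_groups_multi_condition": int(len(multi)),
        "n_ge_2fold": int((multi["fold_range"] >= 2).sum()),
        "n_ge_5fold": int((multi["fold_range"] >= 5).sum()),
    }


def run_pipeline(dataset: Dataset, cfg: PipelineConfig) -> dict:
    """Run the configured stages and write the report bundle.

    Returns a dict of in-memory results (DataFrames and summary counts).
    A stage failure raises :class:`StageError` after preserving whatever
    outputs earlier stages wrote.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg.resample.seed
    results: dict = {}

    with open(out / "effective_config.txt", "w") as fh:
        fh.write(f"seed\t{seed}\n")
        for key in (
            "cutoff", "min_conditions", "min_branch_points", "alpha",
            "branch_exclude", "run_splits", "run_es", "run_growth", "run_onoff",
        ):
            fh.write(f"{key}\t{getattr(cfg, key)}\n")
        fh.write(f"n_iter\t{cfg.resample.n_iter}\n")
        fh.write(f"subset_fraction\t{cfg.resample.subset_fraction}\n")
        fh.write(f"min_subset\t{cfg.resample.min_subset}\n")
        fh.write(f"noise\t{cfg.resample.noise}\n")
        fh.write(f"mrna_a\t{cfg.mrna_model.a}\nmrna_b\t{cfg.mrna_model.b}\n")

    def _stage(name: str):
        log.info("stage %s: start", name)
        return time.perf_counter()

    # --- enzyme inference -------------------------------------------------
    t0 = _stage("infer_enzymes")
    try:
        enzymes = infer_enzymes(
            dataset.transcripts, dataset.conditions, cfg.mrna_model, cfg.alpha
        )
    except Exception as exc:
        raise StageError("infer_enzymes", exc)
    results["enzymes"] = enzymes
    log.info(
        "stage infer_enzymes: %d rows in %.2fs", len(enzymes), time.perf_counter() - t0
    )

    # --- rho_h fits -------------------------------------------------------
    t0 = _stage("fit_rho")
    try:
        tasks = build_fit_tasks(dataset, enzymes, cfg.cutoff, cfg.min_conditions)
        fits = [
            fit_rho(t, replace(cfg.resample, seed=_task_seed(seed, i)))
            for i, t in enumerate(tasks)
        ]
    except Exception as exc:
        raise StageError("fit_rho", exc)
    results["tasks"] = tasks
    results["rho_h"] = fits
    if fits:
        write_results(fits, out / "rho_h.tsv")
    log.info("stage fit_rho: %d tasks in %.2fs", len(tasks), time.perf_counter() - t0)

    # --- branch splits ----------------------------------------------------
    if cfg.run_splits:
        t0 = _stage("split_ratio")
        try:
            series = build_branch_series(
                dataset, enzymes, cfg.cutoff, cfg.min_branch_points, cfg.branch_exclude
            )
            hr_fits = [
                fit_rho_hr(
                    s,
                    replace(cfg.resample, seed=_task_seed(seed, 10_000 + i)),
                    cfg.min_branch_points,
                )
                for i, s in enumerate(series)
            ]
        except Exception as exc:
            raise StageError("split_ratio", exc)
        results["rho_hr"] = hr_fits
        if hr_fits:
            write_results(hr_fits, out / "rho_hr.tsv")
        log.info(
            "stage split_ratio: %d branches in %.2fs",
            len(series), time.perf_counter() - t0,
        )

    # --- combined enzyme + substrate --------------------------------------
    if cfg.run_es:
        t0 = _stage("fit_rho_es")
        try:
            met = dataset.metabolites.set_index(["metabolite", "condition"])
            es_rows = []
            for i, task in enumerate(tasks):
                entry = dataset.reaction_map.reactions[task.reaction_id]
                for substrate in entry.substrate_ids:
                    conc, conc_sd = [], []
                    for c in task.condition_ids:
                        if (substrate, c) in met.index:
                            conc.append(float(met.loc[(substrate, c), "concentration"]))
                            conc_sd.append(
                                float(met.loc[(substrate, c), "concentration_sd"])
                            )
                        else:
                            conc.append(np.nan)
                            conc_sd.append(np.nan)
                    sub_cfg = replace(cfg.resample, seed=_task_seed(seed, i))
                    try:
                        sf = fit_rho_es(
                            task, np.array(conc), np.array(conc_sd), sub_cfg
                        )
                    except ValueError as exc:
                        log.warning("task %s: rho_es skipped (%s)", task.task_id, exc)
                        continue
                    es_rows.append(
                        {
                            "id": f"{task.task_id}@{substrate}",
                            "lambda": sf.lambda_,
                            "rho_h": sf.rho_h,
                            "rho_es": sf.fit.rho,
                            "delta": sf.delta,
                            "ci_low": sf.fit.ci_low,
                            "ci_high": sf.fit.ci_high,
                            "r2": sf.fit.r2,
                            "p_value": sf.fit.p_value,
                            "n_points": sf.fit.n_points,
                        }
                    )
        except StageError:
            raise
        except Exception as exc:
            raise StageError("fit_rho_es", exc)
        es_table = pd.DataFrame(es_rows)
        results["rho_es"] = es_table
        if len(es_table):
            _write_with_header(es_table, out / "rho_es.tsv", seed)
        log.info(
            "stage fit_rho_es: %d fits in %.2fs", len(es_rows), time.perf_counter() - t0
        )

    # --- growth scaling ---------------------------------------------------
    if cfg.run_growth and cfg.biosynthetic_genes:
        t0 = _stage("growth_scaling")
        try:
            mu = np.array([c.growth_rate for c in dataset.conditions])
            tr = dataset.transcripts.set_index(["gene", "condition"])
            gs = []
            for gene in cfg.biosynthetic_genes:
                sig = np.array(
                    [
                        float(tr.loc[(gene, c), "signal"])
                        if (gene, c) in tr.index
                        else 0.0
                        for c in dataset.condition_ids
                    ]
                )
                for level in ("mrna", "protein"):
                    res = fit_growth_scaling(gene, sig, mu, level, cfg.mrna_model)
                    if res is not None:
                        gs.append(res)
            gs_table = pd.DataFrame(
                {
                    "gene": [g.gene_id for g in gs],
                    "level": [g.level for g in gs],
                    "rho": [g.rho for g in gs],
                    "r2": [g.r2 for g in gs],
                    "r": [g.r for g in gs],
                    "n_points": [g.n_points for g in gs],
                }
            )
            results["growth_scaling"] = gs_table
            results["growth_scaling_summary"] = (
                summarize_growth_scaling(gs) if gs else None
            )
            if len(gs_table):
                _write_with_header(gs_table, out / "growth_scaling.tsv", seed)
        except Exception as exc:
            raise StageError("growth_scaling", exc)
        log.info("stage growth_scaling: %d fits in %.2fs", len(gs), time.perf_counter() - t0)

    # --- on/off -----------------------------------------------------------
    if cfg.run_onoff:
        t0 = _stage("onoff")
        try:
            oo = onoff_summary(dataset, enzymes, cutoff=cfg.cutoff)
            oo_table = pd.DataFrame(
                {
                    "gene": [s.gene_id for s in oo],
                    "n_on": [len(s.on_conditions) for s in oo],
                    "n_off": [len(s.off_conditions) for s in oo],
                    "mean_on": [s.mean_on for s in oo],
                    "mean_off": [s.mean_off for s in oo],
                    "fold_change": [s.fold_change for s in oo],
                }
            )
        except Exception as exc:
            raise StageError("onoff", exc)
        results["onoff"] = oo_table
        if len(oo_table):
            _write_with_header(oo_table, out / "onoff.tsv", seed)
        log.info("stage onoff: %d genes in %.2fs", len(oo_table), time.perf_counter() - t0)

    # --- summary ----------------------------------------------------------
    variability = flux_variability_summary(
        dataset.fluxes, cfg.collinearity_groups, cfg.cutoff
    )
    results["flux_variability"] = variability
    class_counts = pd.Series(
        [f.fit_class for f in results.get("rho_h", [])], dtype=object
    ).value_counts()
    kept = select_fluxes(dataset.fluxes, cfg.cutoff, cfg.min_conditions)
    with open(out / "summary.txt", "w") as fh:
        fh.write(f"seed\t{seed}\n")
        fh.write(f"n_conditions\t{len(dataset.conditions)}\n")
        fh.write(f"n_reactions_kept\t{kept['reaction'].nunique()}\n")
        fh.write(f"n_tasks\t{len(results.get('tasks', []))}\n")
        for cls, cnt in class_counts.items():
            fh.write(f"class_{cls}\t{cnt}\n")
        fh.write(
            f"flux_groups_multi\t{variability['n_groups_multi_condition']}\n"
            f"flux_groups_ge2fold\t{variability['n_ge_2fold']}\n"
            f"flux_groups_ge5fold\t{variability['n_ge_5fold']}\n"
        )
    return results
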
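"""Flux cutoff filtering and fit-task enumeration."""

import numpy as np
import pandas as pd
import pytest

from regflux.enzyme_inference import infer_enzymes
from regflux.io_model import ReactionEntry
from regflux.pairing import build_fit_tasks, select_fluxes

from conftest import make_dataset


def _flux_df(rows):
    return pd.DataFrame(rows, columns=["reaction", "condition", "flux", "flux_sd"])


class TestSelectFluxes:
    def test_reaction_below_min_conditions_dropped(self):
        rows = [("R1", f"c{i}", 1.0 if i < 2 else 0.05, 0.01) for i in range(8)]
        assert len(select_fluxes(_flux_df(rows), 0.1, 3)) == 0

    def test_reaction_above_cutoff_everywhere_fully_retained(self):
        rows = [("R1", f"c{i}", 2.0, 0.1) for i in range(8)]
        assert len(select_fluxes(_flux_df(rows), 0.1, 3)) == 8

    def test_below_cutoff_conditions_removed_within_kept_reaction(self):
        rows = [("R1", "c1", 1.0, 0.1), ("R1", "c2", 0.05, 0.1),
                ("R1", "c3", 2.0, 0.1), ("R1", "c4", -0.5, 0.1)]
        out = select_fluxes(_flux_df(rows), 0.1, 3)
        assert set(out["condition"]) == {"c1", "c3", "c4"}

    def test_negative_fluxes_count_by_magnitude(self):
        rows = [("R1", f"c{i}", -1.0, 0.1) for i in range(3)]
        assert len(select_fluxes(_flux_df(rows), 0.1, 3)) == 3

    def test_matches_brute_force_filter(self):
        rng = np.random.default_rng(4)
        rows = [
            (f"R{r}", f"c{c}", float(rng.normal(0, 0.5)), 0.01)
            for r in range(5)
            for c in range(8)
        ]
        df = _flux_df(rows)
        out = select_fluxes(df, 0.1, 3)
        # brute-force oracle
        expected = []
        for r in df["reaction"].unique():
            sub = df[df["reaction"] == r]
            above = sub[sub["flux"].abs() > 0.1]
            if len(above) >= 3:
                expected.extend(above.itertuples(index=False))
        assert len(out) == len(expected)
        assert set(zip(out["reaction"], out["condition"])) == {
            (e.reaction, e.condition) for e in expected
        }


def _eight_condition_dataset(flux_rows, reactions, genes):
    conditions = [(f"c{i}", 0.2 + 0.07 * i, 0.01) for i in range(8)]
    transcript_rows = [
        (g, f"c{i}", 1.0 + 0.1 * i, 0.05) for g in genes for i in range(8)
    ]
    return make_dataset(
        conditions=conditions,
        flux_rows=flux_rows,
        transcript_rows=transcript_rows,
        reactions=reactions,
    )


class TestBuildFitTasks:
    def test_isozymes_give_one_task_each(self):
        ds = _eight_condition_dataset(
            [("R1", f"c{i}", 1.0, 0.1) for i in range(8)],
            [ReactionEntry("R1", ("g1", "g2"))],
            ["g1", "g2"],
        )
        enz = infer_enzymes(ds.transcripts, ds.conditions)
        tasks = build_fit_tasks(ds, enz)
        assert sorted(t.task_id for t in tasks) == ["R1:g1", "R1:g2"]

    def test_reversible_sign_change_splits_directions(self):
        flux = [("R1", f"c{i}", 1.0 if i < 3 else -1.0, 0.1) for i in range(6)]
        flux += [("R1", f"c{i}", 0.05, 0.1) for i in range(6, 8)]
        ds = _eight_condition_dataset(
            flux, [ReactionEntry("R1", ("g1",), reversible=True)], ["g1"]
        )
        enz = infer_enzymes(ds.transcripts, ds.conditions)
        tasks = build_fit_tasks(ds, enz)
        assert sorted(t.task_id for t in tasks) == ["R1+:g1", "R1-:g1"]
        assert all(t.n_points == 3 for t in tasks)
        assert all((t.x > 0).all() for t in tasks)

    def test_task_count_matches_hand_enumeration(self):
        # R1: 2 isozymes (2 tasks); R2: active in 2 conditions only (0 tasks);
        # R3: 1 gene (1 task) -> 3 tasks total
        flux = [("R1", f"c{i}", 2.0, 0.1) for i in range(8)]
        flux += [("R2", f"c{i}", 1.0 if i < 2 else 0.01, 0.1) for i in range(8)]
        flux += [("R3", f"c{i}", 0.5, 0.05) for i in range(8)]
        ds = _eight_condition_dataset(
            flux,
            [
                ReactionEntry("R1", ("g1", "g2")),
                ReactionEntry("R2", ("g3",)),
                ReactionEntry("R3", ("g3",)),
            ],
            ["g1", "g2", "g3"],
        )
        enz = infer_enzymes(ds.transcripts, ds.conditions)
        assert len(build_fit_tasks(ds, enz)) == 3

    def test_no_task_contains_below_cutoff_condition(self):
        flux = [("R1", f"c{i}", 0.05 if i % 2 else 1.0, 0.1) for i in range(8)]
        ds = _eight_condition_dataset(flux, [ReactionEntry("R1", ("g1",))], ["g1"])
        enz = infer_enzymes(ds.transcripts, ds.conditions)
        (task,) = build_fit_tasks(ds, enz)
        assert (task.x > 0.1).all()
        assert task.condition_ids == ["c0", "c2", "c4", "c6"]

    def test_gene_without_enzyme_data_skipped(self, caplog):
        ds = _eight_condition_dataset(
            [("R1", f"c{i}", 1.0, 0.1) for i in range(8)],
            [ReactionEntry("R1", ("g1",))],
            ["g1"],
        )
        enz = infer_enzymes(ds.transcripts, ds.conditions)
        enz = enz[enz["gene"] != "g1"]
        assert build_fit_tasks(ds, enz) == []

    def test_condition_order_invariance_of_task_count(self):
        flux = [("R1", f"c{i}", 0.5 + 0.2 * i, 0.05) for i in range(8)]
        ds = _eight_condition_dataset(flux, [ReactionEntry("R1", ("g1",))], ["g1"])
        enz = infer_enzymes(ds.transcripts, ds.conditions)
        n1 = len(build_fit_tasks(ds, enz))
        ds.fluxes = ds.fluxes.iloc[::-1].reset_index(drop=True)
        assert len(build_fit_tasks(ds, enz)) == n1
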
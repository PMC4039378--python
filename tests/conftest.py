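import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from regflux.io_model import (
    BranchDef,
    ConditionProfile,
    Dataset,
    ReactionEntry,
    ReactionMap,
)


def make_dataset(
    conditions=None,
    flux_rows=None,
    transcript_rows=None,
    metabolite_rows=None,
    reactions=None,
    branches=None,
    validate=True,
):
    """Assemble a small Dataset from row tuples."""
    conditions = conditions or [("c1", 0.3, 0.01), ("c2", 0.6, 0.02)]
    flux_rows = flux_rows if flux_rows is not None else []
    transcript_rows = transcript_rows if transcript_rows is not None else []
    metabolite_rows = metabolite_rows if metabolite_rows is not None else []
    ds = Dataset(
        conditions=[ConditionProfile(*c) for c in conditions],
        fluxes=pd.DataFrame(
            flux_rows, columns=["reaction", "condition", "flux", "flux_sd"]
        ),
        transcripts=pd.DataFrame(
            transcript_rows, columns=["gene", "condition", "signal", "signal_sd"]
        ),
        metabolites=pd.DataFrame(
            metabolite_rows,
            columns=["metabolite", "condition", "concentration", "concentration_sd"],
        ),
        reaction_map=ReactionMap(
            reactions={r.reaction_id: r for r in (reactions or [])},
            branches=list(branches or []),
        ),
    )
    return ds.validate() if validate else ds


@pytest.fixture
def two_condition_dataset():
    return make_dataset(
        flux_rows=[("R1", "c1", 1.0, 0.1), ("R1", "c2", 2.0, 0.2)],
        transcript_rows=[("gA", "c1", 0.001, 0.0001), ("gA", "c2", 0.002, 0.0002)],
        metabolite_rows=[("M1", "c1", 1.5, 0.1), ("M1", "c2", 3.0, 0.2)],
        reactions=[ReactionEntry("R1", ("gA",), ("M1",))],
    )


def oracle_weighted_median(values, weights):
    """Independent cumulative-weight scan (sorted by value, lower median)."""
    pairs = sorted(zip(values, weights))
    total = sum(w for _, w in pairs)
    acc = 0.0
    for v, w in pairs:
        acc += w
        if acc >= total / 2.0:
            return v
    return pairs[-1][0]


def oracle_weighted_theil_sen(x, y):
    """Brute-force loop over all pairs; independent of the implementation."""
    slopes, weights = [], []
    for i in range(len(x)):
        for j in range(i + 1, len(x)):
            dx = x[j] - x[i]
            if dx == 0:
                continue
            slopes.append((y[j] - y[i]) / dx)
            weights.append(dx * dx)
    assert slopes, "degenerate oracle input"
    return oracle_weighted_median(slopes, weights)
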
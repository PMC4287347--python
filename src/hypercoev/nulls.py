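"""Null models for the hyperedge pipeline.

Both nulls act on the windowed edge-weight series, not the raw signals:

* *overall*: each edge row is independently permuted over all W windows,
  destroying every temporal relationship while preserving each row's value
  multiset.  Hyperedges surviving this null would indicate a static,
  dynamics-free property of the data; none are expected.
* *within-task*: each edge row is independently permuted within each
  task's window block, so values never cross tasks.  Co-evolution driven
  by between-task level differences survives; purely within-task transient
  co-evolution is destroyed.

Each row gets its own random stream spawned from the master seed - a
common permutation across rows would preserve all edge-edge correlations
and break the null.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .dynamics import EdgeTimeSeriesMatrix
from .hypergraph import (
    Hypergraph,
    edge_edge_correlation,
    extract_hyperedges,
    fdr_binarize,
    size_distribution,
)

NULL_KINDS = ("overall", "within-task")


@dataclass(frozen=True)
class NullSpec:
    kind: str
    seed: int

    def __post_init__(self) -> None:
        if self.kind not in NULL_KINDS:
            raise ValueError(f"null kind must be one of {NULL_KINDS}")


def _row_rngs(n_rows: int, seed: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(n_rows)]


def shuffle_overall(ets: EdgeTimeSeriesMatrix, seed: int) -> EdgeTimeSeriesMatrix:
    """Independently permute every edge row over all windows."""
    shuffled = ets.weights.copy()
    for row, rng in zip(shuffled, _row_rngs(ets.n_edges, seed)):
        rng.shuffle(row)
    return replace(ets, weights=shuffled)


def shuffle_within_task(ets: EdgeTimeSeriesMatrix, seed: int) -> EdgeTimeSeriesMatrix:
    """Independently permute every edge row within each task's window block."""
    if ets.window_tasks.size == 0:
        raise ValueError("window task labels are required for the within-task null")
    blocks = [ets.task_windows(t) for t in ets.tasks]
    shuffled = ets.weights.copy()
    for row, rng in zip(shuffled, _row_rngs(ets.n_edges, seed)):
        for cols in blocks:
            row[cols] = row[cols][rng.permutation(cols.size)]
    return replace(ets, weights=shuffled)


def run_null(
    ets: EdgeTimeSeriesMatrix, spec: NullSpec, q: float = 0.05
) -> tuple[Hypergraph, pd.DataFrame]:
    """Shuffle per ``spec`` and re-run the hypergraph pipeline end-to-end."""
    if spec.kind == "overall":
        surrogate = shuffle_overall(ets, spec.seed)
    else:
        surrogate = shuffle_within_task(ets, spec.seed)
    c = edge_edge_correlation(surrogate)
    hg = extract_hyperedges(
        fdr_binarize(c, q=q), subject_id=f"null-{spec.kind}-seed{spec.seed}"
    )
    hg.meta.update({"null_kind": spec.kind, "null_seed": spec.seed})
    return hg, size_distribution([hg])
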
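"""Windowed functional networks and the edge-weight time series matrix.

Each time window yields an N x N matrix of pairwise Pearson correlations
between region signals (the functional network for that window).  Stacking
the windows and reading out every node pair gives the E x W edge-weight
time series matrix, E = N(N-1)/2, whose rows are the objects the hyperedge
analysis correlates with one another.

Edges are indexed canonically: lexicographic over unordered pairs (i, j)
with 0-based nodes and i < j.  Signed weights are kept as-is; no absolute
value or thresholding is applied at this stage, so anti-correlated region
pairs remain distinguishable downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .prep import RegionTimeSeriesRun, WindowingSpec, segment_windows


def edge_pairs(n_nodes: int) -> np.ndarray:
    """Canonical (E, 2) array of unordered node pairs, lexicographic, i < j."""
    iu = np.triu_indices(n_nodes, k=1)
    return np.column_stack(iu).astype(np.int64)


def n_edges(n_nodes: int) -> int:
    return n_nodes * (n_nodes - 1) // 2


@dataclass
class WindowedNetworkSequence:
    """Ordered windowed adjacency matrices with per-window task labels."""

    adjacency: list[np.ndarray]
    window_tasks: list[str]
    node_ids: Optional[list[str]] = None

    def __post_init__(self) -> None:
        if len(self.adjacency) != len(self.window_tasks):
            raise ValueError("one task label per window is required")
        sizes = {a.shape for a in self.adjacency}
        if len(sizes) > 1:
            raise ValueError(f"inconsistent adjacency shapes: {sizes}")

    @property
    def n_nodes(self) -> int:
        return self.adjacency[0].shape[0]

    @property
    def n_windows(self) -> int:
        return len(self.adjacency)


@dataclass
class EdgeTimeSeriesMatrix:
    """E x W matrix of windowed edge weights.

    ``pairs`` maps row e to its unordered node pair; for a full network it
    is ``edge_pairs(n_nodes)``, but a subset of edges is permitted (used by
    the synthetic worked examples).
    """

    weights: np.ndarray       # (E, W)
    pairs: np.ndarray         # (E, 2), i < j
    window_tasks: np.ndarray  # (W,) task label strings
    n_nodes: int

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.pairs = np.asarray(self.pairs, dtype=np.int64)
        self.window_tasks = np.asarray(self.window_tasks)
        if self.weights.ndim != 2:
            raise ValueError("weights must be 2-D (edges x windows)")
        if self.pairs.shape != (self.weights.shape[0], 2):
            raise ValueError("pairs must align with the weight rows")
        if self.window_tasks.shape[0] != self.weights.shape[1]:
            raise ValueError("one task label per window is required")
        if (self.pairs[:, 0] >= self.pairs[:, 1]).any():
            raise ValueError("pairs must satisfy i < j")
        if self.pairs.max(initial=-1) >= self.n_nodes:
            raise ValueError("pair references a node >= n_nodes")

    @property
    def n_edges(self) -> int:
        return self.weights.shape[0]

    @property
    def n_windows(self) -> int:
        return self.weights.shape[1]

    @property
    def tasks(self) -> list[str]:
        """Distinct task labels in first-appearance order."""
        seen: dict[str, None] = {}
        for t in self.window_tasks.tolist():
            seen.setdefault(t, None)
        return list(seen)

    def task_windows(self, task: str) -> np.ndarray:
        return np.flatnonzero(self.window_tasks == task)

    def row_of(self, i: int, j: int) -> int:
        i, j = (i, j) if i < j else (j, i)
        hit = np.flatnonzero((self.pairs[:, 0] == i) & (self.pairs[:, 1] == j))
        if hit.size == 0:
            raise KeyError(f"edge ({i}, {j}) not present")
        return int(hit[0])


def window_adjacency(window: np.ndarray, window_index: Optional[int] = None) -> np.ndarray:
    """Pearson correlation matrix of the rows of one window, diagonal zeroed.

    A constant row has undefined correlations; its entries are set to 0 and
    a warning naming the offending node(s) (and window, if given) is emitted
    rather than aborting a batch.
    """
    x = np.asarray(window, dtype=float)
    if x.ndim != 2 or x.shape[1] < 3:
        raise ValueError("window must be 2-D with >= 3 samples")
    if not np.isfinite(x).all():
        raise ValueError("window contains missing/non-finite values")
    centered = x - x.mean(axis=1, keepdims=True)
    sd = centered.std(axis=1)
    flat = sd == 0
    if flat.any():
        where = f" in window {window_index}" if window_index is not None else ""
        warnings.warn(
            f"constant signal for node(s) {np.flatnonzero(flat).tolist()}{where}; "
            "their correlations are set to 0",
            stacklevel=2,
        )
    safe_sd = np.where(flat, 1.0, sd)
    z = centered / safe_sd[:, None]
    z[flat] = 0.0
    a = (z @ z.T) / x.shape[1]
    np.clip(a, -1.0, 1.0, out=a)
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 0.0)
    return a


def network_sequence(
    runs: Sequence[RegionTimeSeriesRun], spec: WindowingSpec = WindowingSpec()
) -> WindowedNetworkSequence:
    """Window every run (never straddling runs) and correlate each window."""
    adjacency: list[np.ndarray] = []
    tasks: list[str] = []
    n_regions = {r.n_regions for r in runs}
    if len(n_regions) > 1:
        raise ValueError(f"runs disagree on region count: {sorted(n_regions)}")
    for run in runs:
        for k, (win, task) in enumerate(segment_windows(run, spec)):
            adjacency.append(window_adjacency(win, window_index=len(adjacency)))
            tasks.append(task)
    return WindowedNetworkSequence(adjacency=adjacency, window_tasks=tasks)


def edge_time_series(seq: WindowedNetworkSequence) -> EdgeTimeSeriesMatrix:
    """Read the upper triangle of every windowed network into an E x W matrix."""
    if seq.n_windows < 2:
        raise ValueError("need >= 2 windows for an edge time series")
    n = seq.n_nodes
    iu = np.triu_indices(n, k=1)
    weights = np.stack([a[iu] for a in seq.adjacency], axis=1)
    return EdgeTimeSeriesMatrix(
        weights=weights,
        pairs=edge_pairs(n),
        window_tasks=np.asarray(seq.window_tasks),
        n_nodes=n,
    )


def repack_adjacency(ets: EdgeTimeSeriesMatrix) -> list[np.ndarray]:
    """Inverse of :func:`edge_time_series` (off-diagonal entries); full networks only."""
    if ets.n_edges != n_edges(ets.n_nodes):
        raise ValueError("repacking requires a complete edge set")
    out = []
    iu = tuple(ets.pairs.T)
    for w in range(ets.n_windows):
        a = np.zeros((ets.n_nodes, ets.n_nodes))
        a[iu] = ets.weights[:, w]
        a = a + a.T
        out.append(a)
    return out
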
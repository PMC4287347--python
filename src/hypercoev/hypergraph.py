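"""Hyperedge extraction from the edge-edge correlation matrix.

The central object is the E x E matrix X of Pearson correlations between
edge-weight time series.  Entries whose p-values survive a Benjamini-
Hochberg false-discovery-rate correction are set to 1, all others to 0,
producing a binary edge-edge adjacency matrix.  Each connected component
of that matrix with two or more members is a *hyperedge*: a set of network
edges whose weights co-evolve over windows.  Components of size one are
*singletons* and are excluded from further analyses.

Statistical conventions (all echoed in output metadata):

* p-values come from the t transform of r with W - 2 degrees of freedom,
  two-sided by default so strongly anti-correlated edge series also link
  (a one-sided positive alternative is available);
* the BH procedure is applied once per subject over the E(E-1)/2
  upper-triangular p-values;
* correlation sign is discarded after binarization - components are
  computed on the 0/1 matrix alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import sparse, special
from statsmodels.stats.multitest import multipletests

from .dynamics import EdgeTimeSeriesMatrix


@dataclass
class EdgeEdgeCorrelation:
    """Pearson r and p between all pairs of edge-weight series."""

    r: np.ndarray          # (E, E) symmetric, diagonal 1
    p: np.ndarray          # (E, E) symmetric, diagonal 0
    n_windows: int
    pairs: np.ndarray      # carried through for downstream node bookkeeping
    n_nodes: int


@dataclass
class BinarizedEdgeMatrix:
    """Symmetric 0/1 edge-edge adjacency after FDR thresholding."""

    b: np.ndarray
    q: float
    alternative: str
    pairs: np.ndarray
    n_nodes: int


@dataclass
class Hypergraph:
    """Partition of one subject's edges into hyperedges and singletons.

    ``hyperedges`` are frozensets of edge-row indices, each of size >= 2;
    every edge index appears in exactly one hyperedge or in ``singletons``.
    """

    hyperedges: tuple[frozenset[int], ...]
    singletons: frozenset[int]
    pairs: np.ndarray
    n_nodes: int
    subject_id: Optional[str] = None
    meta: dict = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return self.pairs.shape[0]

    def nodes_of(self, hyperedge: Iterable[int]) -> frozenset[int]:
        """Nodes touched by at least one member edge of a hyperedge."""
        out: set[int] = set()
        for e in hyperedge:
            out.update(self.pairs[e].tolist())
        return frozenset(out)

    def membership(self) -> np.ndarray:
        """Per-edge hyperedge index, -1 for singletons."""
        m = np.full(self.n_edges, -1, dtype=np.int64)
        for k, h in enumerate(self.hyperedges):
            m[list(h)] = k
        return m


def _t_sf_two_sided(r: np.ndarray, df: int) -> np.ndarray:
    """Two-sided p for Pearson r via the t transform, vectorized and inf-safe."""
    rr = np.clip(r, -1.0, 1.0)
    denom = np.maximum(1.0 - rr * rr, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = rr * rr * df / np.where(denom == 0.0, np.inf, denom)
    # |r| = 1 => t = inf => p = 0
    p = np.where(denom == 0.0, 0.0, special.betainc(df / 2.0, 0.5, df / np.maximum(df + t2, df)))
    return p


def edge_edge_correlation(
    ets: EdgeTimeSeriesMatrix, block_size: int = 4096
) -> EdgeEdgeCorrelation:
    """Pearson correlation (and t-transform p-value) between all edge rows.

    Computed in row blocks of ``block_size`` against the standardized full
    matrix so the E x E result is streamed rather than formed from
    intermediate E x E temporaries at once.  Constant rows get r = 0,
    p = 1 against every other edge.
    """
    w = ets.n_windows
    if w < 4:
        raise ValueError("need at least 4 windows for edge-edge p-values")
    x = ets.weights
    centered = x - x.mean(axis=1, keepdims=True)
    sd = centered.std(axis=1)
    flat = sd == 0
    z = centered / np.where(flat, 1.0, sd)[:, None]
    z[flat] = 0.0

    e = ets.n_edges
    r = np.empty((e, e), dtype=float)
    for start in range(0, e, block_size):
        stop = min(start + block_size, e)
        r[start:stop] = (z[start:stop] @ z.T) / w
    np.clip(r, -1.0, 1.0, out=r)
    r = (r + r.T) / 2.0

    p = _t_sf_two_sided(r, w - 2)
    if flat.any():
        r[flat, :] = 0.0
        r[:, flat] = 0.0
        p[flat, :] = 1.0
        p[:, flat] = 1.0
    np.fill_diagonal(r, 1.0)
    np.fill_diagonal(p, 0.0)
    return EdgeEdgeCorrelation(r=r, p=p, n_windows=w, pairs=ets.pairs, n_nodes=ets.n_nodes)


def fdr_binarize(
    c: EdgeEdgeCorrelation, q: float = 0.05, alternative: str = "two-sided"
) -> BinarizedEdgeMatrix:
    """Benjamini-Hochberg threshold the upper-triangular p-values, binarize.

    ``alternative="greater"`` converts the stored two-sided p-values into
    one-sided (positive correlation) ones before the BH pass.
    """
    if not (0.0 < q < 1.0):
        raise ValueError(f"FDR level q = {q} outside (0, 1)")
    if alternative not in ("two-sided", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    e = c.r.shape[0]
    iu = np.triu_indices(e, k=1)
    pvec = c.p[iu]
    if alternative == "greater":
        rvec = c.r[iu]
        pvec = np.where(rvec > 0, pvec / 2.0, 1.0 - pvec / 2.0)
    if not np.isfinite(pvec).all():
        raise ValueError("non-finite p-values")
    reject, *_ = multipletests(pvec, alpha=q, method="fdr_bh")
    b = np.zeros((e, e), dtype=np.uint8)
    b[iu] = reject
    b = b + b.T
    return BinarizedEdgeMatrix(b=b, q=q, alternative=alternative, pairs=c.pairs, n_nodes=c.n_nodes)


def extract_hyperedges(
    bm: BinarizedEdgeMatrix, subject_id: Optional[str] = None
) -> Hypergraph:
    """Connected components of the binarized matrix: size >= 2 -> hyperedge."""
    b = bm.b
    if b.shape[0] != b.shape[1] or not np.array_equal(b, b.T):
        raise ValueError("binarized matrix must be square and symmetric")
    n_comp, labels = sparse.csgraph.connected_components(
        sparse.csr_matrix(b), directed=False
    )
    groups: dict[int, list[int]] = {}
    for edge, lab in enumerate(labels.tolist()):
        groups.setdefault(lab, []).append(edge)
    hyperedges = tuple(
        frozenset(members)
        for _, members in sorted(groups.items())
        if len(members) >= 2
    )
    singles = frozenset(
        m for members in groups.values() if len(members) == 1 for m in members
    )
    return Hypergraph(
        hyperedges=hyperedges,
        singletons=singles,
        pairs=bm.pairs,
        n_nodes=bm.n_nodes,
        subject_id=subject_id,
        meta={"q": bm.q, "alternative": bm.alternative, "p_value": "t-transform"},
    )


def hyperedge_size(hyperedge: Iterable[int]) -> int:
    """Number of edges contained in a hyperedge."""
    h = frozenset(hyperedge)
    if not h:
        raise ValueError("empty hyperedge")
    return len(h)


def hyperedge_node_degree(
    hypergraphs: Sequence[Hypergraph], n_nodes: int
) -> np.ndarray:
    """Per-node count of (non-singleton) hyperedges touching the node, summed
    over the supplied hypergraphs."""
    deg = np.zeros(n_nodes, dtype=np.int64)
    for hg in hypergraphs:
        if hg.n_nodes != n_nodes:
            raise ValueError("hypergraphs disagree on node count")
        for h in hg.hyperedges:
            for node in hg.nodes_of(h):
                deg[node] += 1
    return deg


def size_distribution(hypergraphs: Sequence[Hypergraph]) -> pd.DataFrame:
    """Complementary cumulative hyperedge-size counts pooled across hypergraphs.

    Returns a table with one row per observed size s: the number of
    non-singleton hyperedges of size >= s.  Monotone non-increasing in s.
    """
    sizes = sorted(
        hyperedge_size(h) for hg in hypergraphs for h in hg.hyperedges
    )
    if not sizes:
        return pd.DataFrame({"size": pd.Series(dtype=int),
                             "count_at_least": pd.Series(dtype=int)})
    arr = np.asarray(sizes)
    uniq = np.unique(arr)
    counts = [(arr >= s).sum() for s in uniq]
    return pd.DataFrame({"size": uniq, "count_at_least": counts})
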
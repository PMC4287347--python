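"""Ensemble aggregation: the co-evolution probability network.

Over an ensemble of hypergraphs (typically one per subject), the
co-evolution network P records, for every node pair (i, j), the fraction
of hypergraphs in which the edge (i, j) belongs to a non-singleton
hyperedge.  Because hyperedges partition edges, an edge is in at most one
hyperedge per hypergraph, so the fraction is a probability.  Downstream
metrics use the P entry verbatim as the connection "strength".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .hypergraph import Hypergraph


@dataclass
class CoevolutionNetwork:
    P: np.ndarray          # (N, N) symmetric, entries in [0, 1], diagonal 0
    n_hypergraphs: int
    label: str = "all"

    @property
    def n_nodes(self) -> int:
        return self.P.shape[0]


def coevolution_matrix(
    hypergraphs: Sequence[Hypergraph], n_nodes: int, label: str = "all"
) -> CoevolutionNetwork:
    """P(i, j) = fraction of hypergraphs whose edge (i, j) is in a hyperedge."""
    if not hypergraphs:
        raise ValueError("need at least one hypergraph")
    counts = np.zeros((n_nodes, n_nodes), dtype=float)
    for hg in hypergraphs:
        if hg.n_nodes != n_nodes:
            raise ValueError("hypergraphs disagree on node count")
        member = np.zeros(hg.n_edges, dtype=bool)
        for h in hg.hyperedges:
            member[list(h)] = True
        rows = hg.pairs[member]
        counts[rows[:, 0], rows[:, 1]] += 1.0
    p = counts / len(hypergraphs)
    p = p + p.T
    np.fill_diagonal(p, 0.0)
    return CoevolutionNetwork(P=p, n_hypergraphs=len(hypergraphs), label=label)


def threshold_bands(
    net: CoevolutionNetwork, top_fraction: float = 0.01, n_bands: int = 5
) -> pd.DataFrame:
    """Rank node pairs by P and keep the top fraction, split into bands.

    With the defaults this reproduces the display convention of showing the
    top 1% of co-evolution probabilities in five 0.2% bands (band 0 is the
    strongest).  Ties are broken by canonical edge order, so the banding is
    deterministic.
    """
    if not (0.0 < top_fraction <= 1.0):
        raise ValueError("top_fraction must be in (0, 1]")
    if n_bands < 1:
        raise ValueError("n_bands must be >= 1")
    n = net.n_nodes
    iu = np.triu_indices(n, k=1)
    strengths = net.P[iu]
    order = np.lexsort((iu[1], iu[0], -strengths))
    n_keep = int(round(top_fraction * strengths.size))
    n_nonzero = int((strengths > 0).sum())
    if n_nonzero < n_keep:
        warnings.warn(
            f"only {n_nonzero} nonzero co-evolution entries for a requested "
            f"top fraction of {n_keep}; returning all nonzero entries",
            stacklevel=2,
        )
        n_keep = n_nonzero
    kept = order[:n_keep]
    band_of = np.concatenate(
        [np.full(chunk.size, b, dtype=int)
         for b, chunk in enumerate(np.array_split(np.arange(n_keep), n_bands))]
    ) if n_keep else np.array([], dtype=int)
    return pd.DataFrame({
        "i": iu[0][kept],
        "j": iu[1][kept],
        "strength": strengths[kept],
        "band": band_of,
    })
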
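"""Spatial organization metrics of co-evolution networks.

Two summary statistics relate connection strength (the co-evolution
probability P(i, j)) to node geometry, over *all* upper-triangular node
pairs of the full unthresholded network:

* length-strength: Pearson R between strength and the Euclidean distance
  between the two node centroids;
* position-strength: Pearson R between strength and the mean
  anterior-posterior (y) coordinate of the two nodes (anterior positive,
  so a negative R means strong connections sit posterior).

Significance comes from permuting the strength values across connections;
between-network differences from a connection-wise paired swap null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .coevolution import CoevolutionNetwork

LENGTH_STRENGTH = "length-strength"
POSITION_STRENGTH = "position-strength"


@dataclass
class NodeGeometry:
    """Node centroids: columns x (left-right), y (anterior-posterior,
    anterior positive), z (inferior-superior); one row per node."""

    coords: np.ndarray  # (N, 3)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n_nodes, 3)")
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates must be finite")

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "NodeGeometry":
        return cls(df[["x", "y", "z"]].to_numpy(dtype=float))


@dataclass
class MetricResult:
    metric: str
    R: float
    p: Optional[float] = None
    label: str = "all"
    defined: bool = True


def connection_length(geom: NodeGeometry, i: int, j: int) -> float:
    """Euclidean distance between the centroids of nodes i and j."""
    d = geom.coords[i] - geom.coords[j]
    return float(math.sqrt(float(d @ d)))


def _features(net: CoevolutionNetwork, geom: NodeGeometry, metric: str):
    if geom.n_nodes != net.n_nodes:
        raise ValueError("geometry and network disagree on node count")
    iu = np.triu_indices(net.n_nodes, k=1)
    strength = net.P[iu]
    if metric == LENGTH_STRENGTH:
        diff = geom.coords[iu[0]] - geom.coords[iu[1]]
        feature = np.sqrt((diff * diff).sum(axis=1))
    elif metric == POSITION_STRENGTH:
        y = geom.coords[:, 1]
        feature = (y[iu[0]] + y[iu[1]]) / 2.0
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return strength, feature


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.corrcoef(a, b)[0, 1])


def _metric_result(net, geom, metric) -> MetricResult:
    strength, feature = _features(net, geom, metric)
    if strength.size < 3 or strength.std() == 0 or feature.std() == 0:
        return MetricResult(metric=metric, R=float("nan"), label=net.label,
                            defined=False)
    return MetricResult(metric=metric, R=_pearson(strength, feature),
                        label=net.label)


def length_strength(net: CoevolutionNetwork, geom: NodeGeometry) -> MetricResult:
    """R between connection strength and inter-centroid distance.

    Degenerate inputs (constant strengths or lengths, or fewer than three
    connections) yield an undefined-result marker (``defined=False``)
    rather than a number.
    """
    return _metric_result(net, geom, LENGTH_STRENGTH)


def position_strength(net: CoevolutionNetwork, geom: NodeGeometry) -> MetricResult:
    """R between connection strength and mean anterior-posterior position."""
    return _metric_result(net, geom, POSITION_STRENGTH)


def metric_significance(
    net: CoevolutionNetwork,
    geom: NodeGeometry,
    metric: str = LENGTH_STRENGTH,
    n_permutations: int = 1000,
    seed: int = 0,
) -> MetricResult:
    """Two-sided permutation p for a spatial metric.

    The null redistributes the observed strengths uniformly over the
    connections; p = (1 + #{|R_null| >= |R_obs|}) / (1 + n_permutations).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    result = _metric_result(net, geom, metric)
    if not result.defined:
        return result
    strength, feature = _features(net, geom, metric)
    rng = np.random.default_rng(seed)
    hits = 0
    obs = abs(result.R)
    for _ in range(n_permutations):
        r_null = _pearson(rng.permutation(strength), feature)
        if abs(r_null) >= obs:
            hits += 1
    result.p = (1.0 + hits) / (1.0 + n_permutations)
    return result


def pairwise_task_comparison(
    net_a: CoevolutionNetwork,
    net_b: CoevolutionNetwork,
    geom: NodeGeometry,
    metric: str = LENGTH_STRENGTH,
    n_permutations: int = 1000,
    seed: int = 0,
) -> float:
    """Permutation p for |R_a - R_b| between two task networks.

    The null swaps the two networks' strength values connection-wise with
    probability 1/2 per connection, preserving each connection's geometry
    while destroying the task identity of its strengths.  The caller is
    responsible for the Bonferroni correction over all task pairs and
    metrics (alpha / 12 for four tasks and two metrics).
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if net_a.n_nodes != net_b.n_nodes or geom.n_nodes != net_a.n_nodes:
        raise ValueError("networks/geometry disagree on node count")
    s_a, feature = _features(net_a, geom, metric)
    s_b, _ = _features(net_b, geom, metric)
    observed = abs(_pearson(s_a, feature) - _pearson(s_b, feature))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        swap = rng.random(s_a.size) < 0.5
        x = np.where(swap, s_b, s_a)
        y = np.where(swap, s_a, s_b)
        if abs(_pearson(x, feature) - _pearson(y, feature)) >= observed:
            hits += 1
    return (1.0 + hits) / (1.0 + n_permutations)
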
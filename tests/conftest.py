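import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from hypercoev.dynamics import EdgeTimeSeriesMatrix, edge_pairs
from hypercoev.synthetic import PlantedDesign, PlantedGroup, TaskBlock


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def small_ets(rng):
    """10-node, 16-window random edge series over two tasks."""
    n = 10
    pairs = edge_pairs(n)
    tasks = np.asarray(["a"] * 8 + ["b"] * 8)
    weights = np.tanh(0.4 * rng.standard_normal((pairs.shape[0], 16)))
    return EdgeTimeSeriesMatrix(weights=weights, pairs=pairs,
                                window_tasks=tasks, n_nodes=n)


@pytest.fixture
def two_task_design():
    return PlantedDesign(
        n_nodes=8,
        tasks=(TaskBlock("a", 2.0, 10), TaskBlock("b", 2.5, 10)),
        groups=(PlantedGroup(edges=((0, 1), (2, 3), (4, 5)), amplitude=0.9),),
        noise_sd=0.2,
        seed=7,
    )


def brute_pearson(x, y):
    """Two-pass textbook Pearson, the oracle for all correlation code."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xm = x - x.mean()
    ym = y - y.mean()
    denom = np.sqrt((xm * xm).sum()) * np.sqrt((ym * ym).sum())
    return float((xm * ym).sum() / denom)


def brute_bh(pvals, q):
    """Sort-and-scan Benjamini-Hochberg: returns a boolean reject mask."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    below = sorted_p <= q * (np.arange(1, m + 1) / m)
    reject = np.zeros(m, dtype=bool)
    if below.any():
        k = int(np.flatnonzero(below).max())
        reject[order[: k + 1]] = True
    return reject


def brute_components(adj):
    """Connected components via boolean transitive closure (matrix powers)."""
    a = np.asarray(adj, dtype=bool) | np.eye(adj.shape[0], dtype=bool)
    reach = a.copy()
    while True:
        nxt = reach | (reach @ reach)
        if (nxt == reach).all():
            break
        reach = nxt
    labels = -np.ones(adj.shape[0], dtype=int)
    lab = 0
    for v in range(adj.shape[0]):
        if labels[v] < 0:
            labels[reach[v]] = lab
            lab += 1
    return labels
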
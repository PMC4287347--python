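"""Planted-structure benchmarks of the full pipeline.

These functions bundle the synthetic study conditions used throughout the
test suite and the reproduction script: a four-task ladder mimicking the
study design (rest and attention at TR 2 s, two memory tasks at TR 2.5 s,
eight 60-s windows each, 32 windows total), three planted groups of three
disjoint edges on 30 nodes, and the scoring rules for recovery, null
soundness, and task labelling.  Each benchmark takes a base seed and is
fully deterministic.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .coevolution import CoevolutionNetwork
from .dynamics import EdgeTimeSeriesMatrix
from .hypergraph import (
    Hypergraph,
    edge_edge_correlation,
    extract_hyperedges,
    fdr_binarize,
)
from .nulls import NullSpec, run_null
from .spatial import NodeGeometry
from .synthetic import (
    GroundTruth,
    PlantedDesign,
    PlantedGroup,
    TaskBlock,
    generate_edge_level,
)
from .taskspec import classify

DEFAULT_TASKS = (
    TaskBlock("rest", 2.0, 8),
    TaskBlock("attention", 2.0, 8),
    TaskBlock("word", 2.5, 8),
    TaskBlock("face", 2.5, 8),
)

# three groups of three disjoint node pairs on 30 nodes
_GROUP_EDGES = (
    ((0, 1), (2, 3), (4, 5)),
    ((6, 7), (8, 9), (10, 11)),
    ((12, 13), (14, 15), (16, 17)),
)


def recovery_design(
    seed: int, amplitude: float = 0.9, noise_sd: float = 0.2, n_nodes: int = 30
) -> PlantedDesign:
    """Always-active planted groups (the single-hyperedge recovery setting)."""
    groups = tuple(PlantedGroup(edges=e, amplitude=amplitude) for e in _GROUP_EDGES)
    return PlantedDesign(n_nodes=n_nodes, tasks=DEFAULT_TASKS,
                         groups=groups, noise_sd=noise_sd, seed=seed)


def null_design(seed: int, noise_sd: float = 0.2, n_nodes: int = 30) -> PlantedDesign:
    """All amplitudes zero: pure noise, nothing to recover."""
    groups = tuple(PlantedGroup(edges=e, amplitude=0.0) for e in _GROUP_EDGES)
    return PlantedDesign(n_nodes=n_nodes, tasks=DEFAULT_TASKS,
                         groups=groups, noise_sd=noise_sd, seed=seed)


def task_restricted_design(
    seed: int,
    amplitude: float = 0.9,
    noise_sd: float = 0.2,
    n_nodes: int = 30,
    windows_per_task: int = 16,
) -> PlantedDesign:
    """One task-confined group per task (rest, attention, word).

    A task-confined signal occupies only a quarter of the windows, so this
    benchmark uses longer runs (16 windows per task by default) to give the
    edge-edge correlation the sample size that dilution demands.
    """
    tasks = tuple(TaskBlock(t.name, t.sampling_period, windows_per_task)
                  for t in DEFAULT_TASKS)
    groups = tuple(
        PlantedGroup(edges=e, amplitude=amplitude, task=tasks[k].name)
        for k, e in enumerate(_GROUP_EDGES)
    )
    return PlantedDesign(n_nodes=n_nodes, tasks=tasks,
                         groups=groups, noise_sd=noise_sd, seed=seed)


def ladder_design(seed: int, n_nodes: int = 30, noise_sd: float = 0.2) -> PlantedDesign:
    """Between-task level-shift groups plus within-task transient groups.

    The three level groups carry mutually orthogonal per-task mean
    patterns (so they do not cross-link) and no shared trajectory; their
    co-evolution is purely a between-task contrast and survives the
    within-task null.  The three transient groups co-evolve only inside
    one task and are destroyed by any shuffling of that task's windows.
    """
    lvl = 0.8
    level_groups = (
        PlantedGroup(edges=_GROUP_EDGES[0], amplitude=0.0,
                     task_levels={"rest": lvl, "attention": -lvl}),
        PlantedGroup(edges=_GROUP_EDGES[1], amplitude=0.0,
                     task_levels={"word": lvl, "face": -lvl}),
        PlantedGroup(edges=_GROUP_EDGES[2], amplitude=0.0,
                     task_levels={"rest": lvl, "attention": lvl,
                                  "word": -lvl, "face": -lvl}),
    )
    transient_edges = (
        ((18, 19), (20, 21), (22, 23)),
        ((24, 25), (26, 27), (28, 29)),
        ((0, 2), (4, 6), (8, 10)),
    )
    transient_groups = tuple(
        PlantedGroup(edges=e, amplitude=1.0, task=DEFAULT_TASKS[k].name)
        for k, e in enumerate(transient_edges)
    )
    return PlantedDesign(n_nodes=n_nodes, tasks=DEFAULT_TASKS,
                         groups=level_groups + transient_groups,
                         noise_sd=noise_sd, seed=seed)


def pipeline_hypergraph(ets: EdgeTimeSeriesMatrix, q: float = 0.05) -> Hypergraph:
    """Edge-edge correlation -> BH binarization -> connected components."""
    return extract_hyperedges(fdr_binarize(edge_edge_correlation(ets), q=q))


def n_non_singleton(hg: Hypergraph) -> int:
    return len(hg.hyperedges)


def groups_recovered(hg: Hypergraph, truth: GroundTruth) -> bool:
    """Each planted group inside one hyperedge; no hyperedge spans two groups."""
    membership = hg.membership()
    homes = []
    for rows in truth.member_rows:
        containers = set(membership[rows].tolist())
        if len(containers) != 1 or -1 in containers:
            return False
        homes.append(containers.pop())
    return len(set(homes)) == len(homes)


def fig2_instance(seed: int = 0, n_windows: int = 20, q: float = 0.05):
    """Zero-noise four-edge worked example: three co-evolving edges on six
    nodes plus one independent edge.

    Returns (hypergraph, truth); the expected outcome is exactly one
    hyperedge of size 3 spanning 6 nodes and one singleton.
    """
    design = PlantedDesign(
        n_nodes=8,
        tasks=(TaskBlock("demo", 2.0, n_windows),),
        groups=(PlantedGroup(edges=((0, 1), (2, 3), (4, 5)), amplitude=1.0),),
        noise_sd=0.0,
        seed=seed,
    )
    ets, truth = generate_edge_level(
        design, edges=[(0, 1), (2, 3), (4, 5), (6, 7)]
    )
    return pipeline_hypergraph(ets, q=q), truth


def null_overall_zero_rate(
    n_seeds: int = 50, base_seed: int = 0, q: float = 0.05
) -> float:
    """Fraction of seeds where the overall null on planted dynamic data
    yields zero non-singleton hyperedges."""
    zero = 0
    for k in range(n_seeds):
        ets, _ = generate_edge_level(recovery_design(base_seed + k))
        hg, _ = run_null(ets, NullSpec(kind="overall", seed=base_seed + 10_000 + k), q=q)
        zero += n_non_singleton(hg) == 0
    return zero / n_seeds


def null_soundness_rate(
    n_seeds: int = 50, base_seed: int = 0, q: float = 0.05
) -> float:
    """Fraction of all-amplitude-zero seeds with zero non-singleton hyperedges."""
    zero = 0
    for k in range(n_seeds):
        ets, _ = generate_edge_level(null_design(base_seed + k))
        zero += n_non_singleton(pipeline_hypergraph(ets, q=q)) == 0
    return zero / n_seeds


def recovery_rate(
    n_seeds: int = 50, base_seed: int = 0, q: float = 0.05
) -> float:
    """Fraction of seeds where every planted group is recovered as a single
    hyperedge with no cross-group merging."""
    ok = 0
    for k in range(n_seeds):
        ets, truth = generate_edge_level(recovery_design(base_seed + k))
        ok += groups_recovered(pipeline_hypergraph(ets, q=q), truth)
    return ok / n_seeds


def task_label_rate(
    n_seeds: int = 50,
    base_seed: int = 0,
    q: float = 0.05,
    alpha: float = 0.05,
    n_permutations: int = 1000,
) -> float:
    """Fraction of seeds where each task-restricted planted group is
    recovered and its hyperedge labelled with the correct task."""
    ok = 0
    for k in range(n_seeds):
        design = task_restricted_design(base_seed + k)
        ets, truth = generate_edge_level(design)
        hg = pipeline_hypergraph(ets, q=q)
        result = classify(hg, ets, alpha=alpha,
                          n_permutations=n_permutations, seed=base_seed + k)
        good = True
        for g_idx, rows in enumerate(truth.member_rows):
            expected_task = design.groups[g_idx].task
            containers = {
                h_idx for h_idx, h in enumerate(hg.hyperedges)
                if set(rows) <= h
            }
            if len(containers) != 1:
                good = False
                break
            if result.labels[containers.pop()] != expected_task:
                good = False
                break
        ok += good
    return ok / n_seeds


def ladder_medians(
    n_seeds: int = 50, base_seed: int = 0, q: float = 0.05
) -> dict[str, float]:
    """Median non-singleton counts: original vs within-task vs overall null."""
    orig, within, overall = [], [], []
    for k in range(n_seeds):
        ets, _ = generate_edge_level(ladder_design(base_seed + k))
        orig.append(n_non_singleton(pipeline_hypergraph(ets, q=q)))
        hg_w, _ = run_null(ets, NullSpec("within-task", base_seed + 20_000 + k), q=q)
        within.append(n_non_singleton(hg_w))
        hg_o, _ = run_null(ets, NullSpec("overall", base_seed + 30_000 + k), q=q)
        overall.append(n_non_singleton(hg_o))
    return {
        "original": float(np.median(orig)),
        "within_task": float(np.median(within)),
        "overall": float(np.median(overall)),
    }


def planted_spatial_network(
    seed: int = 0, n_nodes: int = 60, length_scale: float = 40.0
) -> tuple[CoevolutionNetwork, NodeGeometry]:
    """Co-evolution strengths decaying with distance and concentrating at
    posterior (negative-y) nodes, on random centroids in a 140 mm box."""
    rng = np.random.default_rng(seed)
    coords = rng.uniform(-70.0, 70.0, size=(n_nodes, 3))
    geom = NodeGeometry(coords)
    iu = np.triu_indices(n_nodes, k=1)
    diff = coords[iu[0]] - coords[iu[1]]
    dist = np.sqrt((diff * diff).sum(axis=1))
    ybar = (coords[iu[0], 1] + coords[iu[1], 1]) / 2.0
    strength = np.exp(-dist / length_scale) * np.exp(-(ybar + 70.0) / 70.0)
    p = np.zeros((n_nodes, n_nodes))
    p[iu] = strength
    p = p + p.T
    return CoevolutionNetwork(P=p, n_hypergraphs=1, label="planted"), geom
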
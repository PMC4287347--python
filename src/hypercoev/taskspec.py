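"""Task-specific classification of hyperedges.

A hyperedge's within-task statistic is the mean, over all unordered pairs
of its member edges, of the Pearson correlation between their weight
series restricted to that task's windows.  The permutation null re-draws a
window set of the same size from the other tasks' windows (without
replacement) and recomputes the statistic; the test is one-sided (observed
greater than null) because the question is whether co-evolution is
*elevated* within the task.

A Bonferroni correction over all (hyperedge, task) tests of one subject
controls the family-wise rate.  A hyperedge significant in exactly one
task is labelled with that task; one significant in two or more tasks is
excluded from all task-specific hypergraphs ("multi-task"); the remainder
are unlabelled ("none").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dynamics import EdgeTimeSeriesMatrix
from .hypergraph import Hypergraph

MULTI_TASK = "multi-task"
UNCLASSIFIED = "none"


def _pairwise_mean_corr(x: np.ndarray) -> float:
    """Mean Pearson correlation over all unordered row pairs of ``x``.

    Constant rows contribute 0 correlation with every other row.
    """
    k, w = x.shape
    centered = x - x.mean(axis=1, keepdims=True)
    sd = centered.std(axis=1)
    flat = sd == 0
    z = centered / np.where(flat, 1.0, sd)[:, None]
    z[flat] = 0.0
    c = (z @ z.T) / w
    iu = np.triu_indices(k, k=1)
    return float(np.clip(c[iu], -1.0, 1.0).mean())


def _pairwise_mean_corr_batch(x: np.ndarray) -> np.ndarray:
    """Vectorized :func:`_pairwise_mean_corr` over a (k, B, w) stack."""
    k, b, w = x.shape
    centered = x - x.mean(axis=2, keepdims=True)
    sd = centered.std(axis=2)
    flat = sd == 0
    z = centered / np.where(flat, 1.0, sd)[:, :, None]
    z[flat] = 0.0
    c = np.einsum("ibw,jbw->bij", z, z) / w
    iu = np.triu_indices(k, k=1)
    return np.clip(c[:, iu[0], iu[1]], -1.0, 1.0).mean(axis=1)


def within_task_statistic(
    hyperedge: Sequence[int] | frozenset[int],
    ets: EdgeTimeSeriesMatrix,
    task: str,
) -> float:
    """Average within-task edge-edge correlation of a hyperedge."""
    members = sorted(hyperedge)
    if len(members) < 2:
        raise ValueError("hyperedge must contain >= 2 edges")
    cols = ets.task_windows(task)
    if cols.size < 4:
        raise ValueError(f"task {task!r} has fewer than 4 windows")
    return _pairwise_mean_corr(ets.weights[np.ix_(members, cols)])


def task_permutation_test(
    hyperedge: Sequence[int] | frozenset[int],
    ets: EdgeTimeSeriesMatrix,
    task: str,
    n_permutations: int = 1000,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[float, float]:
    """One-sided permutation p-value for within-task elevation.

    Returns (observed statistic, p).  p uses the add-one rule
    ``(1 + #{null >= observed}) / (1 + n_permutations)`` so it is never 0.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    members = sorted(hyperedge)
    cols = ets.task_windows(task)
    pool = np.flatnonzero(ets.window_tasks != task)
    k = cols.size
    if pool.size < k:
        raise ValueError(
            f"other tasks provide only {pool.size} windows; {k} needed"
        )
    observed = within_task_statistic(members, ets, task)
    rng = np.random.default_rng(seed)
    # each row of `draws`: a without-replacement sample of k pool indices
    keys = rng.random((n_permutations, pool.size))
    draws = pool[np.argsort(keys, axis=1)[:, :k]]
    null_stack = ets.weights[np.asarray(members)[:, None, None], draws[None, :, :]]
    null = _pairwise_mean_corr_batch(null_stack)
    p = (1.0 + float((null >= observed).sum())) / (1.0 + n_permutations)
    return observed, p


@dataclass
class TaskSpecificityResult:
    """Per-(hyperedge, task) statistics and the resulting hyperedge labels."""

    table: pd.DataFrame                 # hyperedge, task, statistic, p, significant
    labels: dict[int, str]              # hyperedge index -> task | multi-task | none
    task_hypergraphs: dict[str, Hypergraph]
    alpha: float
    n_permutations: int
    n_tests: int

    @property
    def threshold(self) -> float:
        return self.alpha / self.n_tests


def classify(
    hypergraph: Hypergraph,
    ets: EdgeTimeSeriesMatrix,
    tasks: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
    n_permutations: int = 1000,
    seed: int = 0,
) -> TaskSpecificityResult:
    """Label every hyperedge task-specific, multi-task, or unclassified.

    The Bonferroni denominator is (number of non-singleton hyperedges) x
    (number of tasks).  Each (hyperedge, task) test draws its permutations
    from an independent stream spawned from ``seed``, so results do not
    depend on evaluation order.
    """
    task_list = list(tasks) if tasks is not None else ets.tasks
    if len(task_list) < 2:
        raise ValueError("need >= 2 tasks to classify")
    hyperedges = hypergraph.hyperedges
    n_tests = max(len(hyperedges) * len(task_list), 1)
    threshold = alpha / n_tests
    streams = np.random.SeedSequence(seed).spawn(len(hyperedges) * len(task_list))

    rows = []
    labels: dict[int, str] = {}
    for h_idx, h in enumerate(hyperedges):
        significant: list[str] = []
        for t_idx, task in enumerate(task_list):
            stream = streams[h_idx * len(task_list) + t_idx]
            stat, p = task_permutation_test(
                h, ets, task, n_permutations=n_permutations, seed=stream
            )
            hit = p < threshold
            if hit:
                significant.append(task)
            rows.append({
                "hyperedge": h_idx, "task": task,
                "statistic": stat, "p": p, "significant": hit,
            })
        if len(significant) == 1:
            labels[h_idx] = significant[0]
        elif len(significant) >= 2:
            labels[h_idx] = MULTI_TASK
        else:
            labels[h_idx] = UNCLASSIFIED

    all_edges = frozenset(range(hypergraph.n_edges))
    task_hgs: dict[str, Hypergraph] = {}
    for task in task_list:
        selected = tuple(
            h for h_idx, h in enumerate(hyperedges) if labels[h_idx] == task
        )
        members = frozenset().union(*selected) if selected else frozenset()
        task_hgs[task] = Hypergraph(
            hyperedges=selected,
            singletons=all_edges - members,
            pairs=hypergraph.pairs,
            n_nodes=hypergraph.n_nodes,
            subject_id=hypergraph.subject_id,
            meta={**hypergraph.meta, "task_specific": task,
                  "alpha": alpha, "n_tests": n_tests,
                  "n_permutations": n_permutations, "seed": seed},
        )

    return TaskSpecificityResult(
        table=pd.DataFrame(rows),
        labels=labels,
        task_hypergraphs=task_hgs,
        alpha=alpha,
        n_permutations=n_permutations,
        n_tests=n_tests,
    )
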
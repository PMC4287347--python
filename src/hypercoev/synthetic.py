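"""Synthetic multi-task data with planted edge co-evolution.

The generators produce the two kinds of input the pipeline consumes, with
known ground truth so recovery can be scored:

* *edge level*: an E x W matrix of windowed edge weights in which the
  member edges of each planted group share a latent window trajectory
  (scaled by the group amplitude) plus independent noise.  Optionally the
  shared trajectory is confined to one task's windows, and/or the group
  carries per-task mean levels so its edges sit high in one task and low
  in another.
* *region level*: per-task region x sample time series in which the two
  nodes of each planted member edge share a band-limited carrier signal
  whose mixing weight follows the group trajectory, so windowed Pearson
  edge weights inherit the planted co-evolution after filtering.

Latent trajectories are smooth random walks squashed through tanh into
[-1, 1], giving slowly varying edge weights.  All generators are
deterministic given the design seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .dynamics import EdgeTimeSeriesMatrix, edge_pairs
from .prep import RegionTimeSeriesRun

# Walk sd multiplier before the tanh squash; spreads trajectories over
# [-1, 1] (sd of tanh(1.5 z) ~ 0.8 for a standardized walk).
SQUASH_GAIN = 1.5

# Mean-reversion coefficient of the latent walk.  A pure random walk is so
# smooth that two independent trajectories of a few dozen windows often
# correlate spuriously; the AR(1) pull-back keeps trajectories slowly
# varying while making independent groups statistically separable.
AR_COEF = 0.6

# Carrier band for region-level signals, inside the analysis passband.
CARRIER_BAND = (0.065, 0.12)


@dataclass(frozen=True)
class TaskBlock:
    """One task run: name, sampling period (s), number of windows."""

    name: str
    sampling_period: float
    n_windows: int


@dataclass(frozen=True)
class PlantedGroup:
    """A set of node pairs sharing one latent co-evolution trajectory.

    ``amplitude`` in [0, 1] scales the shared trajectory; ``task`` (if
    given) confines it to that task's windows; ``task_levels`` adds a
    constant per-task mean offset to every member edge, creating
    between-task weight contrasts that survive within-task shuffling.
    """

    edges: tuple[tuple[int, int], ...]
    amplitude: float
    task: Optional[str] = None
    task_levels: Optional[Mapping[str, float]] = None

    def __post_init__(self) -> None:
        norm = tuple(tuple(sorted(e)) for e in self.edges)
        object.__setattr__(self, "edges", norm)
        if not self.edges:
            raise ValueError("a planted group needs >= 1 edge")
        if len(set(self.edges)) != len(self.edges):
            raise ValueError("duplicate edges in planted group")
        for i, j in self.edges:
            if i == j:
                raise ValueError(f"self-pair ({i}, {j}) is not an edge")
        if not (0.0 <= self.amplitude <= 1.0):
            raise ValueError(f"amplitude {self.amplitude} outside [0, 1]")


@dataclass(frozen=True)
class PlantedDesign:
    n_nodes: int
    tasks: tuple[TaskBlock, ...]
    groups: tuple[PlantedGroup, ...]
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "tasks", tuple(self.tasks))
        object.__setattr__(self, "groups", tuple(self.groups))
        if self.n_nodes < 2:
            raise ValueError("need >= 2 nodes")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        names = [t.name for t in self.tasks]
        for t in self.tasks:
            if t.n_windows < 2:
                raise ValueError(f"task {t.name!r} needs >= 2 windows")
            if t.sampling_period <= 0:
                raise ValueError("sampling periods must be positive")
        for g in self.groups:
            for i, j in g.edges:
                if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes):
                    raise ValueError(
                        f"group edge ({i}, {j}) references a node >= {self.n_nodes}"
                    )
            if g.task is not None and g.task not in names:
                raise ValueError(f"group restricted to unknown task {g.task!r}")
            if g.task_levels:
                unknown = set(g.task_levels) - set(names)
                if unknown:
                    raise ValueError(f"task_levels name unknown tasks {unknown}")

    @property
    def n_windows(self) -> int:
        return sum(t.n_windows for t in self.tasks)

    @property
    def window_tasks(self) -> np.ndarray:
        return np.asarray(
            [t.name for t in self.tasks for _ in range(t.n_windows)]
        )


@dataclass
class GroundTruth:
    """Planted structure: per group, the member edge rows and latent path."""

    member_rows: list[list[int]]
    latents: list[np.ndarray]        # per group, over its active windows
    active_windows: list[np.ndarray]
    window_tasks: np.ndarray


def _latent_trajectory(rng: np.random.Generator, n: int) -> np.ndarray:
    """Smooth mean-reverting walk, standardized then squashed into [-1, 1]."""
    eps = rng.standard_normal(n)
    walk = np.empty(n)
    walk[0] = eps[0] / np.sqrt(1.0 - AR_COEF ** 2)
    for t in range(1, n):
        walk[t] = AR_COEF * walk[t - 1] + eps[t]
    walk -= walk.mean()
    sd = walk.std()
    if sd > 0:
        walk /= sd
    return np.tanh(SQUASH_GAIN * walk)


def generate_edge_level(
    design: PlantedDesign,
    edges: Optional[Sequence[tuple[int, int]]] = None,
) -> tuple[EdgeTimeSeriesMatrix, GroundTruth]:
    """Edge-weight matrix with planted co-evolving groups.

    ``edges`` restricts the matrix to an explicit edge list (canonical
    order preserved as given); by default all N(N-1)/2 pairs are emitted
    in lexicographic order.  Member rows are
    ``tanh(level + amplitude * latent + noise_sd * eps)``; non-member rows
    and inactive windows are independent noise through the same squash, so
    every weight stays in (-1, 1).
    """
    if edges is None:
        pairs = edge_pairs(design.n_nodes)
    else:
        pairs = np.asarray([tuple(sorted(e)) for e in edges], dtype=np.int64)
    row_of = {tuple(p): k for k, p in enumerate(pairs.tolist())}
    window_tasks = design.window_tasks
    w = window_tasks.size
    ss = np.random.SeedSequence(design.seed)
    noise_ss, *group_ss = ss.spawn(1 + len(design.groups))
    raw = design.noise_sd * np.random.default_rng(noise_ss).standard_normal(
        (pairs.shape[0], w)
    )

    truth = GroundTruth([], [], [], window_tasks)
    for g, gss in zip(design.groups, group_ss):
        rng = np.random.default_rng(gss)
        active = (
            np.flatnonzero(window_tasks == g.task)
            if g.task is not None else np.arange(w)
        )
        latent = _latent_trajectory(rng, active.size)
        rows = []
        for e in g.edges:
            if e not in row_of:
                raise ValueError(f"group edge {e} missing from the edge list")
            rows.append(row_of[e])
        for r in rows:
            raw[r, active] += g.amplitude * latent
            if g.task_levels:
                for task, level in g.task_levels.items():
                    raw[r, window_tasks == task] += level
        truth.member_rows.append(rows)
        truth.latents.append(latent)
        truth.active_windows.append(active)

    ets = EdgeTimeSeriesMatrix(
        weights=np.tanh(raw),
        pairs=pairs,
        window_tasks=window_tasks,
        n_nodes=design.n_nodes,
    )
    return ets, truth


def _bandlimited(rng: np.random.Generator, n: int, dt: float, k: int = 16) -> np.ndarray:
    """Unit-sd random signal with power confined to the carrier band."""
    t = np.arange(n) * dt
    freqs = rng.uniform(*CARRIER_BAND, size=k)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=k)
    x = np.cos(2.0 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]).sum(axis=0)
    x -= x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_region_level(
    design: PlantedDesign,
    window_seconds: float = 60.0,
    mean_fd: float = 0.1,
    subject_id: str = "sim",
) -> tuple[list[RegionTimeSeriesRun], GroundTruth]:
    """Per-task region time series realizing the planted design.

    Within each window, the two nodes of a planted member edge share a
    band-limited carrier scaled by ``amplitude * (1 + latent) / 2`` on top
    of independent baseline noise of sd ``noise_sd``, so the windowed
    Pearson weight of that edge rises and falls with the group trajectory
    (and equals 1 in every active window when ``noise_sd`` is 0).

    Carriers and baselines are drawn independently per window: the
    generator plants *window-level* edge dynamics, and carrying narrowband
    signals across window boundaries would smear temporal autocorrelation
    into every edge-weight series and with it spurious edge-edge
    correlation that has nothing to do with the planted structure.
    """
    ss = np.random.SeedSequence(design.seed)
    base_ss, carrier_ss, fd_ss, *group_ss = ss.spawn(3 + len(design.groups))
    base_rng = np.random.default_rng(base_ss)
    carrier_rng = np.random.default_rng(carrier_ss)
    fd_seeds = fd_ss.generate_state(len(design.tasks))

    window_tasks = design.window_tasks
    w_total = window_tasks.size

    # one trajectory per group over its active windows, shared across tasks
    truth = GroundTruth([], [], [], window_tasks)
    pairs_full = edge_pairs(design.n_nodes)
    row_of = {tuple(p): k for k, p in enumerate(pairs_full.tolist())}
    for g, gss in zip(design.groups, group_ss):
        rng = np.random.default_rng(gss)
        active = (
            np.flatnonzero(window_tasks == g.task)
            if g.task is not None else np.arange(w_total)
        )
        truth.member_rows.append([row_of[e] for e in g.edges])
        truth.latents.append(_latent_trajectory(rng, active.size))
        truth.active_windows.append(active)

    runs: list[RegionTimeSeriesRun] = []
    w_offset = 0
    for t_idx, block in enumerate(design.tasks):
        spw = int(np.floor(window_seconds / block.sampling_period))
        if spw < 3:
            raise ValueError(
                f"window of {spw} samples in task {block.name!r} is too short"
            )
        n = spw * block.n_windows
        data = np.zeros((design.n_nodes, n))
        for local in range(block.n_windows):
            sl = slice(local * spw, (local + 1) * spw)
            for node in range(design.n_nodes):
                data[node, sl] = design.noise_sd * _bandlimited(
                    base_rng, spw, block.sampling_period
                )
        block_windows = np.arange(w_offset, w_offset + block.n_windows)
        for g, latent, active in zip(design.groups, truth.latents,
                                     truth.active_windows):
            # map global active windows into this block, mixing in [0, 1]
            pos = {int(wn): k for k, wn in enumerate(active)}
            for local, wn in enumerate(block_windows):
                if int(wn) not in pos:
                    continue
                mix = g.amplitude * (1.0 + latent[pos[int(wn)]]) / 2.0
                sl = slice(local * spw, (local + 1) * spw)
                for i, j in g.edges:
                    carrier = mix * _bandlimited(
                        carrier_rng, spw, block.sampling_period
                    )
                    data[i, sl] += carrier
                    data[j, sl] += carrier
        fd = generate_fd_trace(n - 1, mean_fd, int(fd_seeds[t_idx]))
        runs.append(RegionTimeSeriesRun(
            subject_id=subject_id, task=block.name,
            sampling_period=block.sampling_period, data=data, fd=fd,
            run_id=f"run{t_idx}",
        ))
        w_offset += block.n_windows
    return runs, truth


def generate_fd_trace(n_samples: int, mean_fd: float, seed: int) -> np.ndarray:
    """Nonnegative framewise-displacement trace with the requested mean."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if mean_fd < 0:
        raise ValueError("mean_fd must be nonnegative")
    if mean_fd == 0:
        return np.zeros(n_samples)
    rng = np.random.default_rng(seed)
    x = np.abs(rng.normal(1.0, 0.35, size=n_samples))
    return x * (mean_fd / x.mean())


def generate_region_size_table(
    n_subjects: int,
    n_regions: int,
    outlier_spec: Optional[Mapping[int, Mapping[str, object]]] = None,
    seed: int = 0,
    base_size: float = 500.0,
    base_cv: float = 0.05,
    children_per_parent: int = 3,
):
    """Two-scale per-subject region-size table for atlas refinement.

    Fine-scale regions ``fine_###`` carry a parent pointer to a
    coarse-scale region; coarse sizes are the sums of their children.
    ``outlier_spec`` maps a fine-region index to one of
    ``{"cv": level}`` (inflate cross-subject variability),
    ``{"small": True}`` (shrink the mean size), or
    ``{"zero_subject": s}`` (no data acquired for subject ``s``).
    """
    import pandas as pd

    if n_subjects < 1 or n_regions < 1:
        raise ValueError("counts must be >= 1")
    spec = dict(outlier_spec or {})
    rng = np.random.default_rng(seed)
    means = base_size * np.exp(rng.normal(0.0, 0.08, size=n_regions))
    cvs = np.full(n_regions, base_cv)
    zero_at = {}
    for idx, rule in spec.items():
        if "cv" in rule:
            cvs[idx] = float(rule["cv"])  # type: ignore[arg-type]
        if rule.get("small"):
            means[idx] = base_size * 0.1
        if "zero_subject" in rule:
            zero_at[idx] = int(rule["zero_subject"])  # type: ignore[arg-type]

    rows = []
    sizes = np.empty((n_regions, n_subjects), dtype=int)
    for r in range(n_regions):
        draw = rng.normal(means[r], cvs[r] * means[r], size=n_subjects)
        draw = np.maximum(np.round(draw), 1).astype(int)
        if r in zero_at:
            draw[zero_at[r]] = 0
        sizes[r] = draw
        parent = f"coarse_{r // children_per_parent:03d}"
        for s in range(n_subjects):
            rows.append({
                "region": f"fine_{r:03d}", "scale": "fine", "parent": parent,
                "subject": f"sub{s:02d}", "voxels": int(draw[s]),
            })
    n_parents = -(-n_regions // children_per_parent)
    for pidx in range(n_parents):
        children = range(pidx * children_per_parent,
                         min((pidx + 1) * children_per_parent, n_regions))
        tot = sizes[list(children)].sum(axis=0)
        for s in range(n_subjects):
            rows.append({
                "region": f"coarse_{pidx:03d}", "scale": "coarse", "parent": None,
                "subject": f"sub{s:02d}", "voxels": int(tot[s]),
            })
    return pd.DataFrame(rows)
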
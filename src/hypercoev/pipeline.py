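"""End-to-end pipeline orchestration with validated, hashable configs.

A :class:`PipelineConfig` (YAML/JSON on disk) fully determines one run:
input (a bundled synthetic design or a manifest of run files), band and
window parameters, FDR level, permutation settings, null models, and one
master seed from which every stage's random stream is spawned.  Re-running
the same config reproduces every output bit-for-bit; each artifact
directory carries a metadata block with the config hash.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import io as hio
from .coevolution import coevolution_matrix, threshold_bands
from .dynamics import edge_time_series, network_sequence
from .hypergraph import (
    edge_edge_correlation,
    extract_hyperedges,
    fdr_binarize,
    hyperedge_node_degree,
    size_distribution,
)
from .nulls import NULL_KINDS, NullSpec, run_null
from .prep import BandpassSpec, WindowingSpec, bandpass, exclude_high_motion
from .spatial import (
    LENGTH_STRENGTH,
    POSITION_STRENGTH,
    NodeGeometry,
    metric_significance,
)
from .synthetic import PlantedDesign, PlantedGroup, TaskBlock, generate_region_level
from .taskspec import classify


class BandConfig(BaseModel):
    low: float = 0.06
    high: float = 0.125
    order: int = 4


class WindowConfig(BaseModel):
    mode: str = "duration"
    seconds: float = 60.0
    points: Optional[int] = None

    def to_spec(self) -> WindowingSpec:
        return WindowingSpec(mode="points" if self.mode == "points" else "duration",
                             window_seconds=self.seconds, window_points=self.points)


class GroupConfig(BaseModel):
    edges: list[tuple[int, int]]
    amplitude: float = Field(ge=0.0, le=1.0)
    task: Optional[str] = None
    task_levels: Optional[dict[str, float]] = None


class SimulateConfig(BaseModel):
    n_nodes: int = 30
    tasks: list[tuple[str, float, int]] = [
        ("rest", 2.0, 8), ("attention", 2.0, 8),
        ("word", 2.5, 8), ("face", 2.5, 8),
    ]
    groups: list[GroupConfig] = [
        GroupConfig(edges=[(0, 1), (2, 3), (4, 5)], amplitude=0.9),
        GroupConfig(edges=[(6, 7), (8, 9), (10, 11)], amplitude=0.9, task="rest"),
    ]
    noise_sd: float = Field(default=0.2, ge=0.0)

    def to_design(self, seed: int) -> PlantedDesign:
        return PlantedDesign(
            n_nodes=self.n_nodes,
            tasks=tuple(TaskBlock(*t) for t in self.tasks),
            groups=tuple(
                PlantedGroup(edges=tuple(tuple(e) for e in g.edges),
                             amplitude=g.amplitude, task=g.task,
                             task_levels=g.task_levels)
                for g in self.groups
            ),
            noise_sd=self.noise_sd,
            seed=seed,
        )


class PipelineConfig(BaseModel):
    simulate: Optional[SimulateConfig] = SimulateConfig()
    runs_manifest: Optional[str] = None  # text file, one run prefix per line
    geometry: Optional[str] = None       # CSV node,x,y,z; synthetic if absent
    band: BandConfig = BandConfig()
    window: WindowConfig = WindowConfig()
    fd_threshold: float = 0.25
    fdr_q: float = 0.05
    alpha: float = 0.05
    n_permutations: int = Field(default=1000, ge=1)
    null_kinds: list[str] = []
    seed: int
    outdir: str

    @field_validator("fdr_q", "alpha")
    @classmethod
    def _unit_interval(cls, v: float, info) -> float:
        if not (0.0 < v < 1.0):
            raise ValueError(f"{info.field_name} = {v} outside (0, 1)")
        return v

    @field_validator("null_kinds")
    @classmethod
    def _known_kinds(cls, v: list[str]) -> list[str]:
        bad = set(v) - set(NULL_KINDS)
        if bad:
            raise ValueError(f"unknown null kinds {sorted(bad)}")
        return v

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path: str | Path) -> PipelineConfig:
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    return PipelineConfig.model_validate(data)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute exclude -> filter -> window -> edge series -> hypergraph ->
    diagnostics -> task specificity -> metrics (-> nulls), writing every
    artifact under ``config.outdir``."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    sim_s, cls_s, met_s, null_s, geo_s = (int(s.generate_state(1)[0]) % (2**31)
                                          for s in ss.spawn(5))

    if config.runs_manifest:
        prefixes = [
            line.strip() for line in Path(config.runs_manifest).read_text().splitlines()
            if line.strip()
        ]
        runs = [hio.load_run(p) for p in prefixes]
    elif config.simulate is not None:
        design = config.simulate.to_design(sim_s)
        runs, _ = generate_region_level(design)
    else:
        raise ValueError("config must provide either simulate or runs_manifest")

    kept, excluded = exclude_high_motion(runs, threshold=config.fd_threshold)
    if not kept:
        raise ValueError("every run was excluded by the motion criterion")
    bspec = BandpassSpec(low=config.band.low, high=config.band.high,
                         order=config.band.order)
    filtered = [bandpass(r, bspec) for r in kept]
    seq = network_sequence(filtered, config.window.to_spec())
    ets = edge_time_series(seq)
    hio.save_edge_series(ets, out / "edge_series.h5")

    c = edge_edge_correlation(ets)
    bm = fdr_binarize(c, q=config.fdr_q)
    hg = extract_hyperedges(bm, subject_id=kept[0].subject_id)
    hio.save_hypergraph(hg, out / "hypergraph.json")
    hio.binarized_to_graphml(bm, out / "edge_edge_graph.graphml")
    size_distribution([hg]).to_csv(out / "size_distribution.csv", index=False)
    pd.DataFrame({
        "node": np.arange(ets.n_nodes),
        "hyperedge_degree": hyperedge_node_degree([hg], ets.n_nodes),
    }).to_csv(out / "node_degree.csv", index=False)

    net = coevolution_matrix([hg], ets.n_nodes)
    hio.coevolution_to_csv(net, out / "coevolution_P.csv")
    hio.coevolution_to_graphml(net, out / "coevolution.graphml")
    threshold_bands(net).to_csv(out / "coevolution_bands.csv", index=False)

    result = classify(hg, ets, alpha=config.alpha,
                      n_permutations=config.n_permutations, seed=cls_s)
    result.table.assign(label=result.table["hyperedge"].map(result.labels)) \
        .to_csv(out / "task_labels.csv", index=False)
    for task, thg in result.task_hypergraphs.items():
        hio.save_hypergraph(thg, out / f"hypergraph_{task}.json")

    if config.geometry:
        geom = hio.load_geometry(config.geometry)
    else:
        rng = np.random.default_rng(geo_s)
        geom = NodeGeometry(rng.uniform(-70.0, 70.0, size=(ets.n_nodes, 3)))
        hio.save_geometry(geom, out / "geometry_synthetic.csv")
    metrics = []
    for metric in (LENGTH_STRENGTH, POSITION_STRENGTH):
        res = metric_significance(net, geom, metric=metric,
                                  n_permutations=config.n_permutations,
                                  seed=met_s)
        metrics.append({"metric": metric, "R": res.R, "p": res.p,
                        "defined": res.defined, "network": res.label})
    pd.DataFrame(metrics).to_csv(out / "metrics.csv", index=False)

    null_counts = {}
    for kind in config.null_kinds:
        nhg, dist = run_null(ets, NullSpec(kind=kind, seed=null_s), q=config.fdr_q)
        tag = kind.replace("-", "_")
        hio.save_hypergraph(nhg, out / f"null_{tag}_hypergraph.json")
        dist.to_csv(out / f"null_{tag}_size_distribution.csv", index=False)
        null_counts[kind] = len(nhg.hyperedges)

    meta = {
        "config": config.model_dump(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "excluded_runs": excluded,
        "n_windows": ets.n_windows,
        "n_edges": ets.n_edges,
        "n_hyperedges": len(hg.hyperedges),
        "n_singletons": len(hg.singletons),
        "null_non_singleton_counts": null_counts,
        "p_value": "t-transform",
    }
    (out / "metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return meta
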
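"""File formats: delimited-text runs, HDF5 edge series, JSON hypergraphs,
CSV geometry, GraphML exports."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import h5py
import networkx as nx
import numpy as np
import pandas as pd

from .coevolution import CoevolutionNetwork
from .dynamics import EdgeTimeSeriesMatrix
from .hypergraph import BinarizedEdgeMatrix, Hypergraph
from .prep import RegionTimeSeriesRun
from .spatial import NodeGeometry


def save_run(run: RegionTimeSeriesRun, prefix: str | Path) -> None:
    """Write ``<prefix>.tsv`` (one row per region) plus a JSON sidecar.

    The optional FD trace goes to ``<prefix>.fd.txt`` as single-column text.
    """
    prefix = Path(prefix)
    np.savetxt(prefix.with_suffix(".tsv"), run.data, delimiter="\t")
    sidecar = {
        "subject_id": run.subject_id,
        "task": run.task,
        "sampling_period": run.sampling_period,
        "run_id": run.run_id,
        "n_regions": run.n_regions,
        "n_samples": run.n_samples,
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    if run.fd is not None:
        np.savetxt(prefix.with_suffix(".fd.txt"), run.fd)


def load_run(prefix: str | Path) -> RegionTimeSeriesRun:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    data = np.loadtxt(prefix.with_suffix(".tsv"), delimiter="\t", ndmin=2)
    fd_path = prefix.with_suffix(".fd.txt")
    fd = np.loadtxt(fd_path) if fd_path.exists() else None
    return RegionTimeSeriesRun(
        subject_id=meta["subject_id"], task=meta["task"],
        sampling_period=meta["sampling_period"], data=data, fd=fd,
        run_id=meta.get("run_id"),
    )


def save_edge_series(ets: EdgeTimeSeriesMatrix, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("weights", data=ets.weights, compression="gzip")
        f.create_dataset("pairs", data=ets.pairs)
        f.create_dataset(
            "window_tasks",
            data=np.asarray(ets.window_tasks, dtype=h5py.string_dtype()),
        )
        f.attrs["n_nodes"] = ets.n_nodes


def load_edge_series(path: str | Path) -> EdgeTimeSeriesMatrix:
    with h5py.File(path, "r") as f:
        return EdgeTimeSeriesMatrix(
            weights=f["weights"][()],
            pairs=f["pairs"][()],
            window_tasks=np.asarray(
                [t.decode() if isinstance(t, bytes) else str(t)
                 for t in f["window_tasks"][()]]
            ),
            n_nodes=int(f.attrs["n_nodes"]),
        )


def edge_series_to_csv(ets: EdgeTimeSeriesMatrix, path: str | Path) -> None:
    index = [f"{i}-{j}" for i, j in ets.pairs.tolist()]
    df = pd.DataFrame(ets.weights, index=index, columns=list(ets.window_tasks))
    df.to_csv(path, index_label="edge")


def hypergraph_to_dict(hg: Hypergraph) -> dict:
    return {
        "subject_id": hg.subject_id,
        "n_nodes": hg.n_nodes,
        "pairs": hg.pairs.tolist(),
        "hyperedges": [
            [hg.pairs[e].tolist() for e in sorted(h)] for h in hg.hyperedges
        ],
        "singletons": [hg.pairs[e].tolist() for e in sorted(hg.singletons)],
        "meta": hg.meta,
    }


def save_hypergraph(hg: Hypergraph, path: str | Path) -> None:
    Path(path).write_text(json.dumps(hypergraph_to_dict(hg), indent=2))


def load_hypergraph(path: str | Path) -> Hypergraph:
    d = json.loads(Path(path).read_text())
    pairs = np.asarray(d["pairs"], dtype=np.int64)
    row_of = {tuple(p): k for k, p in enumerate(pairs.tolist())}
    hyperedges = tuple(
        frozenset(row_of[tuple(e)] for e in h) for h in d["hyperedges"]
    )
    singletons = frozenset(row_of[tuple(e)] for e in d["singletons"])
    return Hypergraph(
        hyperedges=hyperedges, singletons=singletons, pairs=pairs,
        n_nodes=d["n_nodes"], subject_id=d.get("subject_id"),
        meta=d.get("meta", {}),
    )


def binarized_to_graphml(bm: BinarizedEdgeMatrix, path: str | Path) -> None:
    """GraphML of the edge-edge graph: vertices are network edges."""
    g = nx.Graph()
    for k, (i, j) in enumerate(bm.pairs.tolist()):
        g.add_node(k, node_i=int(i), node_j=int(j))
    rows, cols = np.nonzero(np.triu(bm.b, k=1))
    g.add_edges_from(zip(rows.tolist(), cols.tolist()))
    nx.write_graphml(g, path)


def coevolution_to_graphml(net: CoevolutionNetwork, path: str | Path) -> None:
    g = nx.Graph(label=net.label, n_hypergraphs=net.n_hypergraphs)
    g.add_nodes_from(range(net.n_nodes))
    iu = np.triu_indices(net.n_nodes, k=1)
    for i, j, w in zip(iu[0].tolist(), iu[1].tolist(), net.P[iu].tolist()):
        if w > 0:
            g.add_edge(i, j, weight=float(w))
    nx.write_graphml(g, path)


def coevolution_to_csv(net: CoevolutionNetwork, path: str | Path) -> None:
    pd.DataFrame(net.P).to_csv(path, index=False)


def load_geometry(path: str | Path) -> NodeGeometry:
    """Geometry CSV with columns node, x, y, z (node order defines index)."""
    df = pd.read_csv(path)
    return NodeGeometry.from_frame(df)


def save_geometry(geom: NodeGeometry, path: str | Path) -> None:
    df = pd.DataFrame(geom.coords, columns=["x", "y", "z"])
    df.insert(0, "node", np.arange(geom.n_nodes))
    df.to_csv(path, index=False)
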
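"""Spatial interaction graphs over cell centroids.

Two constructions are supported, both operating on 2-D centroids in µm
(1 px = 1 µm at the imaging resolution assumed throughout):

* expansion graph — an undirected edge joins every pair of cells whose
  centroid distance is at most a threshold (boundary inclusive, default
  15 µm);
* k-nearest-neighbor graph — each cell selects its ``k`` nearest others
  (default 10), distance ties broken toward the lower cell id, and the
  directed selections are symmetrized by union.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

__all__ = ["SpatialGraph", "build_expansion_graph", "build_knn_graph", "degree_summary"]


@dataclass
class SpatialGraph:
    """Undirected spatial graph over the cells of one sample.

    ``edges`` is an (m, 2) integer array of cell-id pairs with
    ``edges[:, 0] < edges[:, 1]``; ``node_ids`` lists every cell, including
    isolated ones.
    """

    sample_id: str
    node_ids: np.ndarray
    edges: np.ndarray
    method: str
    parameter: float
    distances: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.node_ids = np.asarray(self.node_ids)
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> pd.Series:
        deg = pd.Series(0, index=pd.Index(self.node_ids, name="cell_id"), name="degree")
        if self.n_edges:
            counts = pd.concat([pd.Series(self.edges[:, 0]),
                                pd.Series(self.edges[:, 1])]).value_counts()
            deg.loc[counts.index] = counts.values
        return deg

    def neighbors(self) -> dict[int, np.ndarray]:
        adj: dict[int, list[int]] = {int(i): [] for i in self.node_ids}
        for a, b in self.edges:
            adj[int(a)].append(int(b))
            adj[int(b)].append(int(a))
        return {k: np.array(v, dtype=np.int64) for k, v in adj.items()}

    def to_edge_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.edges, columns=["cell_a", "cell_b"])
        df.insert(0, "sample_id", self.sample_id)
        if self.distances is not None:
            df["distance"] = self.distances
        return df

    def params_dict(self) -> dict:
        return {"sample_id": self.sample_id, "method": self.method,
                "parameter": self.parameter, "n_nodes": int(self.n_nodes),
                "n_edges": int(self.n_edges), "units": "um"}

    def save(self, edge_path, sidecar_path=None) -> None:
        self.to_edge_frame().to_csv(edge_path, index=False)
        if sidecar_path is not None:
            with open(sidecar_path, "w") as fh:
                json.dump(self.params_dict(), fh, indent=2)


def _check_coords(coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 2:
        raise ValueError("centroids must be an (n, 2) array")
    if not np.isfinite(coords).all():
        raise ValueError("centroids must be finite")
    return coords


def _sorted_by_id(cell_ids, coords):
    cell_ids = np.asarray(cell_ids, dtype=np.int64)
    order = np.argsort(cell_ids, kind="stable")
    return cell_ids[order], coords[order]


def build_expansion_graph(coords, cell_ids=None, threshold: float = 15.0,
                          sample_id: str = "sample") -> SpatialGraph:
    """Expansion graph: edge (i, j) iff ``dist(i, j) <= threshold`` (µm)."""
    coords = _check_coords(coords)
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if len(coords) < 1:
        raise ValueError("need at least one cell")
    if cell_ids is None:
        cell_ids = np.arange(len(coords))
    cell_ids, coords = _sorted_by_id(cell_ids, coords)
    pairs = cKDTree(coords).query_pairs(r=threshold, output_type="ndarray")
    if len(pairs):
        a = cell_ids[pairs[:, 0]]
        b = cell_ids[pairs[:, 1]]
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        order = np.lexsort((hi, lo))
        edges = np.column_stack([lo, hi])[order]
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)[order]
    else:
        edges = np.empty((0, 2), dtype=np.int64)
        d = np.empty(0)
    return SpatialGraph(sample_id=sample_id, node_ids=cell_ids, edges=edges,
                        method="expansion", parameter=float(threshold), distances=d)


def build_knn_graph(coords, cell_ids=None, k: int = 10,
                    sample_id: str = "sample") -> SpatialGraph:
    """Symmetrized k-nearest-neighbor graph.

    Every cell selects its ``k`` nearest others (``k`` clipped to n−1;
    exact distance ties resolved toward the lower cell id) and an
    undirected edge exists wherever either endpoint selected the other.
    """
    coords = _check_coords(coords)
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(coords)
    if n < 2:
        raise ValueError("need at least two cells for a knn graph")
    if cell_ids is None:
        cell_ids = np.arange(n)
    cell_ids, coords = _sorted_by_id(cell_ids, coords)
    k_eff = min(k, n - 1)

    sel_rows = np.empty((n, k_eff), dtype=np.int64)
    chunk = max(1, int(2e7) // n)
    for start in range(0, n, chunk):
        stop = min(n, start + chunk)
        d = cdist(coords[start:stop], coords)
        rows = np.arange(start, stop)
        d[rows - start, rows] = np.inf
        # stable sort on distance; nodes are id-ordered, so ties fall to lower id
        idx = np.argsort(d, axis=1, kind="stable")[:, :k_eff]
        sel_rows[start:stop] = idx
    src = np.repeat(np.arange(n), k_eff)
    dst = sel_rows.ravel()
    lo = np.minimum(src, dst)
    hi = np.maximum(src, dst)
    und = np.unique(np.column_stack([lo, hi]), axis=0)
    edges = np.column_stack([cell_ids[und[:, 0]], cell_ids[und[:, 1]]])
    d = np.linalg.norm(coords[und[:, 0]] - coords[und[:, 1]], axis=1)
    return SpatialGraph(sample_id=sample_id, node_ids=cell_ids, edges=edges,
                        method="knn", parameter=float(k), distances=d)


def degree_summary(graph: SpatialGraph) -> tuple[pd.Series, dict]:
    """Per-node degree plus summary statistics (mean = 2·|E|/|V|)."""
    deg = graph.degrees()
    stats = {
        "n_nodes": int(graph.n_nodes),
        "n_edges": int(graph.n_edges),
        "mean_degree": float(deg.mean()) if len(deg) else 0.0,
        "max_degree": int(deg.max()) if len(deg) else 0,
        "min_degree": int(deg.min()) if len(deg) else 0,
        "n_isolated": int((deg == 0).sum()),
    }
    return deg, stats
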
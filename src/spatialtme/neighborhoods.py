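"""Cellular neighborhoods: neighbor-composition profiles and k-means CNs.

A cell's neighborhood profile is the fraction of each cell type among its
spatial-graph neighbors (self excluded).  Profiles are pooled across the
cohort and clustered with k-means (default k = 8) into cellular
neighborhoods (CNs): groups of cells that live in similar local cell-type
environments, regardless of their own phenotype.  CN indices carry no
meaning across runs; reports therefore attach a CN-by-type z-score matrix
so a "neutrophil-rich" CN is identified by composition, not by index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .graphs import SpatialGraph
from .synthetic import CELL_TYPES

__all__ = [
    "aggregate_neighbor_fractions",
    "CNModel",
    "cluster_neighborhoods",
    "cn_composition_zscores",
    "cn_frequencies",
    "plot_cn_heatmap",
]


def aggregate_neighbor_fractions(graph: SpatialGraph, labels: pd.Series,
                                 types=CELL_TYPES) -> pd.DataFrame:
    """Per-cell neighbor cell-type fractions.

    ``labels`` maps cell id -> type for every node of the graph.  Isolated
    cells get an all-zero profile with ``n_neighbors`` 0.  Returns a frame
    indexed by cell id with one column per type plus ``n_neighbors``.
    """
    node_ids = graph.node_ids
    missing = set(map(int, node_ids)) - set(map(int, labels.index))
    if missing:
        raise KeyError(f"unlabeled graph nodes, e.g. {sorted(missing)[:5]}")
    types = list(types)
    type_code = {t: i for i, t in enumerate(types)}
    codes = labels.loc[node_ids].map(type_code).to_numpy(dtype=float)
    if np.isnan(codes).any():
        bad = sorted(set(labels.loc[node_ids]) - set(types))
        raise ValueError(f"labels outside type set: {bad}")
    codes = codes.astype(np.int64)
    pos = {int(cid): i for i, cid in enumerate(node_ids)}
    counts = np.zeros((len(node_ids), len(types)), dtype=np.int64)
    if graph.n_edges:
        a = np.fromiter((pos[int(i)] for i in graph.edges[:, 0]), dtype=np.int64,
                        count=graph.n_edges)
        b = np.fromiter((pos[int(i)] for i in graph.edges[:, 1]), dtype=np.int64,
                        count=graph.n_edges)
        np.add.at(counts, (a, codes[b]), 1)
        np.add.at(counts, (b, codes[a]), 1)
    n_neighbors = counts.sum(axis=1)
    denom = np.where(n_neighbors > 0, n_neighbors, 1)
    fractions = counts / denom[:, None]
    out = pd.DataFrame(fractions, index=pd.Index(node_ids, name="cell_id"),
                       columns=types)
    out["n_neighbors"] = n_neighbors
    return out


@dataclass
class CNModel:
    """Fitted k-means cellular-neighborhood model."""

    k: int
    centroids: pd.DataFrame          # k x n_types, indexed by CN label 1..k
    labels: pd.Series                # per-cell CN label in {1..k}
    inertia: float
    seed: int
    n_init: int

    def composition(self, final_labels: pd.Series) -> pd.DataFrame:
        """Observed cell-type composition of each CN (rows sum to 1)."""
        df = pd.DataFrame({"cn": self.labels, "type": final_labels.loc[self.labels.index]})
        comp = (df.groupby(["cn", "type"], observed=False).size()
                  .unstack(fill_value=0)
                  .reindex(index=range(1, self.k + 1), fill_value=0))
        totals = comp.sum(axis=1)
        return comp.div(totals.where(totals > 0, 1), axis=0)


def cluster_neighborhoods(profiles: pd.DataFrame, k: int = 8, seed: int = 0,
                          n_init: int = 10, types=CELL_TYPES) -> CNModel:
    """Cluster pooled neighbor profiles into ``k`` cellular neighborhoods.

    Lloyd's k-means with k-means++ initialization and ``n_init`` restarts
    (best inertia kept); deterministic given the seed.  Profiles should be
    pooled across all samples of a cohort so CN labels are comparable
    between groups.  Requires at least ``k`` distinct profiles.
    """
    x = profiles.loc[:, list(types)].to_numpy(dtype=float)
    n_distinct = len(np.unique(x, axis=0))
    if n_distinct < k:
        raise ValueError(f"need >= {k} distinct profiles, got {n_distinct}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, max_iter=300,
                tol=1e-6, random_state=seed)
    assign = km.fit_predict(x)
    centroids = pd.DataFrame(km.cluster_centers_, columns=list(types),
                             index=pd.RangeIndex(1, k + 1, name="cn"))
    labels = pd.Series(assign + 1, index=profiles.index, name="cn")
    return CNModel(k=k, centroids=centroids, labels=labels,
                   inertia=float(km.inertia_), seed=seed, n_init=n_init)


def cn_composition_zscores(cn_labels: pd.Series, final_labels: pd.Series,
                           types=CELL_TYPES) -> pd.DataFrame:
    """CN-by-type composition, z-scored per type across CNs.

    Each column (cell type) of the CN composition matrix is standardized to
    mean 0, sd 1 across the CNs, so the heat map answers "which CNs are
    enriched for this type".  A type with identical abundance in every CN
    gets z = 0 by convention.
    """
    cns = sorted(cn_labels.unique())
    if len(cns) < 2:
        raise ValueError("need >= 2 non-empty CNs to z-score")
    df = pd.DataFrame({"cn": cn_labels, "type": final_labels.loc[cn_labels.index]})
    comp = (df.groupby(["cn", "type"], observed=False).size()
              .unstack(fill_value=0)
              .reindex(columns=list(types), fill_value=0))
    comp = comp.div(comp.sum(axis=1), axis=0)
    mean = comp.mean(axis=0)
    sd = comp.std(axis=0, ddof=1)
    z = (comp - mean).div(sd.where(sd > 0, np.inf), axis=1)
    z.index.name = "cn"
    return z


def cn_frequencies(cn_labels: pd.Series, sample_ids: pd.Series,
                   k: int | None = None) -> pd.DataFrame:
    """Per-sample CN frequencies, normalized by the sample's total cell count.

    Rows (samples) sum to 1.
    """
    if len(cn_labels) == 0:
        raise ValueError("no cells")
    df = pd.DataFrame({"sample_id": sample_ids.loc[cn_labels.index].to_numpy(),
                       "cn": cn_labels.to_numpy()})
    counts = df.groupby(["sample_id", "cn"], observed=False).size().unstack(fill_value=0)
    if k is not None:
        counts = counts.reindex(columns=range(1, k + 1), fill_value=0)
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("sample with zero cells")
    return counts.div(totals, axis=0)


def plot_cn_heatmap(zscores: pd.DataFrame, path=None, ax=None):
    """Heat map of the CN-by-type z-score matrix (optional figure output)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 4))
    else:
        fig = ax.figure
    im = ax.imshow(zscores.to_numpy(), cmap="RdBu_r", aspect="auto")
    ax.set_xticks(range(zscores.shape[1]), zscores.columns, rotation=45, ha="right")
    ax.set_yticks(range(zscores.shape[0]), [f"CN {i}" for i in zscores.index])
    fig.colorbar(im, ax=ax, label="z score")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return ax
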
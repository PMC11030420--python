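"""Leiden clustering with stability-selected resolution, cluster
enrichment, feature modules, and phenotype distance.

Clustering runs on a k-nearest-neighbor graph built from embedding
coordinates.  The resolution parameter is chosen by stability selection:
Leiden is run on repeated 90 % subsamples at each candidate resolution and
the mean pairwise adjusted Rand score (ARS) between subsample labelings,
restricted to shared genes, measures how reproducible the partition is;
the most stable resolution wins (ties break toward the smallest, i.e.
coarsest, resolution).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import adjusted_rand_score
from sklearn.neighbors import NearestNeighbors
from sklearn.cluster import AgglomerativeClustering
from sklearn.base import BaseEstimator, TransformerMixin

from .classify import bh_correct
from .embedding import Embedding

__all__ = [
    "ClusterResult",
    "knn_graph",
    "cluster_leiden",
    "select_resolution",
    "cluster_enrichment",
    "FeatureModules",
    "feature_modules",
    "phenotype_distance",
]


def knn_graph(coords: np.ndarray, k: int = 15) -> ig.Graph:
    """Undirected simple kNN graph on row coordinates."""
    n = len(coords)
    if k >= n:
        raise ValueError("k must be smaller than the number of points")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    edges = {(min(i, j), max(i, j)) for i, row in enumerate(idx) for j in row[1:]}
    g = ig.Graph(n=n, edges=sorted(edges), directed=False)
    return g


def _leiden_labels(g: ig.Graph, resolution: float, seed: int) -> np.ndarray:
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=int(seed),
        n_iterations=2,
    )
    return np.asarray(part.membership)


def cluster_leiden(
    embedding: Embedding | pd.DataFrame | np.ndarray,
    resolution: float,
    knn_graph_k: int = 15,
    seed: int = 0,
) -> pd.Series | np.ndarray:
    """Leiden community labels on a kNN graph of embedding coordinates."""
    if isinstance(embedding, Embedding):
        coords, index = embedding.to_numpy(), embedding.coordinates.index
    elif isinstance(embedding, pd.DataFrame):
        coords, index = embedding.to_numpy(float), embedding.index
    else:
        coords, index = np.asarray(embedding, float), None
    labels = _leiden_labels(knn_graph(coords, knn_graph_k), resolution, seed)
    if index is not None:
        return pd.Series(labels, index=index, name="cluster")
    return labels


@dataclass
class ClusterResult:
    labels: pd.Series           # gene -> cluster id
    resolution: float
    stability_curve: pd.DataFrame  # resolution, mean_ars, n_pairs
    n_clusters: int


def select_resolution(
    embedding: Embedding | pd.DataFrame,
    resolutions: Sequence[float],
    n_iterations: int = 15,
    subsample_fraction: float = 0.9,
    seed: int = 0,
    knn_graph_k: int = 15,
) -> ClusterResult:
    """Stability-select a Leiden resolution and cluster at it.

    For each candidate resolution, Leiden runs on ``n_iterations`` induced
    subgraphs of ``subsample_fraction`` of the genes; stability is the
    mean ARS over all pairs of subsample labelings on their shared genes.
    The final labels come from a full-data run at the winning resolution.
    """
    if len(resolutions) == 0:
        raise ValueError("resolutions must be non-empty")
    resolutions = sorted(float(r) for r in resolutions)
    if isinstance(embedding, Embedding):
        coords, index = embedding.to_numpy(), embedding.coordinates.index
    else:
        coords, index = embedding.to_numpy(float), embedding.index
    n = len(coords)
    g = knn_graph(coords, knn_graph_k)
    rng = np.random.default_rng(int(seed))
    m = max(2, int(round(subsample_fraction * n)))
    subsamples = [np.sort(rng.choice(n, size=m, replace=False)) for _ in range(n_iterations)]

    rows = []
    for res in resolutions:
        labelings = []
        for it, sub in enumerate(subsamples):
            sg = g.induced_subgraph(sub)
            lab = _leiden_labels(sg, res, seed=int(seed) + 7919 * it)
            labelings.append(dict(zip(sub, lab)))
        scores = []
        for a, b in combinations(range(len(labelings)), 2):
            shared = sorted(set(labelings[a]) & set(labelings[b]))
            if len(shared) < 2:
                continue
            la = [labelings[a][i] for i in shared]
            lb = [labelings[b][i] for i in shared]
            scores.append(adjusted_rand_score(la, lb))
        rows.append((res, float(np.mean(scores)) if scores else float("nan"), len(scores)))
    curve = pd.DataFrame(rows, columns=["resolution", "mean_ars", "n_pairs"])

    best = curve.loc[curve["mean_ars"].idxmax()]
    # idxmax takes the first maximum; resolutions are sorted ascending, so
    # ties already break toward the smallest resolution.
    chosen = float(best["resolution"])
    labels = pd.Series(_leiden_labels(g, chosen, seed=int(seed)), index=index, name="cluster")
    return ClusterResult(labels, chosen, curve, int(labels.nunique()))


def cluster_enrichment(
    labels: pd.Series,
    gene_flags: pd.Series,
    background: Sequence[str] | None = None,
    scores: pd.Series | None = None,
    mode: str = "hypergeometric",
) -> pd.DataFrame:
    """Per-cluster over-representation of hit genes.

    ``hypergeometric`` mode tests hit membership (one-sided); the
    alternative ``ranksum`` mode runs a one-sided Wilcoxon rank-sum on
    continuous classifier ``scores`` (cluster vs rest).  BH correction is
    applied across clusters.
    """
    genes = list(background) if background is not None else list(labels.index)
    labels = labels.loc[genes]
    rows = []
    if mode == "hypergeometric":
        flags = gene_flags.loc[genes].astype(bool)
        N, K = len(genes), int(flags.sum())
        for cluster, members in labels.groupby(labels).groups.items():
            n = len(members)
            if n == 0:
                continue
            k = int(flags.loc[list(members)].sum())
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
            denom = (n - k) * (K - k)
            odds = ((k * (N - K - n + k)) / denom) if denom > 0 else float("inf")
            rows.append((cluster, n, k, odds, p))
        out = pd.DataFrame(rows, columns=["cluster", "n_genes", "n_hits", "odds", "p"])
    elif mode == "ranksum":
        if scores is None:
            raise ValueError("ranksum mode needs continuous scores")
        s = scores.loc[genes]
        for cluster, members in labels.groupby(labels).groups.items():
            inside = s.loc[list(members)]
            outside = s.drop(list(members))
            if len(inside) == 0 or len(outside) == 0:
                continue
            stat, p = stats.mannwhitneyu(inside, outside, alternative="greater")
            rows.append((cluster, len(inside), int(stat), float("nan"), float(p)))
        out = pd.DataFrame(rows, columns=["cluster", "n_genes", "stat", "odds", "p"])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    out["q"] = bh_correct(out["p"].to_numpy())
    return out.sort_values("p", ignore_index=True)


class FeatureModules(BaseEstimator, TransformerMixin):
    """Reduce correlated features to module scores.

    Feature columns are co-clustered by agglomerative clustering
    (Euclidean distance, average linkage) into ``n_modules`` groups; a
    gene's module score is the mean of its member features.  Module ids
    are numbered 1..M in order of first feature occurrence, so the map is
    deterministic.
    """

    def __init__(self, n_modules: int = 20):
        self.n_modules = n_modules

    def fit(self, X: pd.DataFrame, y=None) -> "FeatureModules":
        if X.isna().to_numpy().any():
            raise ValueError("NaN values are not allowed")
        if self.n_modules > X.shape[1]:
            raise ValueError("n_modules cannot exceed the feature count")
        raw = AgglomerativeClustering(
            n_clusters=self.n_modules, metric="euclidean", linkage="average"
        ).fit_predict(X.to_numpy(float).T)
        remap: dict[int, int] = {}
        for lab in raw:
            if lab not in remap:
                remap[lab] = len(remap) + 1
        self.feature_modules_ = pd.Series(
            [remap[lab] for lab in raw], index=X.columns, name="module"
        )
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        cols = {}
        width = len(str(self.n_modules))
        for module in range(1, self.n_modules + 1):
            members = self.feature_modules_.index[self.feature_modules_ == module]
            cols[f"module_{module:0{width}d}"] = X[members].mean(axis=1)
        return pd.DataFrame(cols, index=X.index)


def feature_modules(feature_matrix: pd.DataFrame, n_modules: int = 20):
    """Functional wrapper: returns (feature -> module map, module scores)."""
    fm = FeatureModules(n_modules).fit(feature_matrix)
    return fm.feature_modules_, fm.transform(feature_matrix)


def phenotype_distance(
    embedding: Embedding | pd.DataFrame,
    gene: str,
    ntc_rows: Sequence[str],
) -> float:
    """Euclidean distance in embedding space from a gene to the centroid
    of the non-targeting control rows."""
    coords = embedding.coordinates if isinstance(embedding, Embedding) else embedding
    ntc_rows = list(ntc_rows)
    if not ntc_rows:
        raise ValueError("no NTC rows supplied")
    centroid = coords.loc[ntc_rows].to_numpy(float).mean(axis=0)
    return float(np.linalg.norm(coords.loc[gene].to_numpy(float) - centroid))
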
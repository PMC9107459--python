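"""Normalization, highly-variable-gene selection, PCA, shared-nearest-
neighbour graph clustering, subclustering, and cluster marker testing.

This module builds the representation every downstream stage operates on:
library-size log1p normalization (scale 10,000), top-3000 HVGs by positive
residual from a fitted mean-variance trend, a 20-PC (15 for subclustering)
PCA on per-gene standardized values capped at 10 standard deviations, and
modularity (Leiden) community detection at resolution 0.8 on the SNN graph.
Cluster markers are tested one-vs-rest with the Wilcoxon rank-sum test and
Bonferroni adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse, stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

import igraph as ig
import leidenalg

__all__ = [
    "normalize_log",
    "LogNormalizer",
    "select_hvgs",
    "HVGSelector",
    "run_pca",
    "PCAEmbedder",
    "cluster_graph",
    "SNNLeidenClusterer",
    "subcluster",
    "SubclusterResult",
    "find_markers",
]


# --------------------------------------------------------------------------
# normalization
# --------------------------------------------------------------------------

class LogNormalizer(BaseEstimator, TransformerMixin):
    """Library-size log1p normalization: ``log1p(count / library * scale)``."""

    def __init__(self, scale: float = 1e4):
        self.scale = scale

    def fit(self, X, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        values = X.to_numpy(dtype=float)
        lib = values.sum(axis=1)
        if (lib == 0).any():
            bad = list(X.index[lib == 0][:5])
            raise ValueError(
                f"zero-library cell(s) {bad}; run QC filtering first"
            )
        out = np.log1p(values / lib[:, None] * self.scale)
        return pd.DataFrame(out, index=X.index, columns=X.columns)


def normalize_log(counts: pd.DataFrame, scale: float = 1e4) -> pd.DataFrame:
    return LogNormalizer(scale=scale).fit_transform(counts)


# --------------------------------------------------------------------------
# HVG selection
# --------------------------------------------------------------------------

class HVGSelector(BaseEstimator, TransformerMixin):
    """Rank genes by standardized dispersion against a mean-variance trend.

    A quadratic trend of log variance on log mean is fitted across expressed
    genes; genes are ranked by their positive residual and the top ``n_top``
    are kept, in rank order.  With fewer than 10 usable genes the trend is
    unfittable and ranking falls back to raw variance with a warning.
    """

    def __init__(self, n_top: int = 3000):
        self.n_top = n_top

    def fit(self, X: pd.DataFrame, y=None) -> "HVGSelector":
        values = X.to_numpy(dtype=float)
        mean = values.mean(axis=0)
        var = values.var(axis=0, ddof=1) if values.shape[0] > 1 else np.zeros(
            values.shape[1]
        )
        usable = (mean > 0) & (var > 0)
        if usable.sum() < 10:
            warnings.warn(
                "fewer than 10 expressed genes with variance; "
                "falling back to raw variance ranking"
            )
            score = var
        else:
            score = np.full(values.shape[1], -np.inf)
            lm = np.log(mean[usable])
            lv = np.log(var[usable])
            coef = np.polyfit(lm, lv, deg=2)
            score[usable] = lv - np.polyval(coef, lm)
        order = np.argsort(-score, kind="stable")
        n = min(self.n_top, values.shape[1])
        self.hvg_genes_ = list(X.columns[order[:n]])
        self.dispersion_score_ = pd.Series(score, index=X.columns)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return X[self.hvg_genes_]


def select_hvgs(expr: pd.DataFrame, n_hvgs: int = 3000) -> list[str]:
    """Top ``n_hvgs`` highly variable genes of a log-expression matrix,
    in decreasing dispersion order (all genes if fewer are available)."""
    return HVGSelector(n_top=n_hvgs).fit(expr).hvg_genes_


# --------------------------------------------------------------------------
# PCA
# --------------------------------------------------------------------------

class PCAEmbedder(BaseEstimator, TransformerMixin):
    """PCA on per-gene standardized log expression.

    Genes are centred and scaled to unit variance with values capped at
    ``max_value`` standard deviations to bound outlier leverage; components
    carry a deterministic sign (the largest-magnitude gene loading of each
    component is positive).
    """

    def __init__(self, n_components: int = 20, max_value: float = 10.0,
                 random_state: int = 0):
        self.n_components = n_components
        self.max_value = max_value
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None) -> "PCAEmbedder":
        self._fit(X)
        return self

    def _fit(self, X: pd.DataFrame) -> np.ndarray:
        values = X.to_numpy(dtype=float)
        n_cells, n_genes = values.shape
        if self.n_components > min(n_cells, n_genes):
            raise ValueError(
                f"n_components={self.n_components} exceeds "
                f"min(n_cells, n_genes)={min(n_cells, n_genes)}"
            )
        self.mean_ = values.mean(axis=0)
        sd = values.std(axis=0, ddof=0)
        self.sd_ = np.where(sd == 0, 1.0, sd)
        scaled = np.clip(
            (values - self.mean_) / self.sd_, -self.max_value, self.max_value
        )
        svd = "full" if min(scaled.shape) < 3 * self.n_components else "randomized"
        self._pca = PCA(n_components=self.n_components, svd_solver=svd,
                        random_state=self.random_state)
        coords = self._pca.fit_transform(scaled)
        # deterministic sign: largest-|loading| gene of each component positive
        flip = np.ones(self.n_components)
        for c in range(self.n_components):
            load = self._pca.components_[c]
            if load[np.argmax(np.abs(load))] < 0:
                flip[c] = -1.0
        self._pca.components_ *= flip[:, None]
        coords *= flip[None, :]
        self.explained_variance_ = self._pca.explained_variance_
        self.feature_names_in_ = np.asarray(X.columns)
        return coords

    def fit_transform(self, X: pd.DataFrame, y=None) -> pd.DataFrame:
        coords = self._fit(X)
        return pd.DataFrame(
            coords, index=X.index,
            columns=[f"PC{c + 1}" for c in range(self.n_components)],
        )

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        scaled = np.clip(
            (X.to_numpy(dtype=float) - self.mean_) / self.sd_,
            -self.max_value, self.max_value,
        )
        coords = self._pca.transform(scaled)
        return pd.DataFrame(
            coords, index=X.index,
            columns=[f"PC{c + 1}" for c in range(self.n_components)],
        )

    def inverse_transform(self, coords: pd.DataFrame) -> np.ndarray:
        return self._pca.inverse_transform(np.asarray(coords))


def run_pca(
    expr: pd.DataFrame, hvgs: list[str] | None = None, n_pcs: int = 20,
    max_value: float = 10.0, random_state: int = 0,
) -> pd.DataFrame:
    """PCA embedding (cells x n_pcs) of the HVG-restricted expression."""
    if hvgs is not None:
        missing = set(hvgs) - set(expr.columns)
        if missing:
            raise KeyError(f"HVGs absent from the matrix: {sorted(missing)[:5]}")
        expr = expr[list(hvgs)]
    return PCAEmbedder(
        n_components=n_pcs, max_value=max_value, random_state=random_state
    ).fit_transform(expr)


# --------------------------------------------------------------------------
# graph clustering
# --------------------------------------------------------------------------

class SNNLeidenClusterer(BaseEstimator):
    """Shared-nearest-neighbour graph + Leiden modularity clustering.

    A kNN graph (``k_neighbors`` including the cell itself) is converted to
    an SNN graph with Jaccard edge weights over shared neighbourhoods; the
    Leiden algorithm (RB-configuration modularity with a resolution
    parameter) partitions it.  Labels are relabelled by decreasing cluster
    size and are deterministic under a fixed seed.
    """

    def __init__(self, k_neighbors: int = 20, resolution: float = 0.8,
                 random_state: int = 0):
        self.k_neighbors = k_neighbors
        self.resolution = resolution
        self.random_state = random_state

    def fit_predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        coords = np.asarray(X, dtype=float)
        n = coords.shape[0]
        if self.k_neighbors < 2:
            raise ValueError("k_neighbors must be >= 2")
        if n <= self.k_neighbors:
            raise ValueError("need more cells than k_neighbors")
        k = self.k_neighbors
        nn = NearestNeighbors(n_neighbors=k).fit(coords)
        idx = nn.kneighbors(coords, return_distance=False)
        adj = sparse.csr_matrix(
            (np.ones(n * k), (np.repeat(np.arange(n), k), idx.ravel())),
            shape=(n, n),
        )
        shared = adj @ adj.T  # pairwise shared-neighbour counts
        mask = adj.maximum(adj.T)  # keep pairs in either kNN list
        snn = shared.multiply(mask)
        snn = sparse.triu(snn, k=1).tocoo()
        jaccard = snn.data / (2.0 * k - snn.data)
        g = ig.Graph(
            n=n, edges=list(zip(snn.row.tolist(), snn.col.tolist())),
            edge_attrs={"weight": jaccard.tolist()},
        )
        part = leidenalg.find_partition(
            g,
            leidenalg.RBConfigurationVertexPartition,
            weights="weight",
            resolution_parameter=self.resolution,
            seed=self.random_state,
            n_iterations=2,
        )
        labels = np.asarray(part.membership)
        self.labels_ = _relabel_by_size(labels)
        return self.labels_


def _relabel_by_size(labels: np.ndarray) -> np.ndarray:
    """Relabel contiguously from 0 by decreasing size (ties: old label)."""
    ids, counts = np.unique(labels, return_counts=True)
    order = ids[np.lexsort((ids, -counts))]
    mapping = {old: new for new, old in enumerate(order)}
    return np.array([mapping[v] for v in labels], dtype=int)


def cluster_graph(
    embedding: pd.DataFrame, k_neighbors: int = 20, resolution: float = 0.8,
    seed: int = 0,
) -> pd.Series:
    """Graph clustering of a PCA embedding; per-cell integer labels."""
    clu = SNNLeidenClusterer(
        k_neighbors=k_neighbors, resolution=resolution, random_state=seed
    )
    labels = clu.fit_predict(embedding)
    return pd.Series(labels, index=embedding.index, name="cluster")


@dataclass
class SubclusterResult:
    labels: pd.Series
    embedding: pd.DataFrame
    hvgs: list[str]


def subcluster(
    expr: pd.DataFrame, cell_subset, n_hvgs: int = 3000, n_pcs: int = 15,
    k_neighbors: int = 20, resolution: float = 0.8, seed: int = 0,
) -> SubclusterResult:
    """Re-run HVG selection, PCA (default 15 PCs) and graph clustering on a
    cell subset; returns labels, the subset embedding and the subset HVGs."""
    cell_subset = list(cell_subset)
    if not cell_subset:
        raise ValueError("cell subset is empty")
    sub = expr.loc[cell_subset]
    if len(sub) <= k_neighbors:
        raise ValueError("cell subset smaller than k_neighbors")
    hvgs = select_hvgs(sub, n_hvgs)
    emb = run_pca(sub, hvgs, n_pcs=n_pcs, random_state=seed)
    labels = cluster_graph(emb, k_neighbors=k_neighbors,
                           resolution=resolution, seed=seed)
    return SubclusterResult(labels=labels, embedding=emb, hvgs=hvgs)


# --------------------------------------------------------------------------
# marker testing
# --------------------------------------------------------------------------

def find_markers(
    expr: pd.DataFrame, clusters: pd.Series, min_cells: int = 3
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum marker test per cluster and gene.

    Uses the exact null for small tie-free groups and the tie-corrected
    normal approximation otherwise; p values are Bonferroni-adjusted over
    all genes x clusters tested.  Returns rows (gene, cluster, direction,
    mean_diff, p_value, p_adjusted) sorted by adjusted p within cluster.
    Clusters with fewer than ``min_cells`` cells are skipped with a warning.
    """
    clusters = clusters.reindex(expr.index)
    if clusters.isna().any():
        raise ValueError("cluster labels are not aligned to the matrix")
    labels = np.unique(clusters)
    if len(labels) < 2:
        raise ValueError("marker testing needs >= 2 clusters")
    values = expr.to_numpy(dtype=float)
    frames = []
    tested_clusters = []
    for c in labels:
        in_c = (clusters == c).to_numpy()
        if in_c.sum() < min_cells or (~in_c).sum() < min_cells:
            warnings.warn(f"cluster {c} has fewer than {min_cells} cells; skipped")
            continue
        tested_clusters.append(c)
        a, b = values[in_c], values[~in_c]
        res = stats.mannwhitneyu(a, b, axis=0, alternative="two-sided",
                                 method="auto")
        diff = a.mean(axis=0) - b.mean(axis=0)
        frames.append(pd.DataFrame({
            "gene": expr.columns,
            "cluster": c,
            "direction": np.where(diff >= 0, "up", "down"),
            "mean_diff": diff,
            "p_value": res.pvalue,
        }))
    if not frames:
        raise ValueError("no cluster large enough to test")
    table = pd.concat(frames, ignore_index=True)
    n_tests = len(table)
    table["p_adjusted"] = np.minimum(1.0, table["p_value"] * n_tests)
    table = table.sort_values(
        ["cluster", "p_adjusted", "p_value", "gene"], kind="mergesort"
    ).reset_index(drop=True)
    return table
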
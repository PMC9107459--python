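"""Lineage and per-cell pseudotime over cell subclusters: minimum spanning
tree over cluster centroids, the heaviest root-to-leaf path as the lineage,
and a principal-curve refinement whose arc length gives each cell's
pseudotime (distance to the root of the trajectory, min 0).

Single-lineage only: the trajectory is one ordered cluster path; cells in
clusters off the lineage receive undefined (NaN) pseudotime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator

__all__ = [
    "Trajectory",
    "select_root",
    "build_cluster_mst",
    "extract_lineage",
    "PrincipalCurveTrajectory",
    "fit_pseudotime",
]


@dataclass
class Trajectory:
    """Fitted single-lineage trajectory.

    ``pseudotime`` is arc-length distance from the root end of the curve,
    shifted so the minimum over defined cells is 0; NaN off-lineage.
    ``projection_sse_history`` records the total squared projection distance
    after each principal-curve iteration (non-increasing).
    """

    root_cluster: int
    lineage: list[int]
    curve: np.ndarray
    pseudotime: pd.Series
    projection_sse_history: list[float] = field(default_factory=list)


def select_root(clusters: pd.Series, scores: pd.DataFrame) -> int:
    """Root cluster = minimum mean EndMT score (most endothelial state);
    exact ties break toward the smallest label."""
    scores = scores.reindex(clusters.index)
    if scores["endmt_score"].isna().any():
        missing = clusters.index[scores["endmt_score"].isna()][:5]
        raise ValueError(f"EndMT scores missing for cells {list(missing)}")
    if clusters.nunique() < 2:
        raise ValueError("root selection needs >= 2 clusters")
    means = scores.groupby(clusters)["endmt_score"].mean()
    return int(means.sort_index().idxmin())  # idxmin keeps first = smallest label


def _centroids(embedding: pd.DataFrame, clusters: pd.Series) -> pd.DataFrame:
    clusters = clusters.reindex(embedding.index)
    if clusters.isna().any():
        raise ValueError("cluster labels are not aligned to the embedding")
    return embedding.groupby(clusters).mean().sort_index()


def build_cluster_mst(
    embedding: pd.DataFrame, clusters: pd.Series, metric: str = "scaled"
) -> dict[int, dict[int, float]]:
    """Minimum spanning tree over cluster centroids.

    ``metric='scaled'`` (default) measures centroid separation as a
    Mahalanobis-type distance under the average of the two clusters'
    covariances, which discounts embedding dimensions that are mere
    within-cluster spread — on a noisy high-dimensional embedding plain
    centroid distances homogenize and the tree topology becomes fragile.
    ``metric='euclidean'`` uses raw centroid distances.  Returns an
    undirected adjacency mapping ``{label: {label: weight}}``.
    """
    cent = _centroids(embedding, clusters)
    if len(cent) < 2:
        raise ValueError("MST needs >= 2 clusters")
    labels = [int(v) for v in cent.index]
    if metric == "euclidean":
        dist = cdist(cent.to_numpy(), cent.to_numpy())
    elif metric == "scaled":
        dist = _scaled_centroid_distances(embedding, clusters, cent)
    else:
        raise ValueError("metric must be 'scaled' or 'euclidean'")
    mst = minimum_spanning_tree(csr_matrix(dist)).tocoo()
    adj: dict[int, dict[int, float]] = {lab: {} for lab in labels}
    for i, j, w in zip(mst.row, mst.col, mst.data):
        a, b = labels[i], labels[j]
        adj[a][b] = float(w)
        adj[b][a] = float(w)
    return adj


def _scaled_centroid_distances(
    embedding: pd.DataFrame, clusters: pd.Series, cent: pd.DataFrame
) -> np.ndarray:
    """Pairwise Mahalanobis-type centroid distances with averaged
    within-cluster covariances (ridge-regularized for small clusters)."""
    X = embedding.to_numpy(dtype=float)
    clusters = clusters.reindex(embedding.index)
    d = X.shape[1]
    covs = []
    for lab in cent.index:
        sub = X[(clusters == lab).to_numpy()]
        covs.append(
            np.cov(sub.T) if len(sub) > 1 else np.zeros((d, d))
        )
    n = len(cent)
    C = cent.to_numpy()
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            delta = C[i] - C[j]
            S = (covs[i] + covs[j]) / 2.0
            ridge = 1e-8 * max(np.trace(S) / d, 1.0)
            S = S + ridge * np.eye(d)
            dist[i, j] = dist[j, i] = float(
                np.sqrt(delta @ np.linalg.solve(S, delta))
            )
    return dist


def extract_lineage(
    tree: dict[int, dict[int, float]], root: int
) -> list[int]:
    """Heaviest simple path from ``root`` (cumulative edge weight; ties
    break toward the lexicographically smallest label sequence)."""
    if root not in tree:
        raise ValueError(f"root {root} not in tree")
    best_path, best_weight = [root], 0.0
    stack = [(root, [root], 0.0)]
    while stack:
        node, path, weight = stack.pop()
        for nxt in sorted(tree[node]):
            if nxt in path:
                continue
            stack.append((nxt, path + [nxt], weight + tree[node][nxt]))
        if weight > best_weight or (
            weight == best_weight and path < best_path
        ):
            best_path, best_weight = path, weight
    return best_path


class PrincipalCurveTrajectory(BaseEstimator):
    """Principal-curve pseudotime along a cluster lineage.

    The initial curve is the polyline through the lineage cluster centroids
    (root first), densified to ``n_curve_points``.  Each iteration projects
    the lineage cells onto the curve and re-estimates the curve as a smooth
    conditional mean of cell position along arc length; an update is
    accepted only if it lowers the total squared projection distance, so the
    recorded projection error is non-increasing and the fit degrades
    gracefully to the centroid polyline when the smoother cannot follow the
    manifold.  Iteration stops at ``max_iter``, at a relative improvement
    below ``tol``, or at the first rejected update.  Finally both curve ends
    are extended along their terminal directions so every cell projects to
    the curve interior (terminal cells are never clamped onto an endpoint),
    and pseudotime is the arc length of each cell's projection, shifted to
    min 0.

    Two smoothers are available: ``'poly'`` (default) fits each embedding
    coordinate as a low-order polynomial in arc length — stiff, so noise
    dimensions contribute little spurious arc length — while ``'window'``
    is a running mean over an arc-length window of ``window_frac`` times
    the curve length.

    Attributes (after :meth:`fit`): ``trajectory_`` (:class:`Trajectory`),
    ``pseudotime_``.
    """

    def __init__(self, n_curve_points: int = 100, smoother: str = "poly",
                 degree: int = 2, window_frac: float = 0.1,
                 max_iter: int = 10, tol: float = 1e-6):
        self.n_curve_points = n_curve_points
        self.smoother = smoother
        self.degree = degree
        self.window_frac = window_frac
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, embedding: pd.DataFrame, clusters: pd.Series,
            lineage: list[int]) -> "PrincipalCurveTrajectory":
        if not lineage:
            raise ValueError("lineage is empty")
        clusters = clusters.reindex(embedding.index)
        on = clusters.isin(lineage).to_numpy()
        X = embedding.to_numpy(dtype=float)[on]
        if X.shape[0] < 10:
            raise ValueError("fewer than 10 cells on the lineage")

        cent = _centroids(embedding, clusters)
        curve = cent.loc[list(lineage)].to_numpy(dtype=float)
        if len(lineage) == 1:
            raise ValueError("lineage must span >= 2 clusters")
        curve = _densify(curve, self.n_curve_points)

        if self.smoother not in ("poly", "window"):
            raise ValueError("smoother must be 'poly' or 'window'")
        history: list[float] = []
        lam, sse = _project(X, curve)
        history.append(sse)
        for _ in range(self.max_iter):
            if self.smoother == "poly":
                new_curve = _smooth_poly(X, lam, self.n_curve_points,
                                         self.degree)
            else:
                new_curve = _smooth_window(curve, X, lam, self.window_frac)
            if len(new_curve) < 2:
                break
            new_curve = _densify(new_curve, self.n_curve_points)
            new_lam, new_sse = _project(X, new_curve)
            if new_sse > history[-1]:
                break  # discard the worsening update
            curve, lam = new_curve, new_lam
            improved = history[-1] - new_sse
            history.append(new_sse)
            if improved <= self.tol * max(history[0], 1e-300):
                break

        # one final end extension so terminal cells project to the curve
        # interior instead of clamping onto the endpoints
        curve = _extend_ends(curve, X)
        lam, _ = _project(X, curve)

        pt = np.full(len(embedding), np.nan)
        pt[on] = lam - lam.min()
        pseudotime = pd.Series(pt, index=embedding.index, name="pseudotime")
        self.trajectory_ = Trajectory(
            root_cluster=int(lineage[0]),
            lineage=[int(v) for v in lineage],
            curve=curve,
            pseudotime=pseudotime,
            projection_sse_history=history,
        )
        self.pseudotime_ = pseudotime
        return self


def fit_pseudotime(
    embedding: pd.DataFrame, clusters: pd.Series, lineage: list[int],
    **kwargs,
) -> Trajectory:
    """Fit the principal curve along ``lineage`` and return the
    :class:`Trajectory` (per-cell pseudotime = distance to root)."""
    est = PrincipalCurveTrajectory(**kwargs)
    est.fit(embedding, clusters, lineage)
    return est.trajectory_


# --------------------------------------------------------------------------
# geometry helpers
# --------------------------------------------------------------------------

def _arc_lengths(curve: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(curve, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _densify(curve: np.ndarray, n_points: int) -> np.ndarray:
    """Resample a polyline at ``n_points`` equal arc-length stations."""
    arcs = _arc_lengths(curve)
    total = arcs[-1]
    if total == 0:
        raise ValueError("degenerate zero-length curve")
    stations = np.linspace(0.0, total, n_points)
    out = np.empty((n_points, curve.shape[1]))
    for d in range(curve.shape[1]):
        out[:, d] = np.interp(stations, arcs, curve[:, d])
    return out


def _extend_ends(curve: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Extend both terminal segments so every cell projects to the curve
    interior (clamping would otherwise distort terminal pseudotimes)."""
    curve = curve.copy()
    for endpoint, inner, prepend in ((0, 1, True), (-1, -2, False)):
        v = curve[endpoint] - curve[inner]
        norm = np.linalg.norm(v)
        if norm == 0:
            continue
        v = v / norm
        overshoot = ((X - curve[endpoint]) @ v).max()
        if overshoot > 0:
            ext = curve[endpoint] + v * (overshoot + 1e-9)
            curve = (
                np.vstack([ext, curve]) if prepend else np.vstack([curve, ext])
            )
    return curve


def _project(X: np.ndarray, curve: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact orthogonal projection of each cell onto the polyline.

    Returns per-cell arc-length coordinates and the total squared
    projection distance.
    """
    A = curve[:-1]  # segment starts (P-1, d)
    B = curve[1:]
    U = B - A
    L = np.linalg.norm(U, axis=1)
    keep = L > 0
    A, U, L = A[keep], U[keep], L[keep]
    arcs = _arc_lengths(curve)[:-1][keep]
    # (n, p) projection parameter per segment
    diff = X[:, None, :] - A[None, :, :]
    t = np.clip(
        np.einsum("npd,pd->np", diff, U) / (L**2)[None, :], 0.0, 1.0
    )
    proj = A[None, :, :] + t[:, :, None] * U[None, :, :]
    d2 = ((X[:, None, :] - proj) ** 2).sum(axis=2)
    best = d2.argmin(axis=1)
    rows = np.arange(len(X))
    lam = arcs[best] + t[rows, best] * L[best]
    return lam, float(d2[rows, best].sum())


def _smooth_poly(
    X: np.ndarray, lam: np.ndarray, n_points: int, degree: int
) -> np.ndarray:
    """Re-estimate the curve by per-coordinate polynomial regression of cell
    position on arc length (a stiff smoother; exact for straight data)."""
    V = np.vander(lam, degree + 1)
    beta, *_ = np.linalg.lstsq(V, X, rcond=None)
    stations = np.linspace(lam.min(), lam.max(), n_points)
    out = np.vander(stations, degree + 1) @ beta
    keep = np.ones(len(out), bool)
    keep[1:] = np.linalg.norm(np.diff(out, axis=0), axis=1) > 0
    return out[keep]


def _smooth_window(
    curve: np.ndarray, X: np.ndarray, lam: np.ndarray, window_frac: float
) -> np.ndarray:
    """Re-estimate the curve as local means of cells along arc length."""
    total = _arc_lengths(curve)[-1]
    window = max(window_frac * total, 1e-12)
    stations = np.linspace(lam.min(), lam.max(), len(curve))
    out = np.empty((len(stations), X.shape[1]))
    for i, s in enumerate(stations):
        sel = np.abs(lam - s) <= window
        if not sel.any():
            sel = np.abs(lam - s) <= 2 * window
        out[i] = X[sel].mean(axis=0) if sel.any() else curve[i]
    # drop consecutive duplicates that would create zero-length segments
    keep = np.ones(len(out), bool)
    keep[1:] = np.linalg.norm(np.diff(out, axis=0), axis=1) > 0
    out = out[keep]
    if len(out) < 2:
        return curve
    return out
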
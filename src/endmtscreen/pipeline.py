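"""End-to-end regulator screen: QC -> clustering -> EndMT scoring ->
EC subclustering -> trajectory -> regulon activity -> Pearson screen.

This chains the per-stage estimators in the order the analysis prescribes
and keeps every intermediate on the result object so each stage can be
inspected or re-run with different parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qc import (QCThresholds, compute_cell_metrics, filter_cells_genes,
                 doublet_scores, remove_doublets)
from .preprocess import (normalize_log, select_hvgs, run_pca, cluster_graph,
                         subcluster, SubclusterResult)
from .signatures import GeneSignature, endmt_score
from .regulons import Regulon, aucell_activity, correlate_activity_pseudotime
from .trajectory import (Trajectory, select_root, build_cluster_mst,
                         extract_lineage, fit_pseudotime)

__all__ = ["ScreenResult", "run_endmt_screen", "select_ec_clusters"]


@dataclass
class ScreenResult:
    """All intermediates of one end-to-end screen run."""

    qc_metrics: pd.DataFrame
    doublet_scores: pd.Series
    counts_clean: pd.DataFrame
    expr: pd.DataFrame
    embedding: pd.DataFrame
    clusters: pd.Series
    scores: pd.DataFrame
    ec_clusters: list[int]
    sub: SubclusterResult
    trajectory: Trajectory
    activity: pd.DataFrame
    screen: pd.DataFrame


def select_ec_clusters(
    clusters: pd.Series, scores: pd.DataFrame
) -> list[int]:
    """Pick the endothelial cluster group by the largest gap in cluster-mean
    endothelial score.

    Cluster means of the endothelial score are sorted; the clusters above
    the single largest gap form the endothelial (EC) group.  With one
    cluster, that cluster is returned.
    """
    means = scores.groupby(clusters)["endothelial_score"].mean().sort_values(
        ascending=False
    )
    if len(means) == 1:
        return [int(means.index[0])]
    gaps = -np.diff(means.to_numpy())
    cut = int(np.argmax(gaps)) + 1
    return [int(v) for v in means.index[:cut]]


def run_endmt_screen(
    counts: pd.DataFrame,
    mes: GeneSignature,
    endo: GeneSignature,
    regulons: list[Regulon],
    *,
    thresholds: QCThresholds | None = None,
    mito_prefix: str = "mt-",
    n_hvgs: int = 3000,
    n_pcs: int = 20,
    sub_n_pcs: int = 15,
    k_neighbors: int = 20,
    resolution: float = 0.8,
    sub_resolution: float = 0.8,
    top_fraction: float = 0.05,
    doublet_k: int = 60,
    seed: int = 0,
) -> ScreenResult:
    """Run the full EndMT regulator screen on a raw UMI count matrix.

    The stages mirror the single-cell analysis contract: gene/cell QC
    filtering, simulated-doublet removal (cutoff from ``thresholds``),
    log normalization, HVG selection, PCA (``n_pcs``), SNN-Leiden
    clustering, per-cell EndMT scoring, endothelial-cluster selection,
    subclustering at ``sub_n_pcs`` PCs, centroid-MST + principal-curve
    pseudotime rooted at the most endothelial subcluster, AUCell regulon
    activity on the EC cells, and the Pearson activity-vs-pseudotime
    screen ranked by ascending r.
    """
    if thresholds is None:
        thresholds = QCThresholds()

    metrics = compute_cell_metrics(counts, mito_prefix)
    filtered = filter_cells_genes(counts, metrics, thresholds)
    dscores = doublet_scores(filtered, n_pcs=n_pcs, k=doublet_k, seed=seed)
    clean = remove_doublets(filtered, dscores, thresholds.doublet_cutoff)

    expr = normalize_log(clean)
    hvgs = select_hvgs(expr, n_hvgs)
    embedding = run_pca(expr, hvgs, n_pcs=n_pcs, random_state=seed)
    clusters = cluster_graph(embedding, k_neighbors=k_neighbors,
                             resolution=resolution, seed=seed)
    scores = endmt_score(expr, mes, endo)

    ec = select_ec_clusters(clusters, scores)
    ec_cells = clusters.index[clusters.isin(ec)]
    sub = subcluster(expr, ec_cells, n_hvgs=n_hvgs, n_pcs=sub_n_pcs,
                     k_neighbors=k_neighbors, resolution=sub_resolution,
                     seed=seed)

    if sub.labels.nunique() >= 2:
        root = select_root(sub.labels, scores.loc[ec_cells])
        mst = build_cluster_mst(sub.embedding, sub.labels)
        lineage = extract_lineage(mst, root)
    else:
        # degenerate single subcluster: orient along the EndMT score by
        # splitting at the median score so a lineage still exists
        median = scores.loc[ec_cells, "endmt_score"].median()
        sub.labels = pd.Series(
            (scores.loc[ec_cells, "endmt_score"] > median).astype(int),
            index=sub.labels.index,
        )
        lineage = [0, 1]
    traj = fit_pseudotime(sub.embedding, sub.labels, lineage)

    activity = aucell_activity(expr.loc[ec_cells], regulons,
                               top_fraction=top_fraction, seed=seed)
    screen = correlate_activity_pseudotime(activity, traj.pseudotime)

    return ScreenResult(
        qc_metrics=metrics,
        doublet_scores=dscores,
        counts_clean=clean,
        expr=expr,
        embedding=embedding,
        clusters=clusters,
        scores=scores,
        ec_clusters=ec,
        sub=sub,
        trajectory=traj,
        activity=activity,
        screen=screen,
    )
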
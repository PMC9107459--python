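"""Normalization, HVG selection, PCA, clustering and marker testing."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

import endmtscreen as es


# ----------------------------------------------------------------------
# normalization
# ----------------------------------------------------------------------

def test_normalize_log_closed_form():
    counts = pd.DataFrame({"a": [1, 10], "b": [99, 90]}, index=["c1", "c2"])
    expr = es.normalize_log(counts, scale=1e4)
    # library 100, count 1, scale 1e4 -> log1p(100)
    assert expr.loc["c1", "a"] == pytest.approx(np.log1p(100.0))
    assert (expr.to_numpy()[counts.to_numpy() == 0] == 0).all() if (
        counts.to_numpy() == 0).any() else True
    # per-cell linear sums equal the scale
    sums = np.expm1(expr).sum(axis=1)
    assert np.allclose(sums, 1e4)


def test_normalize_log_monotone_per_cell(rng):
    counts = pd.DataFrame(rng.integers(0, 50, (5, 40)))
    expr = es.normalize_log(counts)
    for i in range(5):
        order = np.argsort(counts.iloc[i].to_numpy(), kind="stable")
        assert (np.diff(expr.iloc[i].to_numpy()[order]) >= -1e-12).all()
    assert (expr.to_numpy()[counts.to_numpy() == 0] == 0).all()


def test_normalize_log_zero_library_errors():
    counts = pd.DataFrame({"a": [1, 0], "b": [2, 0]})
    with pytest.raises(ValueError, match="zero-library"):
        es.normalize_log(counts)


# ----------------------------------------------------------------------
# HVG selection
# ----------------------------------------------------------------------

def test_hvg_saturation_returns_all_genes(rng):
    expr = pd.DataFrame(rng.random((30, 12)),
                        columns=[f"g{i}" for i in range(12)])
    assert set(es.select_hvgs(expr, 50)) == set(expr.columns)


def test_hvg_ranks_planted_programs_above_background(small_sim):
    _, counts, truth = small_sim
    keep = ~truth.cells.is_low_quality
    expr = es.normalize_log(counts.loc[keep.index[keep]])
    ranked = es.select_hvgs(expr, len(expr.columns))
    rank = pd.Series(np.arange(len(ranked)), index=ranked)
    program = truth.genes["program"]
    planted_rank = rank[program.isin({"endothelial", "mesenchymal"})]
    background_rank = rank[program == "background"]
    # transition-swing genes rank far above flat background genes
    assert planted_rank.median() < 0.6 * background_rank.median()
    assert (planted_rank < background_rank.median()).mean() > 0.8


def test_hvg_fallback_warns_below_ten_genes(rng):
    expr = pd.DataFrame(rng.random((20, 5)))
    with pytest.warns(UserWarning, match="variance ranking"):
        hvgs = es.select_hvgs(expr, 3)
    assert len(hvgs) == 3


# ----------------------------------------------------------------------
# PCA
# ----------------------------------------------------------------------

def test_pca_rank_deficiency_and_reconstruction(rng):
    base = rng.normal(size=(40, 2))
    X = pd.DataFrame(base @ rng.normal(size=(2, 10)),
                     columns=[f"g{i}" for i in range(10)])
    emb = es.PCAEmbedder(n_components=6, max_value=100.0)
    coords = emb.fit_transform(X)
    var = emb.explained_variance_
    assert (np.diff(var) <= 1e-9).all()
    assert var[2:].max() < 1e-20 * var[0]
    # full-rank reconstruction identity (no clipping at high max_value)
    full = es.PCAEmbedder(n_components=10, max_value=1e9)
    coords = full.fit_transform(X)
    scaled = (X.to_numpy() - full.mean_) / full.sd_
    assert np.allclose(full.inverse_transform(coords), scaled, atol=1e-8)


def test_pca_deterministic_sign_convention(rng):
    X = pd.DataFrame(rng.normal(size=(50, 8)))
    e1 = es.PCAEmbedder(n_components=4).fit(X)
    for c in range(4):
        load = e1._pca.components_[c]
        assert load[np.argmax(np.abs(load))] > 0


def test_pca_rejects_too_many_components(rng):
    X = pd.DataFrame(rng.normal(size=(5, 8)))
    with pytest.raises(ValueError, match="n_components"):
        es.PCAEmbedder(n_components=6).fit(X)


# ----------------------------------------------------------------------
# graph clustering
# ----------------------------------------------------------------------

@pytest.mark.parametrize("resolution", [0.4, 0.8, 1.2])
def test_two_blobs_recovered_exactly(rng, resolution):
    blob1 = rng.normal(0, 1, size=(100, 5))
    blob2 = rng.normal(12, 1, size=(100, 5))
    emb = pd.DataFrame(np.vstack([blob1, blob2]))
    # neighbourhood must be sized to the blob: k far below the blob size
    # under-connects homogeneous blobs and fragments them at high resolution
    labels = es.cluster_graph(emb, k_neighbors=35, resolution=resolution,
                              seed=0)
    true = np.array([0] * 100 + [1] * 100)
    assert adjusted_rand_score(true, labels) == 1.0


def test_identical_cells_form_one_cluster():
    emb = pd.DataFrame(np.zeros((60, 4)))
    labels = es.cluster_graph(emb, k_neighbors=10, seed=0)
    assert labels.nunique() == 1


def test_clustering_deterministic_under_seed(rng):
    emb = pd.DataFrame(rng.normal(size=(150, 6)))
    l1 = es.cluster_graph(emb, seed=5)
    l2 = es.cluster_graph(emb, seed=5)
    assert adjusted_rand_score(l1, l2) == 1.0
    assert (l1 == l2).all()
    # labels contiguous from zero, ordered by size
    sizes = l1.value_counts().sort_index()
    assert list(sizes.index) == list(range(l1.nunique()))
    assert (np.diff(sizes.to_numpy()) <= 0).all()


def test_cluster_parameter_errors(rng):
    emb = pd.DataFrame(rng.normal(size=(30, 3)))
    with pytest.raises(ValueError):
        es.cluster_graph(emb, k_neighbors=1)
    with pytest.raises(ValueError):
        es.cluster_graph(emb, k_neighbors=30)


def test_subcluster_of_everything_matches_top_level(continuum_expr):
    _, expr, _, _ = continuum_expr
    top = es.cluster_graph(
        es.run_pca(expr, es.select_hvgs(expr, 500), n_pcs=15, random_state=0),
        seed=0,
    )
    sub = es.subcluster(expr, expr.index, n_hvgs=500, n_pcs=15, seed=0)
    assert adjusted_rand_score(top, sub.labels) == 1.0


def test_subcluster_validates_subset(continuum_expr):
    _, expr, _, _ = continuum_expr
    with pytest.raises(ValueError):
        es.subcluster(expr, [])
    with pytest.raises(ValueError):
        es.subcluster(expr, expr.index[:5], k_neighbors=20)


# ----------------------------------------------------------------------
# marker testing
# ----------------------------------------------------------------------

def _exact_wilcoxon_p(x, y):
    """Enumeration oracle: two-sided rank-sum p over all group assignments."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n_x = len(x)
    observed = ranks[:n_x].sum()
    mean = n_x * (len(pooled) + 1) / 2.0
    count = 0
    total = 0
    for comb in itertools.combinations(range(len(pooled)), n_x):
        s = ranks[list(comb)].sum()
        if abs(s - mean) >= abs(observed - mean) - 1e-12:
            count += 1
        total += 1
    return count / total


def test_wilcoxon_matches_exact_enumeration(rng):
    for _ in range(5):
        x = rng.normal(size=6)
        y = rng.normal(size=7)
        expr = pd.DataFrame({"g": np.concatenate([x, y])})
        labels = pd.Series([0] * 6 + [1] * 7, index=expr.index)
        table = es.find_markers(expr, labels, min_cells=3)
        got = table[table.cluster == 0].p_value.iloc[0]
        assert got == pytest.approx(_exact_wilcoxon_p(x, y), abs=1e-9)


def test_exclusive_gene_is_top_marker(rng):
    n = 60
    expr = pd.DataFrame(rng.random((n, 20)) * 0.01,
                        columns=[f"g{i}" for i in range(20)])
    labels = pd.Series([0] * 30 + [1] * 30, index=expr.index)
    expr.loc[labels == 0, "g7"] += 5.0
    table = es.find_markers(expr, labels)
    top_a = table[table.cluster == 0].iloc[0]
    assert top_a.gene == "g7" and top_a.direction == "up"


def test_bonferroni_adjustment_and_sorting(rng):
    expr = pd.DataFrame(rng.normal(size=(40, 30)))
    labels = pd.Series([0] * 20 + [1] * 20)
    table = es.find_markers(expr, labels)
    n_tests = len(table)
    assert np.allclose(table.p_adjusted,
                       np.minimum(1.0, table.p_value * n_tests))
    for _, grp in table.groupby("cluster"):
        assert (np.diff(grp.p_adjusted.to_numpy()) >= -1e-15).all()


def test_small_cluster_skipped_with_warning(rng):
    expr = pd.DataFrame(rng.normal(size=(23, 5)))
    labels = pd.Series([0] * 10 + [1] * 11 + [2] * 2)
    with pytest.warns(UserWarning, match="skipped"):
        table = es.find_markers(expr, labels)
    assert set(table.cluster) == {0, 1}
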
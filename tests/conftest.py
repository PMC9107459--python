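import numpy as np
import pytest

import endmtscreen as es


@pytest.fixture(scope="session")
def small_sim():
    """Small planted-transition dataset shared across read-only tests."""
    cfg = es.SimConfig(n_cells=600, n_genes=800, seed=7)
    counts, truth = es.simulate_transition_dataset(cfg)
    return cfg, counts, truth


@pytest.fixture(scope="session")
def qc_fixture():
    """QC benchmark: 100 clean (two clusters) + 10 low-quality +
    5 high-complexity + 20 cross-cluster doublets."""
    counts, truth = es.make_qc_fixture(seed=3)
    return counts, truth


@pytest.fixture(scope="session")
def continuum_expr():
    """Pure-continuum dataset, normalized, with an embedding and clusters."""
    cfg = es.SimConfig(n_cells=700, n_genes=800, transition_fraction=1.0,
                       doublet_rate=0.0, lowq_rate=0.0, seed=11)
    counts, truth = es.simulate_transition_dataset(cfg)
    expr = es.normalize_log(counts)
    emb = es.run_pca(expr, es.select_hvgs(expr, 500), n_pcs=15, random_state=0)
    labels = es.cluster_graph(emb, seed=0)
    return truth, expr, emb, labels


@pytest.fixture
def rng():
    return np.random.default_rng(0)
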
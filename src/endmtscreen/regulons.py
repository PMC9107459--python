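"""Rank-based regulon activity (the AUCell mechanism, re-implemented) and
the Pearson screen of activity against pseudotime.

Per cell, all genes are ranked by decreasing expression (ties broken by a
seeded random permutation fixed per cell).  A regulon's recovery curve
counts how many of its genes fall within the top ``k`` ranks for
``k = 1..T`` where ``T = ceil(top_fraction * n_genes)``; the activity score
is the area under this curve divided by the maximal achievable area (the
regulon's scored genes occupying the very top ranks), so activities lie in
``[0, 1]``.  The screen correlates each regulon's activity vector with
pseudotime (Pearson, two-sided t-test p, Benjamini-Hochberg q) and ranks
regulons by ascending r so the strongest negative regulators come first.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.multitest import multipletests

from . import signatures as _sig

__all__ = [
    "Regulon",
    "AUCellScorer",
    "aucell_activity",
    "correlate_activity_pseudotime",
    "load_regulons_gmt",
    "write_regulons_gmt",
]


@dataclass(frozen=True)
class Regulon:
    """A transcription factor with its target gene set (TF included)."""

    tf_name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"regulon {self.tf_name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"regulon {self.tf_name!r} contains duplicates")

    def __len__(self) -> int:
        return len(self.genes)


def _rank_matrix(
    X: np.ndarray, tie_method: str, rng: np.random.Generator
) -> np.ndarray:
    """1-based ranks of genes per cell (row), highest expression = rank 1.

    ``tie_method='random'`` breaks ties with a seeded random key drawn once
    per cell; ``'average'`` assigns average ranks (for exact comparison with
    tie-free oracles either mode coincides).
    """
    n_cells, n_genes = X.shape
    if tie_method == "average":
        return stats.rankdata(-X, method="average", axis=1)
    if tie_method != "random":
        raise ValueError("tie_method must be 'random' or 'average'")
    ranks = np.empty((n_cells, n_genes), dtype=np.int32)
    keys = rng.random((n_cells, n_genes))
    ar = np.arange(1, n_genes + 1, dtype=np.int32)
    for i in range(n_cells):
        order = np.lexsort((keys[i], -X[i]))
        ranks[i, order] = ar
    return ranks


class AUCellScorer(BaseEstimator, TransformerMixin):
    """Per-cell regulon activity by normalized recovery-curve AUC.

    Parameters
    ----------
    regulons:
        Gene sets to score (TF plus targets, scored as one set).
    top_fraction:
        Fraction of the ranked gene list forming the scoring window
        (default 0.05).
    tie_method:
        'random' (seeded, default) or 'average' rank ties.
    random_state:
        Seed for tie-breaking.
    """

    def __init__(self, regulons, top_fraction: float = 0.05,
                 tie_method: str = "random", random_state: int = 0):
        self.regulons = regulons
        self.top_fraction = top_fraction
        self.tie_method = tie_method
        self.random_state = random_state

    def fit(self, X: pd.DataFrame, y=None) -> "AUCellScorer":
        if not 0.0 < self.top_fraction <= 1.0:
            raise ValueError("top_fraction must lie in (0, 1]")
        if not isinstance(X, pd.DataFrame):
            raise TypeError("expression input must be a DataFrame")
        col_index = {g: j for j, g in enumerate(X.columns)}
        self.gene_indices_ = []
        any_present = False
        for reg in self.regulons:
            idx = np.array(
                [col_index[g] for g in reg.genes if g in col_index], dtype=int
            )
            if idx.size == 0:
                warnings.warn(
                    f"regulon {reg.tf_name!r} has no gene in the matrix; "
                    "its activity will be all zero"
                )
            else:
                any_present = True
            self.gene_indices_.append(idx)
        if not any_present:
            raise ValueError("no regulon gene present in the matrix")
        self.n_genes_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "gene_indices_"):
            self.fit(X)
        values = X.to_numpy(dtype=float)
        n_cells, n_genes = values.shape
        T = int(np.ceil(self.top_fraction * n_genes))
        rng = np.random.default_rng(self.random_state)
        ranks = _rank_matrix(values, self.tie_method, rng)
        out = np.zeros((n_cells, len(self.regulons)))
        for j, idx in enumerate(self.gene_indices_):
            if idx.size == 0:
                continue
            m = min(idx.size, T)
            max_area = (T * m) - (m * (m - 1)) // 2  # genes at ranks 1..m
            contrib = np.clip(T - ranks[:, idx] + 1.0, 0.0, None).sum(axis=1)
            out[:, j] = contrib / max_area
        return pd.DataFrame(
            out, index=X.index,
            columns=[reg.tf_name for reg in self.regulons],
        )


def aucell_activity(
    expr: pd.DataFrame, regulons, top_fraction: float = 0.05,
    seed: int = 0, tie_method: str = "random",
) -> pd.DataFrame:
    """Functional wrapper over :class:`AUCellScorer` (cells x regulons)."""
    scorer = AUCellScorer(regulons, top_fraction=top_fraction,
                          tie_method=tie_method, random_state=seed)
    return scorer.fit(expr).transform(expr)


def correlate_activity_pseudotime(
    activity: pd.DataFrame, pseudotime: pd.Series
) -> pd.DataFrame:
    """Pearson screen of regulon activity against pseudotime.

    Cells with undefined (NaN) pseudotime are dropped pairwise.  Returns one
    row per regulon with ``pearson_r``, two-sided ``p_value`` (t-distribution,
    n-2 df), Benjamini-Hochberg ``q_value`` and ``rank`` by ascending r, so
    the strongest negative regulators rank first.  Constant activity vectors
    yield undefined r/p, are excluded from the q computation and sort last.
    """
    pt = pseudotime.reindex(activity.index)
    mask = pt.notna().to_numpy()
    if mask.sum() < 3:
        raise ValueError("need >= 3 cells with defined pseudotime")
    y = pt.to_numpy(dtype=float)[mask]
    rows = []
    for tf in activity.columns:
        x = activity[tf].to_numpy(dtype=float)[mask]
        if np.std(x) == 0.0 or np.std(y) == 0.0:
            rows.append((tf, np.nan, np.nan))
            continue
        r, p = stats.pearsonr(x, y)
        rows.append((tf, r, p))
    res = pd.DataFrame(rows, columns=["tf_name", "pearson_r", "p_value"])
    res["q_value"] = np.nan
    valid = res["p_value"].notna()
    if valid.any():
        res.loc[valid, "q_value"] = multipletests(
            res.loc[valid, "p_value"], method="fdr_bh"
        )[1]
    res = res.sort_values(
        "pearson_r", na_position="last", kind="mergesort"
    ).reset_index(drop=True)
    res["rank"] = np.arange(1, len(res) + 1)
    return res


def load_regulons_gmt(path) -> list[Regulon]:
    """Read regulons from a GMT file (one TF per line: name, desc, genes)."""
    return [Regulon(name, genes) for name, _, genes in _sig.read_gmt(path)]


def write_regulons_gmt(path, regulons: list[Regulon]) -> None:
    _sig.write_gmt(path, [(r.tf_name, "na", r.genes) for r in regulons])
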
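"""Reading and writing the pipeline's on-disk formats.

Count matrices follow the 10x CellRanger directory convention: a Matrix
Market file with genes as rows and cells as columns, plus ``genes.tsv`` and
``barcodes.tsv``.  In memory the package uses the sklearn sample-major
orientation (cells x genes DataFrame), so readers/writers transpose.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = ["read_mtx_dir", "write_mtx_dir", "read_tsv_matrix",
           "write_tsv_matrix"]


def read_mtx_dir(path) -> pd.DataFrame:
    """Read a 10x-style directory (matrix.mtx, genes.tsv, barcodes.tsv)
    into a cells x genes integer DataFrame."""
    path = Path(path)
    mat = spio.mmread(path / "matrix.mtx")
    genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0]
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0]
    dense = np.asarray(
        mat.todense() if sparse.issparse(mat) else mat
    )
    if dense.shape != (len(genes), len(barcodes)):
        raise ValueError(
            f"matrix shape {dense.shape} does not match "
            f"{len(genes)} genes x {len(barcodes)} barcodes"
        )
    return pd.DataFrame(
        dense.T.astype(np.int64),
        index=pd.Index(barcodes, name="cell_id"),
        columns=pd.Index(genes, name="gene_id"),
    )


def write_mtx_dir(path, counts: pd.DataFrame,
                  cell_labels: pd.Series | None = None,
                  ground_truth: pd.DataFrame | None = None) -> None:
    """Write a cells x genes count DataFrame as a 10x-style directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(
        path / "matrix.mtx",
        sparse.csr_matrix(counts.to_numpy().T),
        field="integer",
    )
    pd.Series(counts.columns).to_csv(
        path / "genes.tsv", sep="\t", header=False, index=False
    )
    pd.Series(counts.index).to_csv(
        path / "barcodes.tsv", sep="\t", header=False, index=False
    )
    if cell_labels is not None:
        cell_labels.rename("label").to_csv(path / "cell_labels.tsv", sep="\t")
    if ground_truth is not None:
        ground_truth.to_csv(path / "ground_truth.tsv", sep="\t")


def read_tsv_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_tsv_matrix(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t")
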
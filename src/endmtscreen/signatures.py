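"""EndMT signature scoring: endothelial score, mesenchymal score, and their
difference (the EndMT score), plus the z-scored heatmap matrix.

Scores are geometric means computed on the log scale: the score of a gene set
in one cell or sample is the arithmetic mean of its log-scale expression
values, which equals the log of the geometric mean of the pseudocounted
linear values.  The EndMT score is the mesenchymal score minus the
endothelial score — on the log scale this is identically the log of the
ratio of the two geometric means, so the "difference" and "ratio" phrasings
of the statistic coincide.  Higher score = more mesenchymal-like phenotype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "GeneSignature",
    "ENDOTHELIAL_SIGNATURE",
    "MESENCHYMAL_SIGNATURE",
    "geometric_mean_score",
    "endmt_score",
    "zscore_matrix",
    "EndMTScorer",
    "read_gmt",
    "write_gmt",
]


@dataclass(frozen=True)
class GeneSignature:
    """A named, duplicate-free, non-empty gene set."""

    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"signature {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"signature {self.name!r} contains duplicates")

    def __len__(self) -> int:
        return len(self.genes)


#: Fixed mesenchymal signature (11 genes) of the EndMT score.
MESENCHYMAL_SIGNATURE = GeneSignature(
    "mesenchymal",
    ("Cnn1", "Fap", "S100a4", "Tagln", "Fn1", "Vim",
     "Col1a2", "Col1a1", "Col3a1", "Cdh2", "Acta2"),
)

#: Fixed endothelial signature (6 genes) of the EndMT score.
ENDOTHELIAL_SIGNATURE = GeneSignature(
    "endothelial", ("Cdh5", "Cldn5", "Tek", "Pecam1", "Tjp1", "Vwf")
)


def _match_genes(columns: pd.Index, signature: GeneSignature) -> list:
    """Case-insensitive signature-gene lookup; returns matched column labels.

    Gene symbols are matched case-insensitively so mouse-style (Cdh5) and
    human-style (CDH5) identifiers both resolve; case-fold collisions among
    matrix columns are reported and the first occurrence is used.
    """
    lower_map: dict[str, object] = {}
    collisions = set()
    for col in columns:
        key = str(col).lower()
        if key in lower_map:
            collisions.add(key)
        else:
            lower_map[key] = col
    matched = []
    for g in signature.genes:
        key = g.lower()
        if key in lower_map:
            if key in collisions:
                warnings.warn(
                    f"gene symbol {g!r} matches multiple columns "
                    "case-insensitively; using the first occurrence"
                )
            matched.append(lower_map[key])
    return matched


def geometric_mean_score(
    expr: pd.DataFrame | pd.Series, signature: GeneSignature
) -> pd.Series | float:
    """Log-scale geometric-mean score of ``signature`` per row of ``expr``.

    ``expr`` holds log-scale expression (units x genes, or a single unit as
    a Series).  Signature genes missing from the matrix are dropped; if none
    is present a ``KeyError`` names the missing set.
    """
    single = isinstance(expr, pd.Series)
    frame = expr.to_frame().T if single else expr
    matched = _match_genes(frame.columns, signature)
    if not matched:
        raise KeyError(
            f"no gene of signature {signature.name!r} found in the matrix; "
            f"missing: {sorted(signature.genes)}"
        )
    scores = frame[matched].mean(axis=1)
    return float(scores.iloc[0]) if single else scores


def endmt_score(
    expr: pd.DataFrame,
    mes: GeneSignature = MESENCHYMAL_SIGNATURE,
    endo: GeneSignature = ENDOTHELIAL_SIGNATURE,
) -> pd.DataFrame:
    """Per-unit EndMT score table over a log-scale expression matrix.

    Returns a DataFrame indexed like ``expr`` with columns
    ``endothelial_score``, ``mesenchymal_score``,
    ``endmt_score`` (= mesenchymal - endothelial, exactly), and the number
    of signature genes actually present and used for each set.
    """
    mes_cols = _match_genes(expr.columns, mes)
    endo_cols = _match_genes(expr.columns, endo)
    if not mes_cols:
        raise KeyError(f"no gene of signature {mes.name!r} present")
    if not endo_cols:
        raise KeyError(f"no gene of signature {endo.name!r} present")
    mes_score = expr[mes_cols].mean(axis=1)
    endo_score = expr[endo_cols].mean(axis=1)
    return pd.DataFrame(
        {
            "endothelial_score": endo_score,
            "mesenchymal_score": mes_score,
            "endmt_score": mes_score - endo_score,
            "n_genes_used_endo": len(endo_cols),
            "n_genes_used_mes": len(mes_cols),
        },
        index=expr.index,
    )


class EndMTScorer(BaseEstimator, TransformerMixin):
    """Transformer computing the EndMT score table for cells or samples.

    Parameters
    ----------
    mes, endo:
        Mesenchymal and endothelial gene signatures; defaults are the fixed
        11-gene and 6-gene EndMT panels.
    """

    def __init__(self, mes: GeneSignature = MESENCHYMAL_SIGNATURE,
                 endo: GeneSignature = ENDOTHELIAL_SIGNATURE):
        self.mes = mes
        self.endo = endo

    def fit(self, X: pd.DataFrame, y=None) -> "EndMTScorer":
        X = _as_frame(X)
        self.mes_genes_used_ = tuple(_match_genes(X.columns, self.mes))
        self.endo_genes_used_ = tuple(_match_genes(X.columns, self.endo))
        if not self.mes_genes_used_ or not self.endo_genes_used_:
            missing = self.mes if not self.mes_genes_used_ else self.endo
            raise KeyError(f"no gene of signature {missing.name!r} present")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if not hasattr(self, "mes_genes_used_"):
            self.fit(X)
        return endmt_score(_as_frame(X), self.mes, self.endo)


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    raise TypeError("expression input must be a pandas DataFrame "
                    "with gene identifiers as columns")


def zscore_matrix(
    expr: pd.DataFrame, genes: list[str] | tuple[str, ...] | None = None,
    ddof: int = 0,
) -> pd.DataFrame:
    """Row-wise z-score matrix (genes x samples) of log-scale expression.

    ``expr`` is samples x genes; the output transposes to the heatmap
    orientation with rows in the order of ``genes`` (default: endothelial
    block then mesenchymal block of the fixed EndMT panel).  Each row is
    centred and scaled by its population standard deviation (``ddof=0``);
    zero-variance rows become all-zero with a warning rather than NaN.
    """
    if genes is None:
        genes = list(ENDOTHELIAL_SIGNATURE.genes) + list(
            MESENCHYMAL_SIGNATURE.genes
        )
    if expr.shape[0] < 2:
        raise ValueError("z-scoring needs >= 2 samples")
    cols = []
    for g in genes:
        matched = _match_genes(expr.columns, GeneSignature(g, (g,)))
        if not matched:
            raise KeyError(f"gene {g!r} not present in the matrix")
        cols.append(matched[0])
    sub = expr[cols].T.to_numpy(dtype=float)  # genes x samples
    mean = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=ddof, keepdims=True)
    flat = sd[:, 0] == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance gene row(s) set to zero"
        )
        sd[flat] = 1.0
    z = (sub - mean) / sd
    z[flat] = 0.0
    return pd.DataFrame(z, index=pd.Index(genes, name="gene"),
                        columns=expr.index)


# --------------------------------------------------------------------------
# GMT I/O (one gene set per line: name <tab> description <tab> genes...)
# --------------------------------------------------------------------------

def read_gmt(path) -> list[tuple[str, str, tuple[str, ...]]]:
    """Parse a GMT file into ``(name, description, genes)`` tuples.

    Duplicate genes within a line are removed (first occurrence kept) with a
    warning; a line with fewer than three fields is a parse error naming the
    line number.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: malformed GMT line {lineno}: "
                    "expected name, description and >= 1 gene"
                )
            name, desc, genes = fields[0], fields[1], fields[2:]
            genes = [g for g in genes if g]
            deduped = list(dict.fromkeys(genes))
            if len(deduped) != len(genes):
                warnings.warn(
                    f"{path}: line {lineno} ({name}): duplicated genes removed"
                )
            out.append((name, desc, tuple(deduped)))
    return out


def write_gmt(path, sets: list[tuple[str, str, tuple[str, ...]]]) -> None:
    with open(path, "w") as fh:
        for name, desc, genes in sets:
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_signatures_gmt(path) -> list[GeneSignature]:
    return [GeneSignature(name, genes) for name, _, genes in read_gmt(path)]


def write_signatures_gmt(path, signatures: list[GeneSignature]) -> None:
    write_gmt(path, [(s.name, "na", s.genes) for s in signatures])
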
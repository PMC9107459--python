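"""Synthetic single-cell and bulk datasets with planted EndMT structure.

The generator emulates the statistical structure the downstream analysis
assumes: negative-binomial UMI counts over a latent continuous
endothelial-to-mesenchymal transition, TF regulons whose activity tracks or
opposes the transition, doublets formed by summing two cells, and planted
low-quality cells.  Every dataset ships with its ground truth so each
pipeline stage has a recoverable answer.

Counts are gamma-Poisson (negative binomial) with a single shared dispersion
``alpha`` such that ``var = mu + alpha * mu**2``; per-cell library sizes are
lognormal around ``mean_library_size``.  Gene programs act on the log scale:
endothelial genes decline log-linearly in the latent transition coordinate
``t`` (total swing = ``effect_size`` natural-log units), mesenchymal genes
rise, and each regulon's TF-plus-target block is scaled by a factor monotone
in ``t`` whose slope sign is the planted regulator sign.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .signatures import GeneSignature, ENDOTHELIAL_SIGNATURE, MESENCHYMAL_SIGNATURE
from .regulons import Regulon

__all__ = [
    "SimConfig",
    "GroundTruth",
    "ConfigurationError",
    "simulate_transition_dataset",
    "simulate_bulk_panel",
    "make_qc_fixture",
    "DEFAULT_BULK_PROFILES",
]


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is infeasible."""


# log-scale elevations of the planted programs over background, chosen so the
# endothelial cluster stands clearly apart from non-endothelial cells even at
# the mesenchymal end of the transition (endothelial swing = effect_size).
_ENDO_ELEVATION = 2.5
_MES_ELEVATION = 1.0
_REGULON_ELEVATION = 1.0
_CLUSTER_MARKER_ELEVATION = 2.0
_MARKERS_PER_CLUSTER = 30
_LIBRARY_SIGMA = 0.35
_NORMAL_MITO_BUDGET = 0.04
_LOWQ_MITO_BUDGET = 0.30


@dataclass
class SimConfig:
    """Parameters of the planted-transition single-cell simulation.

    ``planted_tf_sign`` gives, per regulon, whether its activity rises (+1)
    or falls (-1) along the transition; the default plants one repressor
    (sign -1) followed by activators, mirroring the screen's use case of a
    single negative regulator hidden among positives.
    """

    n_cells: int = 2000
    n_genes: int = 2000
    n_endo_genes: int = 50
    n_mes_genes: int = 50
    n_regulons: int = 20
    targets_per_regulon: int = 20
    planted_tf_sign: tuple[int, ...] | None = None
    transition_fraction: float = 0.6
    doublet_rate: float = 0.05
    lowq_rate: float = 0.05
    mito_gene_fraction: float = 0.02
    nb_dispersion: float = 0.3
    mean_library_size: float = 5000.0
    effect_size: float = 1.0
    seed: int = 0
    n_discrete_clusters: int = 2

    def __post_init__(self) -> None:
        if self.planted_tf_sign is None:
            self.planted_tf_sign = tuple(
                [-1] + [1] * (self.n_regulons - 1) if self.n_regulons else []
            )
        else:
            self.planted_tf_sign = tuple(self.planted_tf_sign)
        self.validate()

    def validate(self) -> None:
        for name in ("transition_fraction", "doublet_rate", "lowq_rate",
                     "mito_gene_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} must lie in [0, 1]")
        for name in ("n_cells", "n_genes"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be positive")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be >= 0")
        if self.mean_library_size <= 0:
            raise ConfigurationError("mean_library_size must be positive")
        if len(self.planted_tf_sign) != self.n_regulons:
            raise ConfigurationError(
                "planted_tf_sign must have one entry per regulon"
            )
        if any(s not in (-1, 1) for s in self.planted_tf_sign):
            raise ConfigurationError("planted_tf_sign entries must be -1 or +1")
        budget = (
            self.n_endo_genes
            + self.n_mes_genes
            + self.n_regulons * (1 + self.targets_per_regulon)
            + int(round(self.mito_gene_fraction * self.n_genes))
            + self.n_discrete_clusters * _MARKERS_PER_CLUSTER
        )
        if budget > self.n_genes:
            raise ConfigurationError(
                f"gene budget {budget} exceeds n_genes={self.n_genes}"
            )


@dataclass
class GroundTruth:
    """Planted truth for a simulated dataset.

    ``cells`` is indexed by cell id with columns ``true_pseudotime`` (NaN for
    doublets, low-quality and non-continuum cells), ``is_doublet``,
    ``is_low_quality``, ``population`` and doublet parent ids.  ``genes`` is
    indexed by gene id with a ``program`` column.  ``tf_effect_sign`` maps
    each planted TF name to its sign.
    """

    cells: pd.DataFrame
    genes: pd.DataFrame
    tf_effect_sign: dict[str, int] = field(default_factory=dict)

    @property
    def endothelial_signature(self) -> GeneSignature:
        g = self.genes.index[self.genes["program"] == "endothelial"]
        return GeneSignature("endothelial", tuple(g))

    @property
    def mesenchymal_signature(self) -> GeneSignature:
        g = self.genes.index[self.genes["program"] == "mesenchymal"]
        return GeneSignature("mesenchymal", tuple(g))

    @property
    def regulons(self) -> list[Regulon]:
        out = []
        for tf in self.tf_effect_sign:
            targets = self.genes.index[self.genes["program"] == f"{tf}-target"]
            out.append(Regulon(tf, (tf, *targets)))
        return out


def _nb_sample(rng: np.random.Generator, mu: np.ndarray,
               dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with var = mu + dispersion * mu**2."""
    mu = np.asarray(mu, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mu)
    lam = rng.gamma(shape=1.0 / dispersion, scale=np.maximum(mu, 1e-300) * dispersion)
    return rng.poisson(lam)


def _gene_table(config: SimConfig) -> pd.DataFrame:
    """Lay out gene ids and program membership."""
    names: list[str] = []
    program: list[str] = []

    def add(block: list[str], prog: str) -> None:
        names.extend(block)
        program.extend([prog] * len(block))

    add([f"Endo{i + 1:03d}" for i in range(config.n_endo_genes)], "endothelial")
    add([f"Mes{i + 1:03d}" for i in range(config.n_mes_genes)], "mesenchymal")
    for k in range(config.n_regulons):
        tf = f"TF{k + 1:02d}"
        names.append(tf)
        program.append(f"{tf}-tf")
        add([f"{tf}-t{j + 1:02d}" for j in range(config.targets_per_regulon)],
            f"{tf}-target")
    n_mito = int(round(config.mito_gene_fraction * config.n_genes))
    add([f"mt-{i + 1:02d}" for i in range(n_mito)], "mitochondrial")
    for d in range(config.n_discrete_clusters):
        add([f"Clu{d}m{i + 1:02d}" for i in range(_MARKERS_PER_CLUSTER)],
            f"cluster-{d}-marker")
    n_bg = config.n_genes - len(names)
    add([f"Gene{i + 1:04d}" for i in range(n_bg)], "background")
    return pd.DataFrame({"program": program},
                        index=pd.Index(names, name="gene_id"))


def simulate_transition_dataset(
    config: SimConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a UMI count matrix with a planted EndMT continuum.

    Returns ``(counts, truth)`` where ``counts`` is a cells x genes integer
    DataFrame (cell ids as index, gene ids as columns).  A fraction
    ``transition_fraction`` of cells lies on a continuum with latent
    coordinate ``t ~ Uniform[0, 1]`` along which the endothelial program
    declines and the mesenchymal program rises; the remaining cells form
    discrete non-endothelial clusters with their own marker programs.
    Doublets (exact sums of two sampled singlets) are appended and flagged;
    planted low-quality cells have library size forced below the standard
    QC thresholds and mitochondrial fraction forced above 0.10.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_table(config)
    gene_ids = genes.index.to_numpy()
    n_genes = len(gene_ids)
    prog = genes["program"].to_numpy()

    n_cont = int(round(config.transition_fraction * config.n_cells))
    n_rest = config.n_cells - n_cont
    if n_cont == 0 and config.transition_fraction > 0:
        raise ConfigurationError("transition requested but zero continuum cells")

    # latent state per base cell
    t = np.full(config.n_cells, np.nan)
    t[:n_cont] = rng.uniform(0.0, 1.0, size=n_cont)
    population = np.array(["continuum"] * config.n_cells, dtype=object)
    if n_rest:
        n_clu = max(config.n_discrete_clusters, 1)
        rest_assign = rng.integers(0, n_clu, size=n_rest)
        population[n_cont:] = [f"cluster-{d}" for d in rest_assign]

    # baseline log-relative-abundance, shared across cells
    base_log = rng.normal(0.0, 0.5, size=n_genes)

    is_endo = prog == "endothelial"
    is_mes = prog == "mesenchymal"
    is_mito = prog == "mitochondrial"
    tf_names = [f"TF{k + 1:02d}" for k in range(config.n_regulons)]

    # per-cell log-mean matrix (cells x genes), built block-wise
    log_mu = np.tile(base_log, (config.n_cells, 1))
    on_cont = ~np.isnan(t)
    tc = t[on_cont]
    es = config.effect_size
    # endothelial: elevated in continuum (EC) cells, declining in t
    log_mu[np.ix_(on_cont, is_endo)] += _ENDO_ELEVATION - es * tc[:, None]
    log_mu[np.ix_(~on_cont, is_endo)] += 0.0
    # mesenchymal: rising in t
    log_mu[np.ix_(on_cont, is_mes)] += _MES_ELEVATION + es * tc[:, None]
    for k, tf in enumerate(tf_names):
        block = (prog == f"{tf}-tf") | (prog == f"{tf}-target")
        sign = config.planted_tf_sign[k]
        log_mu[np.ix_(on_cont, block)] += (
            _REGULON_ELEVATION + sign * es * (tc[:, None] - 0.5)
        )
    for d in range(config.n_discrete_clusters):
        marker = prog == f"cluster-{d}-marker"
        members = population == f"cluster-{d}"
        if members.any():
            log_mu[np.ix_(members, marker)] += _CLUSTER_MARKER_ELEVATION

    # convert to per-cell gene probabilities with a fixed mitochondrial budget
    p = np.exp(log_mu)
    p[:, is_mito] = 0.0
    p /= p.sum(axis=1, keepdims=True)
    n_mito_genes = int(is_mito.sum())
    if n_mito_genes:
        mito_base = np.exp(base_log[is_mito])
        mito_profile = mito_base / mito_base.sum()
        p *= 1.0 - _NORMAL_MITO_BUDGET
        p[:, is_mito] = _NORMAL_MITO_BUDGET * mito_profile

    # low-quality cells: re-budget mito mass, shrink the library below QC range
    n_lowq = rng.binomial(config.n_cells, config.lowq_rate)
    lowq_idx = rng.choice(config.n_cells, size=n_lowq, replace=False)
    is_lowq = np.zeros(config.n_cells, dtype=bool)
    is_lowq[lowq_idx] = True
    if n_mito_genes:
        p[is_lowq] *= (1.0 - _LOWQ_MITO_BUDGET) / (1.0 - _NORMAL_MITO_BUDGET)
        p[np.ix_(is_lowq, is_mito)] = (
            _LOWQ_MITO_BUDGET * mito_profile[None, :]
        )
    t[is_lowq] = np.nan
    population[is_lowq] = "low_quality"

    lib = rng.lognormal(
        np.log(config.mean_library_size) - _LIBRARY_SIGMA**2 / 2.0,
        _LIBRARY_SIGMA, size=config.n_cells,
    )
    lib[is_lowq] = rng.uniform(60, 120, size=n_lowq)

    counts = _nb_sample(rng, lib[:, None] * p, config.nb_dispersion)

    # force the planted low-quality contract: mito fraction strictly > 0.10
    mito_cols = np.where(is_mito)[0]
    if n_mito_genes:
        for i in np.where(is_lowq)[0]:
            tot = counts[i].sum()
            if tot == 0:
                counts[i, mito_cols[0]] = 1
                tot = 1
            while counts[i, mito_cols].sum() <= 0.10 * tot:
                counts[i, mito_cols[0]] += 1
                tot += 1

    # doublets: exact element-wise sums of two distinct singlet cells
    n_dbl = rng.binomial(config.n_cells, config.doublet_rate)
    good = np.where(~is_lowq)[0]
    parents = np.empty((n_dbl, 2), dtype=int)
    dbl_counts = np.zeros((n_dbl, n_genes), dtype=counts.dtype)
    for j in range(n_dbl):
        a, b = rng.choice(good, size=2, replace=False)
        parents[j] = (a, b)
        dbl_counts[j] = counts[a] + counts[b]

    cell_ids = np.array(
        [f"cell-{i + 1:05d}" for i in range(config.n_cells)]
        + [f"doublet-{j + 1:04d}" for j in range(n_dbl)]
    )
    all_counts = np.vstack([counts, dbl_counts]) if n_dbl else counts
    counts_df = pd.DataFrame(
        all_counts, index=pd.Index(cell_ids, name="cell_id"), columns=gene_ids
    )

    cells = pd.DataFrame(
        {
            "true_pseudotime": np.concatenate([t, np.full(n_dbl, np.nan)]),
            "is_doublet": np.concatenate(
                [np.zeros(config.n_cells, bool), np.ones(n_dbl, bool)]
            ),
            "is_low_quality": np.concatenate(
                [is_lowq, np.zeros(n_dbl, bool)]
            ),
            "population": np.concatenate(
                [population, np.array(["doublet"] * n_dbl, dtype=object)]
            ),
            "doublet_parent1": [""] * config.n_cells
            + [cell_ids[a] for a, _ in parents],
            "doublet_parent2": [""] * config.n_cells
            + [cell_ids[b] for _, b in parents],
        },
        index=counts_df.index,
    )
    truth = GroundTruth(
        cells=cells,
        genes=genes,
        tf_effect_sign={
            tf: int(s) for tf, s in zip(tf_names, config.planted_tf_sign)
        },
    )
    return counts_df, truth


# --------------------------------------------------------------------------
# bulk panel
# --------------------------------------------------------------------------

#: Planted EndMT-shift profiles (natural-log units) per disease model and
#: phase: three transient-peak models and one monotone-rise model.
DEFAULT_BULK_PROFILES: Mapping[str, Mapping[str, float]] = {
    "seizure": {"acute": 1.2, "subacute": 0.6, "chronic": 0.2},
    "mcao": {"acute": 1.0, "subacute": 0.5, "chronic": 0.2},
    "tbi": {"acute": 0.8, "subacute": 0.4, "chronic": 0.1},
    "eae": {"acute": 0.5, "subacute": 1.0, "chronic": 1.5},
}


def simulate_bulk_panel(
    config: SimConfig | None = None,
    profiles: Mapping[str, Mapping[str, float]] | None = None,
    *,
    n_replicates: int = 3,
    noise_sd: float = 0.2,
    n_background_genes: int = 100,
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a bulk EC expression panel across disease models and phases.

    Returns ``(table, truth)``: ``table`` is a samples x genes DataFrame of
    log-scale expression whose gene columns start with the endothelial block
    followed by the mesenchymal block of the fixed EndMT signature, then
    background genes; ``truth`` records each sample's condition, time point,
    replicate and planted shift.  A planted shift of ``delta`` adds
    ``+delta/2`` to every mesenchymal gene and ``-delta/2`` to every
    endothelial gene, so the downstream EndMT score moves by exactly
    ``delta`` in the noise-free case.  Replicate noise is Gaussian on the
    log scale (lognormal in linear units) with standard deviation
    ``noise_sd``.
    """
    if profiles is None:
        profiles = DEFAULT_BULK_PROFILES
    if len(profiles) < 2:
        raise ConfigurationError("need >= 2 conditions")
    timepoint_sets = [tuple(p.keys()) for p in profiles.values()]
    if any(len(tps) < 2 for tps in timepoint_sets):
        raise ConfigurationError("need >= 2 time points per condition")
    if n_replicates < 1:
        raise ConfigurationError("n_replicates must be >= 1")
    if seed is None:
        seed = config.seed if config is not None else 0
    rng = np.random.default_rng(seed)

    endo = list(ENDOTHELIAL_SIGNATURE.genes)
    mes = list(MESENCHYMAL_SIGNATURE.genes)
    bg = [f"BG{i + 1:03d}" for i in range(n_background_genes)]
    gene_ids = endo + mes + bg
    baseline = np.concatenate(
        [
            np.full(len(endo), 3.0),
            np.full(len(mes), 2.0),
            rng.normal(2.0, 0.5, size=len(bg)),
        ]
    )

    rows, meta = [], []
    for cond, profile in profiles.items():
        for tp, delta in profile.items():
            for rep in range(1, n_replicates + 1):
                shift = np.zeros(len(gene_ids))
                shift[: len(endo)] = -delta / 2.0
                shift[len(endo): len(endo) + len(mes)] = +delta / 2.0
                noise = (
                    rng.normal(0.0, noise_sd, size=len(gene_ids))
                    if noise_sd > 0
                    else 0.0
                )
                rows.append(baseline + shift + noise)
                meta.append((f"{cond}_{tp}_r{rep}", cond, tp, rep, delta))

    index = pd.Index([m[0] for m in meta], name="sample_id")
    table = pd.DataFrame(np.array(rows), index=index, columns=gene_ids)
    truth = pd.DataFrame(
        {
            "condition": [m[1] for m in meta],
            "timepoint": [m[2] for m in meta],
            "replicate": [m[3] for m in meta],
            "planted_shift": [m[4] for m in meta],
        },
        index=index,
    )
    return table, truth


# --------------------------------------------------------------------------
# QC fixture
# --------------------------------------------------------------------------

def make_qc_fixture(
    seed: int = 0,
    *,
    n_clean: int = 100,
    n_lowq: int = 10,
    n_highcomplex: int = 5,
    n_doublets: int = 20,
    n_genes: int = 4000,
    nb_dispersion: float = 0.3,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Construct the QC benchmark: clean cells in two well-separated clusters,
    planted low-quality cells (tiny library, mito fraction > 0.10),
    high-complexity cells (> 3500 detected genes) and cross-cluster doublets.

    Returns ``(counts, truth)`` with ``truth`` holding ``kind`` in
    {clean, low_quality, high_complexity, doublet}, the clean cells' cluster,
    and doublet parent ids.
    """
    rng = np.random.default_rng(seed)
    n_mito = 40
    n_marker = 200
    gene_ids = (
        [f"mt-{i + 1:02d}" for i in range(n_mito)]
        + [f"Am{i + 1:03d}" for i in range(n_marker)]
        + [f"Bm{i + 1:03d}" for i in range(n_marker)]
        + [f"Gene{i + 1:04d}" for i in range(n_genes - n_mito - 2 * n_marker)]
    )
    n_total_genes = len(gene_ids)
    base_log = rng.normal(0.0, 0.4, size=n_total_genes)
    is_mito = np.zeros(n_total_genes, bool)
    is_mito[:n_mito] = True
    a_block = slice(n_mito, n_mito + n_marker)
    b_block = slice(n_mito + n_marker, n_mito + 2 * n_marker)

    def probs(marker_block: slice | None, mito_budget: float) -> np.ndarray:
        lm = base_log.copy()
        if marker_block is not None:
            lm[marker_block] += _CLUSTER_MARKER_ELEVATION
        p = np.exp(lm)
        p[is_mito] = 0.0
        p /= p.sum()
        p *= 1.0 - mito_budget
        mito_base = np.exp(base_log[is_mito])
        p[is_mito] = mito_budget * mito_base / mito_base.sum()
        return p

    p_a = probs(a_block, _NORMAL_MITO_BUDGET)
    p_b = probs(b_block, _NORMAL_MITO_BUDGET)
    p_low = probs(None, _LOWQ_MITO_BUDGET)

    rows, kinds, clusters = [], [], []
    half = n_clean // 2
    for i in range(n_clean):
        p = p_a if i < half else p_b
        lib = rng.lognormal(np.log(2000.0) - 0.05, 0.3)
        rows.append(_nb_sample(rng, lib * p, nb_dispersion))
        kinds.append("clean")
        clusters.append("A" if i < half else "B")
    for _ in range(n_lowq):
        lib = rng.uniform(60, 120)
        c = _nb_sample(rng, lib * p_low, nb_dispersion)
        if c.sum() == 0:
            c[0] = 1
        while c[is_mito].sum() <= 0.10 * c.sum():
            c[0] += 1
        rows.append(c)
        kinds.append("low_quality")
        clusters.append("")
    for _ in range(n_highcomplex):
        lib = 30000.0
        c = _nb_sample(rng, lib * probs(None, _NORMAL_MITO_BUDGET), nb_dispersion)
        zero = np.where(c == 0)[0]
        need = 3501 - int((c > 0).sum())
        if need > 0:
            boost = rng.choice(zero, size=min(need, len(zero)), replace=False)
            c[boost] = 1
        rows.append(c)
        kinds.append("high_complexity")
        clusters.append("")

    counts = np.array(rows)
    parent1 = [""] * len(rows)
    parent2 = [""] * len(rows)
    cell_ids = [f"cell-{i + 1:04d}" for i in range(len(rows))]
    # cross-cluster doublets: one parent from each clean cluster
    for j in range(n_doublets):
        a = rng.integers(0, half)
        b = rng.integers(half, n_clean)
        counts = np.vstack([counts, counts[a] + counts[b]])
        cell_ids.append(f"doublet-{j + 1:03d}")
        kinds.append("doublet")
        clusters.append("")
        parent1.append(f"cell-{a + 1:04d}")
        parent2.append(f"cell-{b + 1:04d}")

    index = pd.Index(cell_ids, name="cell_id")
    counts_df = pd.DataFrame(counts, index=index, columns=gene_ids)
    truth = pd.DataFrame(
        {"kind": kinds, "cluster": clusters,
         "doublet_parent1": parent1, "doublet_parent2": parent2},
        index=index,
    )
    return counts_df, truth
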
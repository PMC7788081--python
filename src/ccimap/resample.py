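"""Pseudobulk resampling and the four pairwise measurement statistics.

For each (query, reference) population pair and each measurement channel, an
empirical null is built by resampling 30-cell pseudobulks from both
populations (default 10,000 iterations) and recomputing the statistic; the
median of that distribution is the pair's measurement score S_i, and the
distribution itself is the likelihood substrate of the composite index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import rankdata
from sklearn.decomposition import PCA

from ccimap.core import ExpressionMatrix, GeneSetCollection, PopulationLabeling
from ccimap.gsea import DEFAULT_WINDOW, auc_matrix, set_index_arrays
from ccimap.sampling import pseudobulk_matrix, sample_cell_indices

STATISTICS = ("euclidean", "spearman", "pc_dist", "gsea_profile")
ORIENTATION = {
    "euclidean": "distance",
    "spearman": "similarity",
    "pc_dist": "distance",
    "gsea_profile": "distance",
}

DEFAULT_SIZE = 30
DEFAULT_RESAMPLES = 10000


@dataclass(frozen=True)
class PseudobulkProfile:
    values: np.ndarray
    genes: tuple
    population: str
    size: int


@dataclass(frozen=True)
class PCABasis:
    """Top principal components of the joint normalized matrix.

    ``weights`` are explained-variance fractions; the pair distance in PC
    space is sqrt(sum_k w_k * (proj_k(p) - proj_k(q))^2).
    """

    genes: tuple
    mean: np.ndarray
    components: np.ndarray  # (n_components, n_genes)
    weights: np.ndarray  # explained-variance fractions, (n_components,)

    def project(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.genes):
            raise ValueError("basis gene space mismatch")
        return (X - self.mean) @ self.components.T


@dataclass(frozen=True)
class EmpiricalNull:
    statistic: str
    query: str
    reference: str
    values: np.ndarray
    orientation: str
    median: float = field(default=np.nan)

    def __post_init__(self):
        object.__setattr__(self, "median", float(np.median(self.values)))


@dataclass(frozen=True)
class MeasurementScore:
    statistic: str
    query: str
    reference: str
    S: float


def fit_pca_basis(
    X: np.ndarray | sp.spmatrix, genes, n_components: int = 30
) -> PCABasis:
    """Fit the PC basis on the joint (reference + query) normalized matrix."""
    Xd = X.toarray() if sp.issparse(X) else np.asarray(X, dtype=float)
    k = min(n_components, min(Xd.shape) - 1, Xd.shape[1])
    solver = "covariance_eigh" if Xd.shape[0] > Xd.shape[1] else "full"
    pca = PCA(n_components=k, svd_solver=solver)
    pca.fit(Xd)
    return PCABasis(
        genes=tuple(genes),
        mean=pca.mean_,
        components=pca.components_,
        weights=pca.explained_variance_ratio_.copy(),
    )


def pseudobulk(
    em: ExpressionMatrix,
    cells,
    size: int = DEFAULT_SIZE,
    rng: np.random.Generator | int | None = None,
    population: str = "",
) -> PseudobulkProfile:
    """Mean normalized expression of ``size`` randomly drawn cells."""
    if em.normalized is None:
        raise ValueError("normalized layer missing; call normalize_umi first")
    rng = np.random.default_rng(rng)
    idx = em.barcodes.get_indexer(pd.Index(cells))
    if len(idx) == 0:
        raise ValueError("empty population")
    if np.any(idx < 0):
        raise KeyError("unknown barcodes")
    draws = sample_cell_indices(len(idx), size, 1, rng)
    values = pseudobulk_matrix(em.normalized[idx], draws)[0]
    return PseudobulkProfile(
        values=values, genes=tuple(em.genes), population=population, size=size
    )


def _profile_pair(p: PseudobulkProfile, q: PseudobulkProfile, genes=None):
    if genes is None:
        if p.genes != q.genes:
            raise ValueError("profiles cover different gene spaces")
        return np.asarray(p.values, float), np.asarray(q.values, float)
    genes = list(genes)
    if not genes:
        raise ValueError("empty gene list")
    pi = pd.Index(p.genes).get_indexer(genes)
    qi = pd.Index(q.genes).get_indexer(genes)
    if np.any(pi < 0) or np.any(qi < 0):
        raise KeyError("profiles do not cover the requested genes")
    return np.asarray(p.values, float)[pi], np.asarray(q.values, float)[qi]


def stat_euclidean(p: PseudobulkProfile, q: PseudobulkProfile, genes=None) -> float:
    """Euclidean norm of the expression difference (distance channel)."""
    a, b = _profile_pair(p, q, genes)
    return float(np.linalg.norm(a - b))


def stat_spearman(p: PseudobulkProfile, q: PseudobulkProfile, genes=None) -> float:
    """Spearman rank correlation with average ranks (similarity channel)."""
    a, b = _profile_pair(p, q, genes)
    if len(a) < 3:
        raise ValueError("need at least 3 genes for a rank correlation")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("Spearman correlation undefined for a constant profile")
    ra, rb = rankdata(a), rankdata(b)
    return float(np.corrcoef(ra, rb)[0, 1])


def stat_pc_dist(
    p: PseudobulkProfile, q: PseudobulkProfile, basis: PCABasis
) -> float:
    """Explained-variance-weighted Euclidean distance in PC space."""
    a, b = _profile_pair(p, q, list(basis.genes))
    za, zb = basis.project(a)[0], basis.project(b)[0]
    return float(np.sqrt(np.sum(basis.weights * (za - zb) ** 2)))


def stat_gsea_profile(
    p: PseudobulkProfile,
    q: PseudobulkProfile,
    sets: GeneSetCollection,
    window: int = DEFAULT_WINDOW,
) -> float:
    """Euclidean distance between the two gene-set AUC vectors."""
    if len(sets) == 0:
        raise ValueError("empty gene-set collection")
    a, b = _profile_pair(p, q, None)
    genes = np.asarray(p.genes, dtype=object)
    order = np.argsort(genes, kind="stable")
    idx = set_index_arrays(sets, genes[order])
    aucs = auc_matrix(np.vstack([a[order], b[order]]), idx, window=window)
    return float(np.linalg.norm(aucs[0] - aucs[1]))


def _batch_spearman(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    rp = rankdata(P, axis=1)
    rq = rankdata(Q, axis=1)
    rp = rp - rp.mean(axis=1, keepdims=True)
    rq = rq - rq.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(rp, axis=1) * np.linalg.norm(rq, axis=1)
    if np.any(denom == 0):
        warnings.warn("constant pseudobulk profile in Spearman channel; rho set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.einsum("ij,ij->i", rp, rq) / np.where(denom == 0, 1.0, denom)
    return np.where(denom == 0, 0.0, rho)


def batch_statistic(
    statistic: str,
    P: np.ndarray,
    Q: np.ndarray,
    basis: PCABasis | None = None,
    set_indices: list[np.ndarray] | None = None,
    window: int = DEFAULT_WINDOW,
) -> np.ndarray:
    """Evaluate one channel on paired pseudobulk rows.

    For ``pc_dist`` the profile columns must follow ``basis.genes``; for
    ``gsea_profile`` the columns must be sorted by gene id and
    ``set_indices`` must index into that order.
    """
    if statistic == "euclidean":
        return np.linalg.norm(P - Q, axis=1)
    if statistic == "spearman":
        return _batch_spearman(P, Q)
    if statistic == "pc_dist":
        if basis is None:
            raise ValueError("pc_dist requires a fitted PCA basis")
        d = basis.project(P) - basis.project(Q)
        return np.sqrt((basis.weights * d**2).sum(axis=1))
    if statistic == "gsea_profile":
        if set_indices is None:
            raise ValueError("gsea_profile requires gene-set indices")
        a = auc_matrix(P, set_indices, window=window)
        b = auc_matrix(Q, set_indices, window=window)
        return np.linalg.norm(a - b, axis=1)
    raise ValueError(f"unknown statistic {statistic!r}; expected one of {STATISTICS}")


def build_null(
    em: ExpressionMatrix,
    labeling: PopulationLabeling,
    query_pop: str,
    ref_pop: str,
    statistic: str,
    n_resamples: int = DEFAULT_RESAMPLES,
    size: int = DEFAULT_SIZE,
    seed=None,
    genes=None,
    basis: PCABasis | None = None,
    sets: GeneSetCollection | None = None,
    window: int = DEFAULT_WINDOW,
) -> EmpiricalNull:
    """Empirical distribution of ``statistic`` over paired pseudobulk resamples.

    Both populations are resampled afresh at every iteration. ``genes``
    restricts the gene space (defaults to all genes); for ``gsea_profile`` a
    gene-set collection is required, for ``pc_dist`` a fitted basis.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")
    if n_resamples < 2:
        raise ValueError("need at least 2 resamples")
    if n_resamples < 100:
        warnings.warn("fewer than 100 resamples gives an unstable null density")
    if em.normalized is None:
        raise ValueError("normalized layer missing; call normalize_umi first")

    rng = np.random.default_rng(seed)
    gene_list = list(genes) if genes is not None else list(em.genes)
    gidx = em.genes.get_indexer(pd.Index(gene_list))
    if np.any(gidx < 0):
        raise KeyError("requested genes absent from the matrix")

    q_cells = em.barcodes.get_indexer(labeling.cells_of(query_pop))
    r_cells = em.barcodes.get_indexer(labeling.cells_of(ref_pop))

    set_indices = None
    if statistic == "gsea_profile":
        if sets is None:
            raise ValueError("gsea_profile requires a gene-set collection")
        order = np.argsort(np.asarray(gene_list, dtype=object), kind="stable")
        gidx = gidx[order]
        gene_list = [gene_list[i] for i in order]
        set_indices = set_index_arrays(sets, gene_list)
    if statistic == "pc_dist":
        if basis is None:
            raise ValueError("pc_dist requires a fitted PCA basis")
        if tuple(gene_list) != basis.genes:
            gidx = em.genes.get_indexer(pd.Index(list(basis.genes)))
            if np.any(gidx < 0):
                raise KeyError("basis gene space absent from the matrix")

    Xq = em.normalized[q_cells][:, gidx]
    Xr = em.normalized[r_cells][:, gidx]
    dq = sample_cell_indices(Xq.shape[0], size, n_resamples, rng)
    dr = sample_cell_indices(Xr.shape[0], size, n_resamples, rng)
    P = pseudobulk_matrix(Xq, dq)
    Q = pseudobulk_matrix(Xr, dr)
    values = batch_statistic(
        statistic, P, Q, basis=basis, set_indices=set_indices, window=window
    )
    return EmpiricalNull(
        statistic=statistic,
        query=query_pop,
        reference=ref_pop,
        values=np.asarray(values, float),
        orientation=ORIENTATION[statistic],
    )


def null_table(nulls: list[EmpiricalNull]) -> pd.DataFrame:
    """Serialize empirical nulls to a long-form table."""
    frames = []
    for nl in nulls:
        frames.append(
            pd.DataFrame(
                {
                    "statistic": nl.statistic,
                    "query": nl.query,
                    "reference": nl.reference,
                    "iteration": np.arange(len(nl.values)),
                    "value": nl.values,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
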
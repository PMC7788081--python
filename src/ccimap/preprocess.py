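"""Quality control, UMI normalization and highly-variable-gene selection."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from ccimap.core import ExpressionMatrix


@dataclass(frozen=True)
class QCThresholds:
    """Cell-level QC gates.

    Cells are retained when the number of detected genes lies in
    ``[min_genes_per_cell, max_genes_per_cell]`` (inclusive) and the
    mitochondrial UMI fraction is at most ``max_mito_fraction``.
    """

    min_genes_per_cell: int = 500
    max_genes_per_cell: int = 4000
    max_mito_fraction: float = 0.10

    def __post_init__(self) -> None:
        if not (0 < self.min_genes_per_cell <= self.max_genes_per_cell):
            raise ValueError("need 0 < min_genes_per_cell <= max_genes_per_cell")
        if not (0.0 <= self.max_mito_fraction <= 1.0):
            raise ValueError("max_mito_fraction must be in [0, 1]")


@dataclass
class QCReport:
    """Per-cell QC outcome; ``removed`` lists barcodes with reasons."""

    n_input: int
    n_retained: int
    removed: pd.DataFrame = field(default_factory=pd.DataFrame)


def apply_qc(
    em: ExpressionMatrix, thresholds: QCThresholds = QCThresholds()
) -> tuple[ExpressionMatrix, QCReport]:
    """Filter cells on detected-gene count and mitochondrial UMI fraction."""
    detected = em.genes_detected()
    mito_frac = em.mito_fraction()
    low = detected < thresholds.min_genes_per_cell
    high = detected > thresholds.max_genes_per_cell
    mito = mito_frac > thresholds.max_mito_fraction
    keep = ~(low | high | mito)

    reasons = []
    for i in np.flatnonzero(~keep):
        why = []
        if low[i]:
            why.append(f"genes_detected {detected[i]} < {thresholds.min_genes_per_cell}")
        if high[i]:
            why.append(f"genes_detected {detected[i]} > {thresholds.max_genes_per_cell}")
        if mito[i]:
            why.append(
                f"mito_fraction {mito_frac[i]:.4f} > {thresholds.max_mito_fraction}"
            )
        reasons.append((em.barcodes[i], "; ".join(why)))
    removed = pd.DataFrame(reasons, columns=["barcode", "reason"])
    report = QCReport(n_input=em.n_cells, n_retained=int(keep.sum()), removed=removed)
    if report.n_retained == 0:
        warnings.warn("QC removed every cell; returning an empty matrix")
    return em.subset_cells(keep), report


def normalize_umi(em: ExpressionMatrix) -> ExpressionMatrix:
    """Total-count scaling to the median cell total, then natural log.

    normalized[c, g] = ln(1 + raw[c, g] / total_c * median(total)), so zeros
    stay zero and within-cell rank order is preserved.
    """
    totals = em.total_counts()
    if np.any(totals <= 0):
        bad = em.barcodes[totals <= 0][:5].tolist()
        raise ValueError(
            f"cells with zero total counts (e.g. {bad}); run apply_qc first"
        )
    median_total = float(np.median(totals))
    counts = em.counts.tocoo()
    scaled = counts.data / totals[counts.row] * median_total
    norm = sp.csr_matrix(
        (np.log1p(scaled), (counts.row, counts.col)), shape=em.counts.shape
    )
    return ExpressionMatrix(
        barcodes=em.barcodes,
        genes=em.genes,
        counts=em.counts,
        normalized=norm,
        mito=em.mito,
    )


def select_hvg(em: ExpressionMatrix, n_top: int, n_bins: int = 20) -> list[str]:
    """Highly variable genes by normalized dispersion.

    Genes are binned by mean normalized expression into ``n_bins``
    equal-count bins; within each bin the dispersion (variance / mean) is
    z-scored, and the ``n_top`` genes with the highest z win. Ties break
    lexicographically by gene id. Unexpressed genes are never returned.
    """
    if em.normalized is None:
        raise ValueError("normalized layer missing; call normalize_umi first")
    X = em.normalized
    n = em.n_cells
    mean = np.asarray(X.mean(axis=0)).ravel()
    sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    var = (sq - mean**2) * (n / max(n - 1, 1))
    expressed = mean > 0
    n_expressed = int(expressed.sum())
    if n_expressed < n_top:
        warnings.warn(
            f"only {n_expressed} expressed genes for n_top={n_top}; returning all"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.where(expressed, var / np.maximum(mean, 1e-300), 0.0)

    idx = np.flatnonzero(expressed)
    order = np.argsort(mean[idx], kind="stable")
    n_use = min(n_bins, len(idx))
    z = np.zeros(em.n_genes)
    if len(idx):
        bins = np.array_split(idx[order], n_use)
        for members in bins:
            d = dispersion[members]
            sd = d.std(ddof=0)
            z[members] = (d - d.mean()) / sd if sd > 0 else 0.0

    genes = np.asarray(em.genes, dtype=object)
    cand = idx[np.lexsort((genes[idx], -z[idx]))]
    return genes[cand[: min(n_top, len(cand))]].tolist()
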
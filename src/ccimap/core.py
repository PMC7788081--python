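"""Core containers: expression matrices, population labels, gene sets."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp


class FormatError(ValueError):
    """A file does not conform to its declared format."""


def _as_csr(matrix) -> sp.csr_matrix:
    if sp.issparse(matrix):
        return matrix.tocsr()
    return sp.csr_matrix(np.asarray(matrix))


@dataclass
class ExpressionMatrix:
    """Cell-by-gene UMI count matrix with an optional normalized layer.

    Parameters
    ----------
    barcodes : sequence of str
        Unique cell identifiers (rows).
    genes : sequence of str
        Unique gene identifiers (columns).
    counts : array or sparse matrix, shape (n_cells, n_genes)
        Raw UMI counts; non-negative integers.
    normalized : array or sparse matrix, optional
        Log-normalized expression, same shape as ``counts``.
    mito : boolean array per gene, optional
        Mitochondrial-gene flags; derived from a name prefix by the readers.
    """

    barcodes: pd.Index
    genes: pd.Index
    counts: sp.csr_matrix
    normalized: sp.csr_matrix | None = None
    mito: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.barcodes = pd.Index(self.barcodes, dtype=object)
        self.genes = pd.Index(self.genes, dtype=object)
        if self.barcodes.has_duplicates:
            dups = self.barcodes[self.barcodes.duplicated()].unique().tolist()
            raise FormatError(f"duplicate cell barcodes: {dups[:5]}")
        if self.genes.has_duplicates:
            dups = self.genes[self.genes.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dups[:5]}")
        self.counts = _as_csr(self.counts)
        if self.counts.shape != (len(self.barcodes), len(self.genes)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.barcodes)} barcodes x {len(self.genes)} genes"
            )
        data = self.counts.data
        if data.size and (data.min() < 0 or np.any(data != np.round(data))):
            raise FormatError("raw counts must be non-negative integers")
        if self.normalized is not None:
            self.normalized = _as_csr(self.normalized)
            if self.normalized.shape != self.counts.shape:
                raise FormatError("normalized layer shape mismatch")
            if self.normalized.data.size and self.normalized.data.min() < 0:
                raise FormatError("normalized entries must be non-negative")
        if self.mito is None:
            self.mito = np.zeros(len(self.genes), dtype=bool)
        else:
            self.mito = np.asarray(self.mito, dtype=bool)
            if self.mito.shape != (len(self.genes),):
                raise FormatError("mito flag length must equal gene count")

    @property
    def n_cells(self) -> int:
        return len(self.barcodes)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def genes_detected(self) -> np.ndarray:
        """Number of genes with raw count >= 1, per cell."""
        return np.asarray((self.counts > 0).sum(axis=1)).ravel()

    def total_counts(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel().astype(float)

    def mito_fraction(self) -> np.ndarray:
        """Fraction of each cell's UMIs on mitochondrial genes (0 if no UMIs)."""
        totals = self.total_counts()
        mito_tot = np.asarray(self.counts[:, self.mito].sum(axis=1)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, mito_tot / np.maximum(totals, 1e-300), 0.0)
        return frac

    def subset_cells(self, mask_or_barcodes) -> "ExpressionMatrix":
        if isinstance(mask_or_barcodes, np.ndarray) and mask_or_barcodes.dtype == bool:
            idx = np.flatnonzero(mask_or_barcodes)
        else:
            idx = self.barcodes.get_indexer(pd.Index(mask_or_barcodes))
            if np.any(idx < 0):
                raise KeyError("unknown barcodes in subset request")
        return ExpressionMatrix(
            barcodes=self.barcodes[idx],
            genes=self.genes,
            counts=self.counts[idx],
            normalized=None if self.normalized is None else self.normalized[idx],
            mito=self.mito,
        )

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        idx = self.genes.get_indexer(pd.Index(gene_ids))
        if np.any(idx < 0):
            raise KeyError("unknown gene ids in subset request")
        return ExpressionMatrix(
            barcodes=self.barcodes,
            genes=self.genes[idx],
            counts=self.counts[:, idx],
            normalized=None if self.normalized is None else self.normalized[:, idx],
            mito=self.mito[idx],
        )

    def to_anndata(self):
        """Export to an :class:`anndata.AnnData` (counts in X, lognorm layer)."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.counts.copy(),
            obs=pd.DataFrame(index=self.barcodes.astype(str)),
            var=pd.DataFrame({"mito": self.mito}, index=self.genes.astype(str)),
        )
        if self.normalized is not None:
            adata.layers["lognorm"] = self.normalized.copy()
        return adata


@dataclass
class PopulationLabeling:
    """Cell -> population / sample / condition assignments.

    Wraps a DataFrame indexed by barcode with columns ``population``,
    ``sample``, ``condition`` and optional ``pseudotime`` / ``lineage``.
    """

    table: pd.DataFrame

    REQUIRED = ("population", "sample", "condition")

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in self.REQUIRED if c not in t.columns]
        if missing:
            raise FormatError(f"label table missing columns: {missing}")
        if t.index.has_duplicates:
            raise FormatError("duplicate barcodes in label table")
        if "pseudotime" in t.columns:
            pt = pd.to_numeric(t["pseudotime"], errors="coerce")
            valid = pt.dropna()
            if len(valid) and (~np.isfinite(valid.to_numpy())).any():
                raise FormatError("pseudotime values must be finite")

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PopulationLabeling":
        return cls(frame.copy())

    def populations(self, condition: str | None = None) -> list[str]:
        t = self.table
        if condition is not None:
            t = t[t["condition"] == condition]
        return sorted(t["population"].unique().tolist())

    def cells_of(self, population: str) -> pd.Index:
        mask = self.table["population"] == population
        if not mask.any():
            raise KeyError(f"population {population!r} has no cells")
        return self.table.index[mask]

    def validate_against(self, em: ExpressionMatrix) -> None:
        unknown = self.table.index.difference(em.barcodes)
        if len(unknown):
            raise FormatError(
                f"{len(unknown)} labeled barcodes absent from the expression "
                f"matrix (e.g. {unknown[:3].tolist()})"
            )

    def subset(self, barcodes) -> "PopulationLabeling":
        keep = self.table.index.intersection(pd.Index(barcodes))
        return PopulationLabeling(self.table.loc[keep])


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. the 50 MSigDB hallmark sets)."""

    sets: dict[str, list[str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")
            # de-duplicate preserving order
            self.sets[name] = list(dict.fromkeys(members))

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list[str]:
        return list(self.sets)

    def restrict(self, universe) -> "GeneSetCollection":
        """Drop members outside ``universe``; empty sets are removed."""
        uni = set(universe)
        kept = {
            n: [g for g in members if g in uni] for n, members in self.sets.items()
        }
        kept = {n: m for n, m in kept.items() if m}
        return GeneSetCollection(kept, provenance=self.provenance)
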
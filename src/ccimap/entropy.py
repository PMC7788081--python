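"""Per-cell Shannon entropy of the transcriptome.

Entropy = -sum_i p_i log2 p_i over a cell's raw UMI proportions (expressed
genes only); a diversity/potency readout in bits. Raw counts are used so the
measure is self-contained per cell and scale-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import entropy as _shannon

from ccimap.core import ExpressionMatrix, PopulationLabeling


@dataclass(frozen=True)
class EntropyRecord:
    barcode: str
    entropy: float
    n_expressed_genes: int


def cell_entropy(counts, barcode: str = "") -> EntropyRecord:
    """Shannon entropy (bits) of one cell's per-gene count proportions."""
    counts = np.asarray(counts, dtype=float).ravel()
    pos = counts[counts > 0]
    if pos.size == 0:
        raise ValueError("all-zero cell; should have been removed by QC")
    h = float(_shannon(pos, base=2))
    return EntropyRecord(barcode=barcode, entropy=h, n_expressed_genes=int(pos.size))


def entropy_table(em: ExpressionMatrix) -> pd.DataFrame:
    """Per-cell entropy table (barcode, entropy_bits, n_expressed_genes)."""
    X = em.counts.tocsr()
    rows = []
    for i, bc in enumerate(em.barcodes):
        vals = X.data[X.indptr[i] : X.indptr[i + 1]]
        rec = cell_entropy(vals, barcode=str(bc))
        rows.append((rec.barcode, rec.entropy, rec.n_expressed_genes))
    return pd.DataFrame(rows, columns=["barcode", "entropy_bits", "n_expressed_genes"])


def population_entropy_summary(
    table: pd.DataFrame, labeling: PopulationLabeling
) -> pd.DataFrame:
    """Median and IQR of entropy per population."""
    merged = table.set_index("barcode").join(labeling.table["population"], how="inner")
    out = (
        merged.groupby("population")["entropy_bits"]
        .agg(
            median="median",
            q25=lambda s: s.quantile(0.25),
            q75=lambda s: s.quantile(0.75),
            n_cells="size",
        )
        .reset_index()
    )
    out["iqr"] = out["q75"] - out["q25"]
    return out
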
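"""Readers and writers for the standard on-disk formats.

Supported inputs: 10x-style MatrixMarket triplet directories (matrix.mtx +
barcodes.tsv + features.tsv, gzip-tolerant), dense delimited count tables,
GMT gene-set files, label tables, population trees, per-cell allele counts
and haplotype definitions.
"""

from __future__ import annotations

import gzip
import os
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from ccimap.core import ExpressionMatrix, FormatError, GeneSetCollection, PopulationLabeling

DEFAULT_MITO_PREFIX = "MT-"


def _find(directory: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = directory / name
        if p.exists():
            return p
    raise FileNotFoundError(f"{stem}[.gz] not found in {directory}")


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_id_column(path: Path) -> list[str]:
    with _open_text(path) as fh:
        return [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]


def mito_flags(gene_ids, prefix: str = DEFAULT_MITO_PREFIX) -> np.ndarray:
    """Flag mitochondrial genes by case-insensitive name prefix."""
    pref = prefix.lower()
    return np.array([str(g).lower().startswith(pref) for g in gene_ids], dtype=bool)


def read_counts(path, mito_prefix: str = DEFAULT_MITO_PREFIX) -> ExpressionMatrix:
    """Read a count matrix from a 10x-style triplet directory or a dense table.

    Triplet directories hold ``matrix.mtx``, ``barcodes.tsv`` and
    ``features.tsv`` (optionally gzipped); the matrix may be written either
    genes x cells (10x convention) or cells x genes — orientation is resolved
    against the barcode/feature counts. Dense tables (.tsv/.csv) have gene
    ids as the header row and barcodes in the first column.
    """
    path = Path(path)
    if path.is_dir():
        return _read_triplet(path, mito_prefix)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    table = pd.read_csv(path, sep=sep, index_col=0)
    if table.shape[1] == 0:
        raise FormatError(f"{path}: no gene columns found")
    counts = sp.csr_matrix(table.to_numpy(dtype=float))
    genes = table.columns
    return ExpressionMatrix(
        barcodes=table.index.astype(str),
        genes=genes,
        counts=counts,
        mito=mito_flags(genes, mito_prefix),
    )


def _read_triplet(directory: Path, mito_prefix: str) -> ExpressionMatrix:
    mtx_path = None
    for stem in ("matrix.mtx", "matrix.mtx.gz"):
        p = directory / stem
        if p.exists():
            mtx_path = p
            break
    if mtx_path is None:
        raise FileNotFoundError(f"matrix.mtx[.gz] not found in {directory}")
    barcodes_path = _find(directory, "barcodes.tsv")
    features_path = None
    for stem in ("features.tsv", "genes.tsv"):
        try:
            features_path = _find(directory, stem)
            break
        except FileNotFoundError:
            continue
    if features_path is None:
        raise FileNotFoundError(f"features.tsv[.gz]/genes.tsv[.gz] not found in {directory}")

    try:
        if mtx_path.suffix == ".gz":
            with gzip.open(mtx_path, "rb") as fh:
                mat = scipy.io.mmread(fh)
        else:
            mat = scipy.io.mmread(mtx_path)
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise FormatError(f"{mtx_path}: not a valid MatrixMarket file ({exc})") from exc
    mat = sp.csr_matrix(mat)

    barcodes = _read_id_column(barcodes_path)
    genes = _read_id_column(features_path)

    if mat.shape == (len(genes), len(barcodes)):
        mat = mat.T.tocsr()
    elif mat.shape != (len(barcodes), len(genes)):
        raise FormatError(
            f"{mtx_path}: matrix shape {mat.shape} matches neither "
            f"(genes={len(genes)}, cells={len(barcodes)}) nor its transpose"
        )
    return ExpressionMatrix(
        barcodes=barcodes,
        genes=genes,
        counts=mat,
        mito=mito_flags(genes, mito_prefix),
    )


def write_counts(em: ExpressionMatrix, directory) -> None:
    """Write a matrix as an uncompressed MatrixMarket triplet (genes x cells)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(
        os.fspath(directory / "matrix.mtx"),
        sp.coo_matrix(em.counts.T),
        field="integer",
    )
    (directory / "barcodes.tsv").write_text("\n".join(map(str, em.barcodes)) + "\n")
    (directory / "features.tsv").write_text("\n".join(map(str, em.genes)) + "\n")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: name <tab> description <tab> member genes."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not any(p.strip() for p in parts[2:]):
                warnings.warn(f"{path}:{lineno}: empty gene set line skipped")
                continue
            name = parts[0]
            if name in sets:
                raise FormatError(f"{path}: duplicate gene set name {name!r}")
            members = [g for g in parts[2:] if g.strip()]
            sets[name] = list(dict.fromkeys(members))
    return GeneSetCollection(sets, provenance=str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection.sets.items():
            fh.write("\t".join([name, collection.provenance or "na", *members]) + "\n")


def read_labels(path) -> PopulationLabeling:
    """Read a label table: barcode, population, sample, condition[, pseudotime, lineage]."""
    table = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    table.index = table.index.astype(str)
    return PopulationLabeling(table)


def write_labels(labeling: PopulationLabeling, path) -> None:
    labeling.table.to_csv(path, sep="\t", index_label="barcode")


def read_tree(path) -> tuple[list[tuple[str, str]], str]:
    """Read a population tree as parent/child TSV; the root is the unique
    population that never appears as a child."""
    table = pd.read_csv(path, sep="\t", header=0)
    if table.shape[1] < 2:
        raise FormatError(f"{path}: tree table needs parent and child columns")
    edges = list(zip(table.iloc[:, 0].astype(str), table.iloc[:, 1].astype(str)))
    children = {c for _, c in edges}
    roots = sorted({p for p, _ in edges} - children)
    if len(roots) != 1:
        raise FormatError(f"{path}: expected exactly one root, found {roots}")
    return edges, roots[0]


def write_tree(edges, path) -> None:
    pd.DataFrame(edges, columns=["parent", "child"]).to_csv(path, sep="\t", index=False)
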
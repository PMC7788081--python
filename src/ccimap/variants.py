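"""scRNA-seq variant retention filtering, per-cell assignment, haplotype
tracing, and variant-burden comparison.

Variant calling itself happens upstream (pooled reads per individual); this
module consumes per-cell, per-site total/alt read counts. Sites are retained
when (1) covered in >= 20 cells, (2) >= 5 cells have > 2 reads and (3) the
alternative allele is seen in >= 3 cells. A cell carries a phased alternative
haplotype when more than 5 covered loci match it and the one-sided binomial
tail probability (null: alleles match by chance at rate p0) is below 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom

from ccimap.core import FormatError, PopulationLabeling


@dataclass(frozen=True)
class VariantSite:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("positions are 1-based; pos must be >= 1")
        if self.ref == self.alt:
            raise ValueError("ref and alt alleles must differ")

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass
class CellVariantMatrix:
    """Per-cell x per-site total and alt read counts."""

    cells: pd.Index
    sites: list[VariantSite]
    total: np.ndarray  # (n_cells, n_sites) int
    alt: np.ndarray  # (n_cells, n_sites) int

    def __post_init__(self) -> None:
        self.cells = pd.Index(self.cells, dtype=object)
        if self.cells.has_duplicates:
            raise FormatError("duplicate cell barcodes")
        self.total = np.asarray(self.total, dtype=np.int64)
        self.alt = np.asarray(self.alt, dtype=np.int64)
        shape = (len(self.cells), len(self.sites))
        if self.total.shape != shape or self.alt.shape != shape:
            raise FormatError("total/alt shapes must be (n_cells, n_sites)")
        if np.any(self.total < 0) or np.any(self.alt < 0):
            raise FormatError("read counts must be non-negative")
        if np.any(self.alt > self.total):
            raise FormatError("alt reads exceed total reads at some entries")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def site_index(self, site: VariantSite) -> int:
        for i, s in enumerate(self.sites):
            if s == site:
                return i
        raise KeyError(f"site {site.key} not in matrix")

    def subset_sites(self, sites: list[VariantSite]) -> "CellVariantMatrix":
        idx = [self.site_index(s) for s in sites]
        return CellVariantMatrix(
            cells=self.cells,
            sites=list(sites),
            total=self.total[:, idx],
            alt=self.alt[:, idx],
        )


@dataclass(frozen=True)
class Haplotype:
    """Phased alternative haplotype: ordered loci with the haplotype allele."""

    name: str
    sites: tuple
    alleles: tuple  # 'ref' or 'alt' per site

    def __post_init__(self) -> None:
        if len(self.sites) < 1:
            raise ValueError("a haplotype needs at least one locus")
        if len(self.sites) != len(self.alleles):
            raise ValueError("sites and alleles must align")
        if len(set(self.sites)) != len(self.sites):
            raise ValueError("duplicate loci in haplotype")
        bad = [a for a in self.alleles if a not in ("ref", "alt")]
        if bad:
            raise ValueError(f"haplotype alleles must be 'ref' or 'alt', got {bad[:3]}")


@dataclass(frozen=True)
class HaplotypeCall:
    cell: str
    n_covered: int
    n_matching: int
    p_value: float
    assigned: bool

    def __post_init__(self) -> None:
        if self.n_matching > self.n_covered:
            raise ValueError("n_matching cannot exceed n_covered")


def filter_variants(
    cvm: CellVariantMatrix,
    min_called_cells: int = 20,
    min_deep_cells: int = 5,
    deep_read_floor: int = 2,
    min_alt_cells: int = 3,
) -> list[VariantSite]:
    """Retain sites passing all three per-site evidence rules.

    (1) coverage (>= 1 read) in at least ``min_called_cells`` cells;
    (2) at least ``min_deep_cells`` cells with more than ``deep_read_floor``
        reads;
    (3) the alt allele observed (>= 1 alt read) in at least ``min_alt_cells``
        cells.
    """
    covered = (cvm.total >= 1).sum(axis=0)
    deep = (cvm.total > deep_read_floor).sum(axis=0)
    alt = (cvm.alt >= 1).sum(axis=0)
    keep = (covered >= min_called_cells) & (deep >= min_deep_cells) & (alt >= min_alt_cells)
    return [s for s, k in zip(cvm.sites, keep) if k]


def assign_cell_variants(
    cvm: CellVariantMatrix,
    sites: list[VariantSite] | None = None,
    min_alt_reads: int = 1,
) -> pd.DataFrame:
    """Per-cell carrier calls: a cell carries a variant when alt reads reach
    ``min_alt_reads`` at that site."""
    sub = cvm if sites is None else cvm.subset_sites(sites)
    n_cells, n_sites = sub.total.shape
    cell_col = np.repeat(np.asarray(sub.cells, dtype=object), n_sites)
    site_col = np.tile(np.array([s.key for s in sub.sites], dtype=object), n_cells)
    return pd.DataFrame(
        {
            "cell": cell_col,
            "site": site_col,
            "total_reads": sub.total.ravel(),
            "alt_reads": sub.alt.ravel(),
            "carries": (sub.alt >= min_alt_reads).ravel(),
        }
    )


def haplotype_match(
    total: np.ndarray,
    alt: np.ndarray,
    hap: Haplotype,
    cell: str = "",
    min_matching: int = 6,
    alpha: float = 0.05,
    p0: float = 0.5,
) -> HaplotypeCall:
    """Test one cell's observed alleles against a phased haplotype.

    The observed allele at a covered locus (total reads >= 1) is alt when any
    alt read is present, ref otherwise. The p-value is the one-sided binomial
    tail P(X >= n_matching | n_covered, p0). Assignment requires BOTH
    n_matching >= ``min_matching`` (more than 5 loci) and p < ``alpha``.
    """
    total = np.asarray(total, dtype=np.int64).ravel()
    alt = np.asarray(alt, dtype=np.int64).ravel()
    if total.shape != (len(hap.sites),) or alt.shape != total.shape:
        raise ValueError("count vectors must align with the haplotype loci")
    covered = total >= 1
    n_covered = int(covered.sum())
    if n_covered == 0:
        return HaplotypeCall(cell=cell, n_covered=0, n_matching=0, p_value=1.0, assigned=False)
    observed_alt = alt >= 1
    hap_alt = np.array([a == "alt" for a in hap.alleles])
    matching = covered & (observed_alt == hap_alt)
    n_matching = int(matching.sum())
    # one-sided exact binomial tail P(X >= k)
    p_value = float(binom.sf(n_matching - 1, n_covered, p0))
    assigned = (n_matching >= min_matching) and (p_value < alpha)
    call = HaplotypeCall(
        cell=cell,
        n_covered=n_covered,
        n_matching=n_matching,
        p_value=p_value,
        assigned=assigned,
    )
    assert not call.assigned or (call.n_matching >= min_matching and call.p_value < alpha)
    return call


def haplotype_calls(
    cvm: CellVariantMatrix,
    hap: Haplotype,
    min_matching: int = 6,
    alpha: float = 0.05,
    p0: float = 0.5,
) -> pd.DataFrame:
    """Haplotype calls for every cell with at least one covered locus."""
    sub = cvm.subset_sites(list(hap.sites))
    rows = []
    for i, cell in enumerate(sub.cells):
        call = haplotype_match(
            sub.total[i],
            sub.alt[i],
            hap,
            cell=str(cell),
            min_matching=min_matching,
            alpha=alpha,
            p0=p0,
        )
        rows.append(
            (call.cell, call.n_covered, call.n_matching, call.p_value, call.assigned)
        )
    return pd.DataFrame(
        rows, columns=["cell", "n_covered", "n_matching", "p_value", "assigned"]
    )


def variant_burden(
    calls: pd.DataFrame, labeling: PopulationLabeling, group_column: str = "population"
) -> pd.DataFrame:
    """Mean carried variants per cell and per-site carrier fractions by group."""
    carried = calls[calls["carries"]]
    per_cell = carried.groupby("cell").size()
    groups = labeling.table[group_column]
    rows = []
    for group, barcodes in groups.groupby(groups).groups.items():
        barcodes = pd.Index(barcodes)
        if len(barcodes) == 0:
            warnings.warn(f"group {group!r} is empty; excluded")
            continue
        counts = per_cell.reindex(barcodes).fillna(0.0)
        sub = calls[calls["cell"].isin(barcodes)]
        frac = (
            sub.groupby("site")["carries"].mean().rename("carrier_fraction")
            if len(sub)
            else pd.Series(dtype=float)
        )
        rows.append(
            {
                "group": group,
                "n_cells": len(barcodes),
                "mean_variants_per_cell": float(counts.mean()),
                "max_carrier_fraction": float(frac.max()) if len(frac) else 0.0,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# readers / writers


def read_allele_counts(path) -> CellVariantMatrix:
    """TSV with columns barcode, chrom, pos, ref, alt, total_reads, alt_reads."""
    t = pd.read_csv(path, sep="\t", dtype={"barcode": str, "chrom": str})
    required = {"barcode", "chrom", "pos", "ref", "alt", "total_reads", "alt_reads"}
    missing = required - set(t.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    sites = [
        VariantSite(chrom=c, pos=int(p), ref=r, alt=a)
        for c, p, r, a in sorted(
            set(zip(t["chrom"], t["pos"], t["ref"], t["alt"]))
        )
    ]
    site_pos = {s.key: j for j, s in enumerate(sites)}
    cells = pd.Index(sorted(t["barcode"].unique()), dtype=object)
    cell_pos = {c: i for i, c in enumerate(cells)}
    total = np.zeros((len(cells), len(sites)), dtype=np.int64)
    alt = np.zeros_like(total)
    keys = (
        t["chrom"].astype(str)
        + ":"
        + t["pos"].astype(int).astype(str)
        + ":"
        + t["ref"].astype(str)
        + ">"
        + t["alt"].astype(str)
    )
    for bc, key, tot, al in zip(t["barcode"], keys, t["total_reads"], t["alt_reads"]):
        total[cell_pos[bc], site_pos[key]] = int(tot)
        alt[cell_pos[bc], site_pos[key]] = int(al)
    return CellVariantMatrix(cells=cells, sites=sites, total=total, alt=alt)


def write_allele_counts(cvm: CellVariantMatrix, path) -> None:
    rows = []
    for i, bc in enumerate(cvm.cells):
        for j, s in enumerate(cvm.sites):
            if cvm.total[i, j] > 0:
                rows.append(
                    (bc, s.chrom, s.pos, s.ref, s.alt, cvm.total[i, j], cvm.alt[i, j])
                )
    pd.DataFrame(
        rows,
        columns=["barcode", "chrom", "pos", "ref", "alt", "total_reads", "alt_reads"],
    ).to_csv(path, sep="\t", index=False)


def read_haplotype(path, name: str = "") -> Haplotype:
    """TSV with columns chrom, pos, ref, alt, hap_allele ('ref' or 'alt')."""
    t = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt", "hap_allele"}
    missing = required - set(t.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    sites = tuple(
        VariantSite(chrom=c, pos=int(p), ref=r, alt=a)
        for c, p, r, a in zip(t["chrom"], t["pos"], t["ref"], t["alt"])
    )
    return Haplotype(name=name or str(path), sites=sites, alleles=tuple(t["hap_allele"]))


def write_haplotype(hap: Haplotype, path) -> None:
    pd.DataFrame(
        {
            "chrom": [s.chrom for s in hap.sites],
            "pos": [s.pos for s in hap.sites],
            "ref": [s.ref for s in hap.sites],
            "alt": [s.alt for s in hap.sites],
            "hap_allele": list(hap.alleles),
        }
    ).to_csv(path, sep="\t", index=False)


def read_vcf_sites(path) -> list[VariantSite]:
    """Variant site definitions from a VCF (uncompressed or bgzipped)."""
    from cyvcf2 import VCF

    sites = []
    for rec in VCF(str(path)):
        for alt in rec.ALT:
            sites.append(VariantSite(chrom=rec.CHROM, pos=rec.POS, ref=rec.REF, alt=alt))
    return sites


def mask_sites_bed(sites: list[VariantSite], bed_path) -> list[VariantSite]:
    """Drop sites inside BED regions (0-based half-open), e.g. CNV deletions."""
    bed = pd.read_csv(
        bed_path, sep="\t", header=None, usecols=[0, 1, 2], names=["chrom", "start", "end"]
    )
    kept = []
    for s in sites:
        zero_based = s.pos - 1
        hit = (
            (bed["chrom"].astype(str) == s.chrom)
            & (bed["start"] <= zero_based)
            & (zero_based < bed["end"])
        ).any()
        if not hit:
            kept.append(s)
    return kept
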
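"""Synthetic data with known ground truth.

The atlas generator emulates a multi-lineage hematopoietic reference: gene
expression programs live on a rooted population tree and drift along edges,
so sibling populations are more similar than distant ones; counts are
negative binomial. Query (leukemia-like) populations are derived from a known
counterpart's program with a planted perturbation. A variant fixture emulates
two clones where one carries a phased alternative haplotype, for haplotype
tracing and burden comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

from ccimap.cci import PopulationTree
from ccimap.core import ExpressionMatrix, GeneSetCollection, PopulationLabeling
from ccimap.io import mito_flags

# HSC-rooted tree of 8 hematopoietic stem/progenitor populations
DEFAULT_TREE_EDGES = (
    ("HSC", "MPP"),
    ("MPP", "CMP"),
    ("MPP", "LMPP"),
    ("CMP", "GMP"),
    ("CMP", "MEP"),
    ("LMPP", "CLP"),
    ("CLP", "ProB"),
)
DEFAULT_ROOT = "HSC"

DEFAULT_QUERIES = (
    ("Q1", "GMP"),
    ("Q2", "ProB"),
    ("Q3", "MEP"),
    ("Q4", "MPP"),
)


@dataclass(frozen=True)
class AtlasSpec:
    """Reference-atlas generator settings.

    Programs are per-population log-mean vectors: a shared baseline
    (log-normal gene means), per-edge drift (a random gene subset shifted in
    log space) and per-population marker genes with a fixed log-fold effect.
    Counts are negative binomial with dispersion ``dispersion`` (variance =
    mu + mu^2 / dispersion).
    """

    seed: int
    edges: tuple = DEFAULT_TREE_EDGES
    root: str = DEFAULT_ROOT
    n_genes: int = 2000
    cells_per_population: int = 200
    baseline_log_mean: float = float(np.log(0.4))
    baseline_log_sd: float = 1.0
    drift_frac: float = 0.08
    drift_scale: float = 1.0
    n_markers: int = 20
    marker_logfc: float = 1.5
    dispersion: float = 2.0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.cells_per_population <= 0:
            raise ValueError("n_genes and cells_per_population must be positive")
        if not (0.0 <= self.drift_frac <= 1.0):
            raise ValueError("drift_frac must be in [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


@dataclass(frozen=True)
class QuerySpec:
    """Query populations planted from known counterparts.

    ``perturb_frac`` of genes get a ``perturb_logfc`` shift (random sign) on
    top of the counterpart's program — the leukemia-like expression change.
    """

    seed: int
    queries: tuple = DEFAULT_QUERIES
    cells_per_population: int = 200
    perturb_frac: float = 0.10
    perturb_logfc: float = 1.0
    sample: str = "patient1"

    def __post_init__(self) -> None:
        if not (0.0 <= self.perturb_frac <= 1.0):
            raise ValueError("perturb_frac must be in [0, 1]")


@dataclass(frozen=True)
class VariantFixtureSpec:
    """Two-clone variant/haplotype fixture with planted clonal structure."""

    seed: int
    cells_per_clone: int = 100
    n_sites: int = 20
    n_shared_sites: int = 10
    shared_carrier_prob: float = 0.3
    private_carrier_prob: float = 0.7
    background_carrier_prob: float = 0.02
    site_depth: float = 2.0
    n_hap_loci: int = 39
    hap_coverage_prob: float = 0.5
    hap_match_prob: float = 0.95
    carrier_clone: str = "relapse"
    clones: tuple = ("diagnosis", "relapse")


@dataclass
class AtlasResult:
    em: ExpressionMatrix
    labels: PopulationLabeling
    tree: PopulationTree
    programs: pd.DataFrame  # populations x genes, log-mean expression
    spec: AtlasSpec


@dataclass
class QueryResult:
    em: ExpressionMatrix
    labels: PopulationLabeling
    truth: pd.DataFrame  # query -> true counterpart


def _nb_counts(
    rng: np.random.Generator, log_mu: np.ndarray, n_cells: int, dispersion: float
) -> sp.csr_matrix:
    mu = np.exp(log_mu)
    p = dispersion / (dispersion + mu)
    counts = rng.negative_binomial(dispersion, p[None, :], size=(n_cells, len(mu)))
    return sp.csr_matrix(counts)


def _gene_ids(n_genes: int) -> list[str]:
    width = len(str(n_genes))
    return [f"G{i:0{width}d}" for i in range(n_genes)]


def simulate_atlas(spec: AtlasSpec) -> AtlasResult:
    """Generate the reference atlas: counts, labels and the population tree."""
    rng = np.random.default_rng(spec.seed)
    tree = PopulationTree(list(spec.edges), spec.root)
    pops = list(nx.topological_sort(tree.graph))
    genes = _gene_ids(spec.n_genes)

    baseline = rng.normal(spec.baseline_log_mean, spec.baseline_log_sd, spec.n_genes)
    programs: dict[str, np.ndarray] = {}
    marker_pool = rng.permutation(spec.n_genes)
    n_markers = min(spec.n_markers, spec.n_genes // max(len(pops), 1))
    for k, pop in enumerate(pops):
        parent = next(iter(tree.graph.predecessors(pop)), None)
        prog = baseline.copy() if parent is None else programs[parent].copy()
        if parent is not None and spec.drift_frac > 0:
            n_drift = int(round(spec.drift_frac * spec.n_genes))
            drifted = rng.choice(spec.n_genes, size=n_drift, replace=False)
            prog[drifted] += rng.normal(0.0, spec.drift_scale, n_drift)
        markers = marker_pool[k * n_markers : (k + 1) * n_markers]
        prog[markers] += spec.marker_logfc
        programs[pop] = prog

    blocks, barcodes, labels = [], [], []
    for pop in pops:
        blocks.append(
            _nb_counts(rng, programs[pop], spec.cells_per_population, spec.dispersion)
        )
        barcodes.extend(
            f"{pop}_{i:04d}" for i in range(spec.cells_per_population)
        )
        labels.extend([pop] * spec.cells_per_population)

    em = ExpressionMatrix(
        barcodes=barcodes,
        genes=genes,
        counts=sp.vstack(blocks).tocsr(),
        mito=mito_flags(genes),
    )
    label_table = pd.DataFrame(
        {
            "population": labels,
            "sample": "atlas",
            "condition": "reference",
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    prog_frame = pd.DataFrame(
        np.vstack([programs[p] for p in pops]), index=pops, columns=genes
    )
    return AtlasResult(
        em=em,
        labels=PopulationLabeling(label_table),
        tree=tree,
        programs=prog_frame,
        spec=spec,
    )


def simulate_queries(atlas: AtlasResult, spec: QuerySpec) -> QueryResult:
    """Generate query populations from known counterparts with planted shifts."""
    rng = np.random.default_rng(spec.seed)
    n_genes = atlas.spec.n_genes
    genes = list(atlas.em.genes)

    blocks, barcodes, labels, truth_rows = [], [], [], []
    for name, counterpart in spec.queries:
        if counterpart not in atlas.programs.index:
            raise KeyError(f"true counterpart {counterpart!r} not in the atlas")
        prog = atlas.programs.loc[counterpart].to_numpy().copy()
        n_shift = int(round(spec.perturb_frac * n_genes))
        if n_shift:
            shifted = rng.choice(n_genes, size=n_shift, replace=False)
            signs = rng.choice([-1.0, 1.0], size=n_shift)
            prog[shifted] += signs * spec.perturb_logfc
        blocks.append(
            _nb_counts(rng, prog, spec.cells_per_population, atlas.spec.dispersion)
        )
        barcodes.extend(f"{name}_{i:04d}" for i in range(spec.cells_per_population))
        labels.extend([name] * spec.cells_per_population)
        truth_rows.append({"query": name, "counterpart": counterpart})

    em = ExpressionMatrix(
        barcodes=barcodes,
        genes=genes,
        counts=sp.vstack(blocks).tocsr(),
        mito=mito_flags(genes),
    )
    label_table = pd.DataFrame(
        {
            "population": labels,
            "sample": spec.sample,
            "condition": "query",
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    return QueryResult(
        em=em,
        labels=PopulationLabeling(label_table),
        truth=pd.DataFrame(truth_rows),
    )


def simulate_gene_sets(
    genes,
    n_sets: int = 50,
    min_size: int = 50,
    max_size: int = 200,
    seed: int | None = None,
) -> GeneSetCollection:
    """Hallmark-like random gene-set collection over the given gene universe."""
    rng = np.random.default_rng(seed)
    genes = list(genes)
    sets = {}
    for k in range(n_sets):
        size = int(rng.integers(min_size, min(max_size, len(genes)) + 1))
        members = rng.choice(len(genes), size=size, replace=False)
        sets[f"SIM_HALLMARK_{k + 1:02d}"] = [genes[i] for i in sorted(members)]
    return GeneSetCollection(sets, provenance="synthetic")


def simulate_variant_fixture(spec: VariantFixtureSpec):
    """Two-clone allele-count fixture with a planted alternative haplotype.

    Returns (CellVariantMatrix, Haplotype, clone truth Series). The matrix
    covers the general variant sites followed by the haplotype loci; the
    carrier clone's observed alleles match the haplotype with probability
    ``hap_match_prob``, non-carriers match at chance (0.5).
    """
    from ccimap.variants import CellVariantMatrix, Haplotype, VariantSite

    rng = np.random.default_rng(spec.seed)
    cells, clones = [], []
    for clone in spec.clones:
        for i in range(spec.cells_per_clone):
            cells.append(f"{clone}_{i:04d}")
            clones.append(clone)
    n_cells = len(cells)
    clone_arr = np.array(clones, dtype=object)

    # general variant sites: shared sites in both clones, private sites in the
    # carrier clone only (the relapse-specific variants)
    sites = [
        VariantSite(chrom="chr1", pos=1000 + 10 * j, ref="G", alt="A")
        for j in range(spec.n_sites)
    ]
    carrier_prob = np.empty((n_cells, spec.n_sites))
    for j in range(spec.n_sites):
        if j < spec.n_shared_sites:
            carrier_prob[:, j] = spec.shared_carrier_prob
        else:
            carrier_prob[:, j] = np.where(
                clone_arr == spec.carrier_clone,
                spec.private_carrier_prob,
                spec.background_carrier_prob,
            )
    depth = rng.poisson(spec.site_depth, size=(n_cells, spec.n_sites))
    carrier = rng.random((n_cells, spec.n_sites)) < carrier_prob
    alt = np.where(carrier, rng.binomial(depth, 0.6), rng.binomial(depth, 0.005))
    alt = np.minimum(alt, depth)

    # haplotype loci: binary allele state per covered locus
    hap_sites = tuple(
        VariantSite(chrom="chr5", pos=50000 + 100 * j, ref="T", alt="C")
        for j in range(spec.n_hap_loci)
    )
    hap_alleles = tuple(
        "alt" if rng.random() < 0.5 else "ref" for _ in range(spec.n_hap_loci)
    )
    hap = Haplotype(name="SIM_ALT_HAPLOTYPE", sites=hap_sites, alleles=hap_alleles)

    covered = rng.random((n_cells, spec.n_hap_loci)) < spec.hap_coverage_prob
    hap_depth = np.where(covered, 1 + rng.poisson(1.0, size=covered.shape), 0)
    is_carrier_cell = (clone_arr == spec.carrier_clone)[:, None]
    match = np.where(
        is_carrier_cell,
        rng.random(covered.shape) < spec.hap_match_prob,
        rng.random(covered.shape) < 0.5,
    )
    hap_is_alt = np.array([a == "alt" for a in hap_alleles])[None, :]
    observed_alt = match == hap_is_alt  # matching a ref-allele locus means no alt reads
    hap_alt = np.where(covered & observed_alt, hap_depth, 0)

    cvm = CellVariantMatrix(
        cells=cells,
        sites=sites + list(hap_sites),
        total=np.hstack([depth, hap_depth]),
        alt=np.hstack([alt, hap_alt]),
    )
    truth = pd.Series(clone_arr, index=pd.Index(cells, name="cell"), name="clone")
    return cvm, hap, truth
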
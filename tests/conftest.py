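import numpy as np
import pytest
import scipy.sparse as sp

from ccimap.core import ExpressionMatrix, PopulationLabeling
from ccimap.preprocess import normalize_umi
from ccimap.simulate import (
    AtlasSpec,
    QuerySpec,
    simulate_atlas,
    simulate_gene_sets,
    simulate_queries,
)

SMALL_TREE = (("HSC", "MPP"), ("MPP", "GMP"), ("MPP", "MEP"))


@pytest.fixture(scope="session")
def small_atlas():
    """4-population atlas, 500 genes, 80 cells/population, normalized."""
    atlas = simulate_atlas(
        AtlasSpec(
            seed=11,
            edges=SMALL_TREE,
            root="HSC",
            n_genes=500,
            cells_per_population=80,
        )
    )
    atlas.em = normalize_umi(atlas.em)
    return atlas


@pytest.fixture(scope="session")
def small_queries(small_atlas):
    q = simulate_queries(
        small_atlas,
        QuerySpec(seed=12, queries=(("Q1", "GMP"), ("Q2", "MEP")), cells_per_population=80),
    )
    q.em = normalize_umi(q.em)
    return q


@pytest.fixture(scope="session")
def small_sets(small_atlas):
    return simulate_gene_sets(
        small_atlas.em.genes, n_sets=10, min_size=20, max_size=50, seed=13
    )


@pytest.fixture
def tiny_em():
    """3 cells x 4 genes, hand-written counts."""
    counts = np.array([[3, 1, 0, 0], [2, 2, 2, 2], [0, 0, 5, 7]])
    return ExpressionMatrix(
        barcodes=["c1", "c2", "c3"],
        genes=["G1", "G2", "G3", "G4"],
        counts=sp.csr_matrix(counts),
    )


def make_labels(barcodes, populations, sample="s1", condition="reference", **extra):
    import pandas as pd

    frame = pd.DataFrame(
        {"population": populations, "sample": sample, "condition": condition, **extra},
        index=pd.Index(barcodes, name="barcode"),
    )
    return PopulationLabeling(frame)
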
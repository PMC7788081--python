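"""End-to-end evaluation protocols on synthetic ground truth.

These drive the full pipeline — generate an atlas with a known population
tree, plant query populations with known counterparts, map them back — and
measure recovery, calibration of the enrichment Z-score, haplotype tracing
operating characteristics and clonal variant burden. They are what the
package's own claims about itself are computed from.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ccimap.cci import CounterpartMapper
from ccimap.gsea import auc_distribution, z_from_auc_distributions
from ccimap.preprocess import normalize_umi
from ccimap.simulate import (
    AtlasSpec,
    QuerySpec,
    VariantFixtureSpec,
    simulate_atlas,
    simulate_gene_sets,
    simulate_queries,
    simulate_variant_fixture,
)
from ccimap.variants import filter_variants, assign_cell_variants, haplotype_calls, variant_burden
from ccimap.core import PopulationLabeling


def recovery_experiment(
    seeds,
    n_resamples: int = 1000,
    size: int = 30,
    n_genes: int = 2000,
    cells_per_population: int = 200,
    perturb_frac: float = 0.10,
    perturb_logfc: float = 1.0,
) -> pd.DataFrame:
    """Counterpart recovery across simulated atlases.

    For each seed: an 8-population atlas, 4 query populations planted from
    known counterparts with the given perturbation, full composite-index
    mapping. Returns one row per (seed, query) with the truth, the
    assignment and the posterior margin.
    """
    rows = []
    for seed in seeds:
        atlas = simulate_atlas(
            AtlasSpec(seed=seed, n_genes=n_genes, cells_per_population=cells_per_population)
        )
        queries = simulate_queries(
            atlas,
            QuerySpec(
                seed=seed + 10_000,
                cells_per_population=cells_per_population,
                perturb_frac=perturb_frac,
                perturb_logfc=perturb_logfc,
            ),
        )
        ref = normalize_umi(atlas.em)
        qry = normalize_umi(queries.em)
        sets = simulate_gene_sets(ref.genes, seed=seed + 20_000)
        mapper = CounterpartMapper(
            n_resamples=n_resamples,
            size=size,
            gene_sets=sets,
            random_state=seed + 30_000,
        ).fit(ref, atlas.labels, tree=atlas.tree)
        result = mapper.map_populations(qry, queries.labels)
        truth = dict(zip(queries.truth["query"], queries.truth["counterpart"]))
        for _, row in result.assignments.iterrows():
            rows.append(
                {
                    "seed": seed,
                    "query": row["query"],
                    "true_counterpart": truth[row["query"]],
                    "assigned": row["counterpart"],
                    "correct": row["counterpart"] == truth[row["query"]],
                    "posterior": row["posterior"],
                    "margin": row["margin"],
                }
            )
    return pd.DataFrame(rows)


def gsea_calibration(
    seed: int,
    n: int = 1000,
    n_cells: int = 150,
    n_genes: int = 600,
) -> dict:
    """Self-contrast and planted-shift calibration of the enrichment Z-score.

    ``self_z`` compares two independent resampled AUC distributions of the
    same population (expected ~0); ``shift_z`` adds exactly one standard
    deviation of the reference distribution to the other and recomputes
    (expected ~1).
    """
    atlas = simulate_atlas(
        AtlasSpec(seed=seed, n_genes=n_genes, cells_per_population=n_cells)
    )
    em = normalize_umi(atlas.em)
    pop = atlas.labels.populations()[0]
    cells = atlas.labels.cells_of(pop)
    gene_set = simulate_gene_sets(em.genes, n_sets=1, seed=seed + 1).sets[
        "SIM_HALLMARK_01"
    ]
    ss = np.random.SeedSequence(seed + 2)
    rng_a, rng_b = (np.random.default_rng(s) for s in ss.spawn(2))
    auc_a = auc_distribution(em, cells, gene_set, n=n, rng=rng_a)
    auc_b = auc_distribution(em, cells, gene_set, n=n, rng=rng_b)
    sd_b = float(np.std(auc_b, ddof=1))
    return {
        "self_z": z_from_auc_distributions(auc_a, auc_b),
        "shift_z": z_from_auc_distributions(auc_a + sd_b, auc_b),
        "n": n,
    }


def haplotype_tracing_rates(seeds) -> dict:
    """Haplotype assignment rate in carrier vs non-carrier clones."""
    carrier_rates, noncarrier_rates = [], []
    for seed in seeds:
        spec = VariantFixtureSpec(seed=seed)
        cvm, hap, truth = simulate_variant_fixture(spec)
        calls = haplotype_calls(cvm, hap).set_index("cell")
        assigned = calls["assigned"]
        is_carrier = truth == spec.carrier_clone
        carrier_rates.append(float(assigned[is_carrier[assigned.index]].mean()))
        noncarrier_rates.append(float(assigned[~is_carrier[assigned.index]].mean()))
    return {
        "carrier_rate": float(np.mean(carrier_rates)),
        "noncarrier_rate": float(np.mean(noncarrier_rates)),
        "n_seeds": len(list(seeds)),
    }


def clonal_burden_experiment(seeds) -> pd.DataFrame:
    """Mean retained-variant burden per cell in each clone, per seed."""
    rows = []
    for seed in seeds:
        spec = VariantFixtureSpec(seed=seed)
        cvm, _, truth = simulate_variant_fixture(spec)
        retained = filter_variants(cvm)
        calls = assign_cell_variants(cvm, retained)
        labeling = PopulationLabeling(
            pd.DataFrame(
                {"population": truth, "sample": "fixture", "condition": "query"},
                index=truth.index,
            )
        )
        burden = variant_burden(calls, labeling)
        by_clone = burden.set_index("group")["mean_variants_per_cell"]
        rows.append(
            {
                "seed": seed,
                "diagnosis": float(by_clone["diagnosis"]),
                "relapse": float(by_clone["relapse"]),
            }
        )
    return pd.DataFrame(rows)
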
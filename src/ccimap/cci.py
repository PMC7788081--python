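"""Counterpart composite index: composite-likelihood mapping of query cell
populations onto a reference atlas.

For each query population and each candidate reference population, four
measurement channels (Euclidean expression distance, Spearman correlation,
explained-variance-weighted PC distance, gene-set enrichment profile
distance) are summarized by the median of an empirical resampling
distribution. Each channel's medians are converted to per-reference
likelihoods via best-candidate tail probabilities under the references' own
resampling distributions; Bayes' rule with a (default uniform) prior gives a
per-channel posterior, and the composite index is the renormalized product of
the per-channel posteriors. The argmax reference is the query population's
"healthy counterpart", and the query is relabeled with an "-L" suffix.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator

from ccimap.core import ExpressionMatrix, GeneSetCollection, PopulationLabeling
from ccimap.preprocess import select_hvg
from ccimap.resample import (
    DEFAULT_RESAMPLES,
    DEFAULT_SIZE,
    STATISTICS,
    EmpiricalNull,
    MeasurementScore,
    PCABasis,
    batch_statistic,
    fit_pca_basis,
)
from ccimap.gsea import DEFAULT_WINDOW, set_index_arrays
from ccimap.sampling import pseudobulk_matrix, sample_cell_indices

LIKELIHOOD_FLOOR = 1e-6
COUNTERPART_SUFFIX = "-L"


class PopulationTree:
    """Rooted tree over reference populations (e.g. the hematopoietic tree).

    Depth from the root quantifies stemness (smaller = more stem-like); the
    undirected path length between two populations is their tree distance.
    """

    def __init__(self, edges, root: str):
        g = nx.DiGraph()
        g.add_edges_from(edges)
        if root not in g:
            raise ValueError(f"root {root!r} not among tree nodes")
        if g.number_of_edges() != g.number_of_nodes() - 1:
            raise ValueError("edges do not form a tree")
        und = g.to_undirected()
        if not nx.is_connected(und):
            raise ValueError("tree is not connected")
        if g.in_degree(root) != 0 or any(
            g.in_degree(n) != 1 for n in g if n != root
        ):
            raise ValueError("every non-root node must have exactly one parent")
        self.graph = g
        self.root = root
        self._depth = nx.shortest_path_length(und, source=root)
        self._und = und

    @property
    def populations(self) -> list[str]:
        return sorted(self.graph.nodes)

    def depth(self, population: str) -> int:
        if population not in self._depth:
            raise KeyError(f"population {population!r} not in tree")
        return self._depth[population]

    def distance(self, a: str, b: str) -> int:
        if a not in self.graph or b not in self.graph:
            raise KeyError(f"population(s) {a!r}/{b!r} not in tree")
        return nx.shortest_path_length(self._und, a, b)


@dataclass
class CounterpartPosterior:
    """Posterior over reference populations for one query population."""

    query: str
    references: list[str]
    channel_likelihoods: dict[str, np.ndarray]
    channel_posteriors: dict[str, np.ndarray]
    combined: np.ndarray
    counterpart: str = field(init=False)
    label: str = field(init=False)

    def __post_init__(self) -> None:
        for name, post in self.channel_posteriors.items():
            if abs(post.sum() - 1.0) > 1e-9:
                raise ValueError(f"channel {name!r} posterior does not sum to 1")
        if abs(self.combined.sum() - 1.0) > 1e-9:
            raise ValueError("combined posterior does not sum to 1")
        self.counterpart = self.references[int(np.argmax(self.combined))]
        self.label = self.counterpart + COUNTERPART_SUFFIX


@dataclass
class MappingReport:
    per_sample: pd.DataFrame
    abundances: pd.DataFrame


def channel_likelihood(
    nulls: list[EmpiricalNull],
    scores: list[MeasurementScore] | None = None,
    floor: float = LIKELIHOOD_FLOOR,
) -> np.ndarray:
    """Per-reference likelihoods for one measurement channel.

    The channel's best observed median S* (smallest for distance channels,
    largest for similarity channels) is referred to each reference's own
    empirical distribution: L_j is the fraction of reference j's resampled
    values at least as favorable as S*, floored at ``floor`` so no single
    channel can zero the composite product.
    """
    if not nulls:
        raise ValueError("no empirical nulls supplied")
    stats = {n.statistic for n in nulls}
    if len(stats) != 1:
        raise ValueError(f"mixed statistics in one channel: {sorted(stats)}")
    for n in nulls:
        if len(n.values) == 0:
            raise ValueError(f"empty null for reference {n.reference!r}")
    medians = np.array([n.median for n in nulls])
    if scores is not None:
        medians = np.array([s.S for s in scores], dtype=float)
    orientation = nulls[0].orientation
    if orientation == "distance":
        s_star = medians.min()
        lik = np.array([np.mean(n.values <= s_star) for n in nulls])
    else:
        s_star = medians.max()
        lik = np.array([np.mean(n.values >= s_star) for n in nulls])
    return np.maximum(lik, floor)


def cci_posterior(
    channel_likelihoods: dict[str, np.ndarray],
    references,
    priors: np.ndarray | None = None,
    query: str = "",
) -> CounterpartPosterior:
    """Combine per-channel likelihoods into the composite posterior.

    Each channel is turned into a posterior by Bayes' rule with the supplied
    prior (uniform by default); the composite index is the product of the
    per-channel posteriors across channels, renormalized over references.
    """
    references = list(references)
    n_r = len(references)
    if not channel_likelihoods:
        raise ValueError("need at least one measurement channel")
    if priors is None:
        priors = np.full(n_r, 1.0 / n_r)
    priors = np.asarray(priors, dtype=float)
    if priors.shape != (n_r,) or abs(priors.sum() - 1.0) > 1e-9:
        raise ValueError("priors must be a probability vector over references")

    posts: dict[str, np.ndarray] = {}
    log_combined = np.zeros(n_r)
    for name, lik in channel_likelihoods.items():
        lik = np.asarray(lik, dtype=float)
        if lik.shape != (n_r,):
            raise ValueError(f"channel {name!r} likelihood length mismatch")
        weighted = lik * priors
        total = weighted.sum()
        if total <= 0:
            raise ValueError(f"channel {name!r} has all-zero likelihoods")
        posts[name] = weighted / total
        with np.errstate(divide="ignore"):
            log_combined += np.log(posts[name])
    log_combined -= log_combined.max()
    combined = np.exp(log_combined)
    combined /= combined.sum()
    return CounterpartPosterior(
        query=query,
        references=references,
        channel_likelihoods={k: np.asarray(v, float) for k, v in channel_likelihoods.items()},
        channel_posteriors=posts,
        combined=combined,
    )


def assign_counterparts(
    posteriors: list[CounterpartPosterior],
    tree: PopulationTree | None = None,
    margin_flag: float = 0.1,
) -> pd.DataFrame:
    """Argmax counterpart per query population with margins and tie handling.

    Exact posterior ties break toward the reference closer to the tree root
    (the conservative, more stem-like call), then lexicographically.
    """
    rows = []
    for post in posteriors:
        combined = post.combined
        best_val = combined.max()
        tied = [r for r, p in zip(post.references, combined) if p == best_val]
        if len(tied) > 1 and tree is not None:
            tied.sort(key=lambda r: (tree.depth(r), r))
        else:
            tied.sort()
        counterpart = tied[0]
        others = combined[[r != counterpart for r in post.references]]
        margin = float(best_val - (others.max() if others.size else 0.0))
        rows.append(
            {
                "query": post.query,
                "counterpart": counterpart,
                "label": counterpart + COUNTERPART_SUFFIX,
                "posterior": float(best_val),
                "margin": margin,
                "flagged": margin < margin_flag,
            }
        )
    return pd.DataFrame(rows)


def mapping_report(
    assignments: pd.DataFrame,
    tree: PopulationTree,
    query_labels: PopulationLabeling,
) -> MappingReport:
    """Per-sample heterogeneity and stemness readouts from mapped positions.

    Heterogeneity = (number of distinct counterparts, maximal pairwise tree
    distance among them); stemness = minimal root distance among them (0 =
    the counterpart set reaches the root).
    """
    for cp in assignments["counterpart"].unique():
        if cp not in tree.graph:
            raise KeyError(f"counterpart {cp!r} absent from the reference tree")
    cp_of = dict(zip(assignments["query"], assignments["counterpart"]))
    t = query_labels.table
    ab_rows = []
    sample_rows = []
    for sample, sub in t.groupby("sample"):
        pops = sub["population"].value_counts(normalize=True)
        cps = sorted({cp_of[p] for p in pops.index if p in cp_of})
        for pop, frac in pops.items():
            ab_rows.append(
                {
                    "sample": sample,
                    "query": pop,
                    "counterpart": cp_of.get(pop, ""),
                    "abundance": float(frac),
                }
            )
        span = max(
            (tree.distance(a, b) for a in cps for b in cps), default=0
        )
        stemness = min((tree.depth(c) for c in cps), default=np.nan)
        sample_rows.append(
            {
                "sample": sample,
                "n_counterparts": len(cps),
                "tree_span": span,
                "stemness_min_depth": stemness,
            }
        )
    return MappingReport(
        per_sample=pd.DataFrame(sample_rows),
        abundances=pd.DataFrame(ab_rows),
    )


@dataclass
class MappingResult:
    """Full output of a counterpart mapping run."""

    posteriors: list[CounterpartPosterior]
    assignments: pd.DataFrame
    scores: pd.DataFrame  # long table: query, reference, channel, S, likelihood
    gene_space: list[str]
    basis: PCABasis


def _name_seed(master: int, *parts: str) -> np.random.SeedSequence:
    key = tuple(zlib.crc32(p.encode()) for p in parts)
    return np.random.SeedSequence(entropy=master, spawn_key=key)


class CounterpartMapper(BaseEstimator):
    """Assign query cell populations to their reference counterparts.

    Parameters
    ----------
    n_resamples : int
        Pseudobulk resampling iterations per (query, reference, channel).
    size : int
        Cells per pseudobulk sample.
    n_hvg : int
        Highly variable genes selected per dataset; the working gene space is
        the union of reference and query HVGs restricted to genes detected in
        both datasets.
    n_pcs : int
        Principal components for the weighted PC-distance channel, fitted on
        the joint normalized matrix.
    window : int
        Recovery-curve AUC window for the enrichment-profile channel.
    channels : tuple of str
        Measurement channels to combine.
    gene_sets : GeneSetCollection or None
        Gene sets for the enrichment channel; if None that channel is dropped
        with a warning.
    priors : dict or None
        Prior probability per reference population (uniform if None).
    likelihood_floor : float
        Lower bound on channel likelihoods before normalization.
    random_state : int or None
        Master seed; per-(query, reference) resampling streams are derived
        from it keyed by population names, so results are independent of
        reference ordering. All channels for a pair are computed from the
        same pseudobulk draws.
    """

    def __init__(
        self,
        n_resamples: int = DEFAULT_RESAMPLES,
        size: int = DEFAULT_SIZE,
        n_hvg: int = 2000,
        n_pcs: int = 30,
        window: int = DEFAULT_WINDOW,
        channels: tuple = STATISTICS,
        gene_sets: GeneSetCollection | None = None,
        priors: dict | None = None,
        likelihood_floor: float = LIKELIHOOD_FLOOR,
        random_state: int | None = None,
    ):
        self.n_resamples = n_resamples
        self.size = size
        self.n_hvg = n_hvg
        self.n_pcs = n_pcs
        self.window = window
        self.channels = channels
        self.gene_sets = gene_sets
        self.priors = priors
        self.likelihood_floor = likelihood_floor
        self.random_state = random_state

    # -- estimator API ---------------------------------------------------
    def fit(
        self,
        reference: ExpressionMatrix,
        labels: PopulationLabeling,
        tree: PopulationTree | None = None,
    ) -> "CounterpartMapper":
        """Store the reference atlas (normalized matrix + population labels)."""
        if reference.normalized is None:
            raise ValueError("reference matrix needs a normalized layer")
        labels.validate_against(reference)
        pops = labels.populations()
        if not pops:
            raise ValueError("reference labeling has no populations")
        for p in pops:
            if len(labels.cells_of(p)) < self.size:
                warnings.warn(
                    f"reference population {p!r} has fewer than {self.size} "
                    "cells; pseudobulks will sample with replacement"
                )
        if tree is not None:
            missing = set(pops) - set(tree.graph.nodes)
            if missing:
                raise ValueError(f"tree missing reference populations: {sorted(missing)}")
        self.reference_ = reference
        self.reference_labels_ = labels
        self.tree_ = tree
        self.reference_populations_ = pops
        self.reference_hvg_ = select_hvg(
            reference, min(self.n_hvg, reference.n_genes)
        )
        return self

    def map_populations(
        self, query: ExpressionMatrix, labels: PopulationLabeling
    ) -> MappingResult:
        """Compute posteriors and counterpart assignments for all query populations."""
        self._check_fitted()
        if query.normalized is None:
            raise ValueError("query matrix needs a normalized layer")
        labels.validate_against(query)
        q_pops = labels.populations()
        if not q_pops:
            raise ValueError("query labeling has no populations")

        channels = list(self.channels)
        sets = self.gene_sets
        if "gsea_profile" in channels and (sets is None or len(sets) == 0):
            warnings.warn("no gene sets supplied; dropping the enrichment channel")
            channels = [c for c in channels if c != "gsea_profile"]
        if not channels:
            raise ValueError("no measurement channels left to combine")

        gene_space = self._gene_space(query)
        master = 0 if self.random_state is None else int(self.random_state)

        ref_em = self.reference_.subset_genes(gene_space)
        qry_em = query.subset_genes(gene_space)
        Xr_all = ref_em.normalized
        Xq_all = qry_em.normalized

        # joint PCA basis over the shared gene space
        basis = None
        if "pc_dist" in channels:
            joint = sp.vstack([Xr_all, Xq_all])
            basis = fit_pca_basis(joint, gene_space, n_components=self.n_pcs)

        genes_arr = np.asarray(gene_space, dtype=object)
        order = np.argsort(genes_arr, kind="stable")
        set_indices = None
        if "gsea_profile" in channels:
            restricted = sets.restrict(gene_space)
            if len(restricted) == 0:
                raise ValueError("gene sets share no genes with the working gene space")
            set_indices = set_index_arrays(restricted, genes_arr[order])

        refs = self.reference_populations_
        priors = self._prior_vector(refs)

        # densify per-population views once; pseudobulk products hit BLAS paths
        ref_X = {
            r: Xr_all[ref_em.barcodes.get_indexer(self.reference_labels_.cells_of(r))].toarray()
            for r in refs
        }
        qry_X = {
            q: Xq_all[qry_em.barcodes.get_indexer(labels.cells_of(q))].toarray()
            for q in q_pops
        }

        posteriors = []
        score_rows = []
        for qpop in q_pops:
            Xq = qry_X[qpop]
            chan_lik: dict[str, np.ndarray] = {}
            chan_nulls: dict[str, list[EmpiricalNull]] = {c: [] for c in channels}
            for rpop in refs:
                Xr = ref_X[rpop]
                # one resampling per population pair; every channel is
                # computed from the same pseudobulk draws
                rng = np.random.default_rng(_name_seed(master, qpop, rpop))
                dq = sample_cell_indices(Xq.shape[0], self.size, self.n_resamples, rng)
                dr = sample_cell_indices(Xr.shape[0], self.size, self.n_resamples, rng)
                P = pseudobulk_matrix(Xq, dq)
                Q = pseudobulk_matrix(Xr, dr)
                for chan in channels:
                    if chan == "gsea_profile":
                        values = batch_statistic(
                            chan,
                            P[:, order],
                            Q[:, order],
                            set_indices=set_indices,
                            window=self.window,
                        )
                    else:
                        values = batch_statistic(chan, P, Q, basis=basis)
                    chan_nulls[chan].append(
                        EmpiricalNull(
                            statistic=chan,
                            query=qpop,
                            reference=rpop,
                            values=values,
                            orientation="similarity" if chan == "spearman" else "distance",
                        )
                    )
            for chan in channels:
                chan_lik[chan] = channel_likelihood(
                    chan_nulls[chan], floor=self.likelihood_floor
                )
            post = cci_posterior(chan_lik, refs, priors=priors, query=qpop)
            posteriors.append(post)
            for chan in channels:
                for j, rpop in enumerate(refs):
                    score_rows.append(
                        {
                            "query": qpop,
                            "reference": rpop,
                            "channel": chan,
                            "S": chan_nulls[chan][j].median,
                            "likelihood": chan_lik[chan][j],
                            "posterior": post.channel_posteriors[chan][j],
                            "combined": post.combined[j],
                        }
                    )

        assignments = assign_counterparts(posteriors, tree=self.tree_)
        return MappingResult(
            posteriors=posteriors,
            assignments=assignments,
            scores=pd.DataFrame(score_rows),
            gene_space=gene_space,
            basis=basis,
        )

    def predict(self, query: ExpressionMatrix, labels: PopulationLabeling) -> pd.Series:
        """Counterpart label ("<reference>-L") per query population."""
        result = self.map_populations(query, labels)
        return result.assignments.set_index("query")["label"]

    def predict_proba(
        self, query: ExpressionMatrix, labels: PopulationLabeling
    ) -> pd.DataFrame:
        """Combined posterior (query populations x reference populations)."""
        result = self.map_populations(query, labels)
        return pd.DataFrame(
            [p.combined for p in result.posteriors],
            index=[p.query for p in result.posteriors],
            columns=self.reference_populations_,
        )

    # -- helpers ----------------------------------------------------------
    def _check_fitted(self) -> None:
        if not hasattr(self, "reference_"):
            raise RuntimeError("CounterpartMapper is not fitted; call fit() first")

    def _prior_vector(self, refs: list[str]) -> np.ndarray:
        if self.priors is None:
            return np.full(len(refs), 1.0 / len(refs))
        vec = np.array([float(self.priors[r]) for r in refs])
        if abs(vec.sum() - 1.0) > 1e-9:
            raise ValueError("priors must sum to 1 over reference populations")
        return vec

    def _gene_space(self, query: ExpressionMatrix) -> list[str]:
        q_hvg = select_hvg(query, min(self.n_hvg, query.n_genes))
        union = set(self.reference_hvg_) | set(q_hvg)
        det_ref = set(
            np.asarray(self.reference_.genes, dtype=object)[
                np.asarray((self.reference_.counts > 0).sum(axis=0)).ravel() > 0
            ]
        )
        det_qry = set(
            np.asarray(query.genes, dtype=object)[
                np.asarray((query.counts > 0).sum(axis=0)).ravel() > 0
            ]
        )
        space = sorted(union & det_ref & det_qry)
        if len(space) < 3:
            raise ValueError("shared gene space is too small to compare populations")
        return space
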
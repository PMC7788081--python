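"""Regulator scoring along pseudotime trajectories and TF co-expression networks.

A transcriptional regulator i is scored on trajectory j as
score = c * m * n, where c is the mutual information (bits) between the
regulator's expression and pseudotime, m is the mean MI between its predicted
targets and pseudotime, and n is the number of targets whose MI exceeds a
permutation null (i.e. targets actually regulated along the trajectory).

Lineage-coordinated TFs are those whose expression changes significantly
along the lineage; their co-expression graph keeps an edge when Pearson
r > 0.1 and keeps a node only while it has at least 5 such partners (applied
iteratively to a fixed point).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr
from statsmodels.stats.multitest import multipletests

from ccimap.core import ExpressionMatrix, PopulationLabeling


@dataclass(frozen=True)
class TrajectoryAssignment:
    """Ordered cells of one lineage with pseudotime values."""

    lineage: str
    barcodes: tuple
    pseudotime: np.ndarray

    def __post_init__(self) -> None:
        pt = np.asarray(self.pseudotime, dtype=float)
        if len(self.barcodes) != len(pt):
            raise ValueError("barcodes and pseudotime must align")
        if len(pt) < 20:
            raise ValueError("need at least 20 cells per trajectory for binning")
        if not np.all(np.isfinite(pt)) or np.any(pt < 0):
            raise ValueError("pseudotime must be finite and non-negative")
        object.__setattr__(self, "pseudotime", pt)

    @classmethod
    def from_labels(cls, labeling: PopulationLabeling, lineage: str) -> "TrajectoryAssignment":
        t = labeling.table
        if "pseudotime" not in t.columns:
            raise ValueError("label table has no pseudotime column")
        sub = t[(t.get("lineage") == lineage) & t["pseudotime"].notna()]
        return cls(
            lineage=lineage,
            barcodes=tuple(sub.index),
            pseudotime=sub["pseudotime"].to_numpy(dtype=float),
        )


@dataclass(frozen=True)
class GRNScore:
    regulator: str
    lineage: str
    c: float
    m: float
    n: int

    @property
    def score(self) -> float:
        return self.c * self.m * self.n


def _rank_bins(x: np.ndarray, bins: int) -> np.ndarray:
    """Equal-frequency bin codes by stable rank position."""
    n = len(x)
    order = np.argsort(x, kind="stable")
    codes = np.empty(n, dtype=np.int64)
    codes[order] = (np.arange(n) * bins) // n
    return codes


def mi_from_joint(joint: np.ndarray) -> float:
    """Plug-in mutual information (bits) from a joint count/probability table."""
    joint = np.asarray(joint, dtype=float)
    total = joint.sum()
    if total <= 0:
        raise ValueError("empty joint table")
    p = joint / total
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    return float(np.sum(p[mask] * np.log2(p[mask] / (px @ py)[mask])))


def mutual_info(x, t, bins: int = 10) -> float:
    """Plug-in MI (bits) between two vectors on equal-frequency bins.

    Constant vectors carry no information and return 0.
    """
    x = np.asarray(x, dtype=float).ravel()
    t = np.asarray(t, dtype=float).ravel()
    if x.shape != t.shape:
        raise ValueError("vectors must align")
    if len(x) < bins:
        raise ValueError(f"need at least {bins} observations for {bins} bins")
    if np.ptp(x) == 0 or np.ptp(t) == 0:
        return 0.0
    cx = _rank_bins(x, bins)
    ct = _rank_bins(t, bins)
    joint = np.bincount(cx * bins + ct, minlength=bins * bins).reshape(bins, bins)
    return mi_from_joint(joint)


def _mi_from_codes(cx: np.ndarray, ct: np.ndarray, bins: int) -> float:
    joint = np.bincount(cx * bins + ct, minlength=bins * bins).reshape(bins, bins)
    return mi_from_joint(joint)


def grn_score(
    regulator: str,
    regulator_expr,
    target_exprs: dict,
    trajectory: TrajectoryAssignment,
    bins: int = 10,
    mi_threshold_quantile: float = 0.95,
    n_perm: int = 100,
    seed: int | None = None,
) -> GRNScore:
    """Score one regulator on one trajectory as c * m * n.

    A target counts toward n when its MI with pseudotime exceeds the
    ``mi_threshold_quantile`` of its own permutation null (``n_perm``
    shuffles of the pseudotime bin codes).
    """
    t = trajectory.pseudotime
    c = mutual_info(regulator_expr, t, bins=bins)
    if not target_exprs:
        warnings.warn(f"regulator {regulator!r} has no predicted targets; score 0")
        return GRNScore(regulator=regulator, lineage=trajectory.lineage, c=c, m=0.0, n=0)

    rng = np.random.default_rng(seed)
    ct = _rank_bins(t, bins) if np.ptp(t) > 0 else None
    mis = {}
    n_regulated = 0
    for name in sorted(target_exprs):
        expr = np.asarray(target_exprs[name], dtype=float).ravel()
        mi = mutual_info(expr, t, bins=bins)
        mis[name] = mi
        if ct is None or np.ptp(expr) == 0:
            continue
        cx = _rank_bins(expr, bins)
        null = np.array(
            [_mi_from_codes(cx, rng.permutation(ct), bins) for _ in range(n_perm)]
        )
        if mi > np.quantile(null, mi_threshold_quantile):
            n_regulated += 1
    m = float(np.mean(list(mis.values())))
    return GRNScore(
        regulator=regulator, lineage=trajectory.lineage, c=c, m=m, n=n_regulated
    )


def lineage_tfs(
    em: ExpressionMatrix,
    trajectory: TrajectoryAssignment,
    tf_list,
    fdr: float = 0.05,
) -> list[str]:
    """TFs whose expression changes along the lineage (Spearman + BH-FDR)."""
    if em.normalized is None:
        raise ValueError("normalized layer missing; call normalize_umi first")
    tf_list = list(tf_list)
    gidx = em.genes.get_indexer(pd.Index(tf_list))
    if np.any(gidx < 0):
        missing = [g for g, i in zip(tf_list, gidx) if i < 0]
        raise KeyError(f"TFs absent from the gene universe: {missing[:5]}")
    cidx = em.barcodes.get_indexer(pd.Index(list(trajectory.barcodes)))
    if np.any(cidx < 0):
        raise KeyError("trajectory barcodes absent from the matrix")
    X = em.normalized[cidx][:, gidx].toarray()
    t = trajectory.pseudotime
    pvals = np.ones(len(tf_list))
    for j in range(X.shape[1]):
        if np.ptp(X[:, j]) == 0:
            continue
        pvals[j] = spearmanr(X[:, j], t).pvalue
    reject, _, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    return [tf for tf, r in zip(tf_list, reject) if r]


def _prune_low_degree(g: nx.Graph, min_degree: int) -> nx.Graph:
    """Iteratively drop nodes with degree < min_degree until stable.

    The result is the (min_degree)-core, a unique fixed point independent of
    removal order.
    """
    g = g.copy()
    while True:
        drop = [n for n, d in g.degree() if d < min_degree]
        if not drop:
            return g
        g.remove_nodes_from(drop)


def build_tf_network(
    em: ExpressionMatrix,
    coordinated_tfs,
    cells=None,
    r_threshold: float = 0.1,
    min_degree: int = 5,
    lineage: str = "",
) -> nx.Graph:
    """Lineage-coordinated TF co-expression network.

    Edges connect TF pairs with Pearson r > ``r_threshold`` on the normalized
    layer (over ``cells`` if given); nodes with fewer than ``min_degree``
    partners are removed iteratively until stable. Node attributes carry mean
    expression; edges carry r.
    """
    if em.normalized is None:
        raise ValueError("normalized layer missing; call normalize_umi first")
    tfs = list(coordinated_tfs)
    if len(tfs) < min_degree + 1:
        warnings.warn(
            f"fewer than {min_degree + 1} coordinated TFs; network is empty"
        )
        g = nx.Graph()
        g.graph["lineage"] = lineage
        return g
    gidx = em.genes.get_indexer(pd.Index(tfs))
    if np.any(gidx < 0):
        raise KeyError("coordinated TFs absent from the gene universe")
    if cells is not None:
        cidx = em.barcodes.get_indexer(pd.Index(list(cells)))
        if np.any(cidx < 0):
            raise KeyError("cells absent from the matrix")
        X = em.normalized[cidx][:, gidx].toarray()
    else:
        X = em.normalized[:, gidx].toarray()

    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)

    g = nx.Graph(lineage=lineage)
    means = X.mean(axis=0)
    for i, tf in enumerate(tfs):
        g.add_node(tf, mean_expression=float(means[i]))
    for i in range(len(tfs)):
        for j in range(i + 1, len(tfs)):
            if corr[i, j] > r_threshold:
                g.add_edge(tfs[i], tfs[j], r=float(corr[i, j]))
    pruned = _prune_low_degree(g, min_degree)
    if pruned.number_of_nodes() == 0:
        warnings.warn("no TF reaches the degree threshold; network is empty")
    return pruned


def network_tables(g: nx.Graph) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Edge list (tf_a, tf_b, r) and node table (tf, degree, mean_expression)."""
    edges = pd.DataFrame(
        [(a, b, d["r"]) for a, b, d in g.edges(data=True)],
        columns=["tf_a", "tf_b", "r"],
    )
    nodes = pd.DataFrame(
        [
            (n, g.degree(n), d.get("mean_expression", np.nan))
            for n, d in g.nodes(data=True)
        ],
        columns=["tf", "degree", "mean_expression"],
    )
    return edges.sort_values(["tf_a", "tf_b"]).reset_index(drop=True), nodes.sort_values(
        "tf"
    ).reset_index(drop=True)
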
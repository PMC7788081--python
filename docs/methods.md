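# Methods

This note documents the statistical model implemented by `ccimap`, the
default parameters and why they were chosen, the synthetic data generator,
numerical choices, and known limitations.

## 1. Input processing

**QC.** Cells are retained when they express 500–4000 genes (inclusive) and
at most 10% of their UMIs map to mitochondrial genes (`MT-` prefix,
case-insensitive). Boundaries are inclusive on the permitted side; the report
records each removed barcode with its reason.

**Normalization.** Each cell's counts are scaled to the median total UMI
count across cells, then log-transformed: `log1p(count / total * median)`.
Zero-total cells are an error (QC should have removed them). Zeros are
preserved and within-cell rank order is unchanged.

**Highly variable genes.** Dispersion = variance/mean of the normalized
layer, computed per gene over expressed genes, z-scored within 20
equal-count mean bins; the top `n_hvg` (default 2000) by z are kept, ties
broken lexicographically. The working gene space for mapping is the union of
reference and query HVGs restricted to genes detected (≥1 count) in both
datasets.

## 2. Counterpart composite index

For query population *q* and reference population *r*:

1. Draw 30 cells (without replacement when the population allows, otherwise
   with replacement) from each side and average their normalized profiles
   (*pseudobulk*). Repeat `n_resamples` times (default 10,000); all four
   channels are evaluated on the **same** draws, so channels are exactly
   comparable within a pair.
2. Channels: Euclidean distance; Spearman correlation; PC distance
   `sqrt(Σ_k w_k (z_k(p) − z_k(q))²)` where `z` projects onto the top-30 PCs
   of the joint (reference + query) normalized matrix and `w_k` are
   explained-variance fractions; and the Euclidean distance between the two
   gene-set recovery-AUC vectors (Section 3).
3. The empirical distribution's median is the pair score `S(q, r)` for the
   channel. Let `S*` be the most favorable score across references (min for
   distances, max for the correlation). The channel likelihood of reference
   *r* is the fraction of *r*'s own resampled values at least as favorable
   as `S*`, floored at `likelihood_floor` (default 1e-6) so a single channel
   cannot zero the product.
4. Bayes' rule with the prior (uniform by default) gives a per-channel
   posterior; the composite index is the renormalized product of the
   per-channel posteriors (computed in log space). The argmax reference is
   the counterpart; the query is relabeled `<reference>-L`. Exact posterior
   ties break toward the tree root (the conservative, more stem-like call),
   then lexicographically. Assignments with top-2 margin < 0.1 are flagged.

**Why a best-candidate tail probability?** The likelihood of `S` under
reference *r*'s resampling distribution must be comparable across channels
with different units. The tail fraction is scale-free, lies in [0, 1], is ~0.5
for the best candidate itself (its median sits at the center of its own
distribution), and decays for references whose distributions sit far from the
best score. Alternatives (kernel density evaluation of `S`) are
bandwidth-sensitive and were rejected.

**Reproducibility.** Each (query, reference) pair's resampling stream is
seeded from the master `random_state` keyed by the two population **names**
(CRC-32 spawn keys of a `SeedSequence`), so posteriors are bit-identical
under any reordering of the reference populations or cells' storage order.

**Reported summaries.** Per sample: number of distinct counterparts, maximal
pairwise tree distance among them (heterogeneity span) and minimal root
distance (stemness). These are this package's formalization of qualitative
tree-coverage readouts; the tree is supplied as a parent/child edge list.

## 3. Recovery-curve gene-set enrichment

Genes are ranked by descending expression within a pseudobulk profile (ties
broken by gene id, so the ranking is deterministic). Walking down the list,
the recovery curve counts cumulative gene-set members; `raw_auc` sums the
curve over the top `L` ranks (default window L = 5000, truncated to the
number of genes) and `norm_auc` divides by the top-packed maximum
`m(m+1)/2 + (L−m)m` with `m = min(|set ∩ universe|, L)`, so 1 means all
reachable members lead the list and 0 means none appear in the window.
Population contrasts use `z = (mean AUC_A − mean AUC_B) / sd(AUC_B)` over
resampled AUC distributions (default 10,000 per side); z > 0 means the set
ranks higher in A. Calibration on synthetic data: |z| < 0.1 for A ≡ B and
z ≈ 1 for a distribution shifted by exactly one reference standard
deviation.

## 4. Regulator scoring and TF networks

A regulator on a trajectory is scored `c · m · n`: `c` is the plug-in mutual
information (bits, 10×10 equal-frequency bins) between the regulator's
expression and pseudotime; `m` is the mean MI between its predicted targets
and pseudotime; `n` counts targets whose MI exceeds the 95th percentile of a
100-permutation null (shuffling the pseudotime bin codes). Equal-frequency
binning by stable rank position makes MI invariant to monotone transforms of
either variable; constant vectors carry zero information by definition.

Lineage-coordinated TFs are those whose expression correlates with
pseudotime (Spearman, Benjamini–Hochberg FDR < 0.05). Their co-expression
network keeps edges with Pearson r > 0.1 and then removes nodes with fewer
than 5 qualifying partners iteratively to a fixed point — the 5-core, which
is independent of removal order.

## 5. Entropy

Per-cell Shannon entropy `−Σ p_i log2 p_i` over the cell's raw UMI
proportions across expressed genes, in bits. Raw counts keep the measure
self-contained per cell and invariant to scaling; a cell expressing *n*
genes uniformly scores exactly `log2 n`.

## 6. Variants and haplotype tracing

Per-cell, per-site total/alt read counts are consumed as a TSV (variant
calling happens upstream). A site is retained when (1) it is covered (≥1
read) in ≥ 20 cells, (2) ≥ 5 cells have > 2 reads, and (3) the alternative
allele is observed in ≥ 3 cells. A cell carries a variant when ≥ 1 alt read
is present at the site.

For clonal tracing against a phased alternative haplotype, a covered locus's
observed allele is `alt` when any alt read is present, else `ref`. With
`n_covered` covered loci and `n_matching` matches, the p-value is the exact
one-sided binomial tail `P(X ≥ n_matching | n_covered, p0 = 0.5)`. A cell is
assigned the haplotype only when **both** `n_matching ≥ 6` (more than 5
loci) and p < 0.05; 5/5 matches is significant (p = 1/32) but not assigned.
Sites inside CNV-deleted regions can be masked with a BED file.

## 7. Synthetic data generator

The atlas is an 8-population rooted tree
(HSC → MPP → {CMP → {GMP, MEP}, LMPP → CLP → ProB}). Each population's
log-mean expression program is inherited from its parent with drift (8% of
genes shifted by N(0, 1)) plus 20 population-specific marker genes at +1.5
log-fold; baseline log-means are N(ln 0.4, 1). Counts are negative binomial
with dispersion 2.0 (variance = μ + μ²/2). Query populations copy a
counterpart's program and perturb 10% of genes by ±1.0 log-fold — enough to
be a distinct population while remaining nearest its counterpart. The
variant fixture has two clones (diagnosis, relapse); both share some
variants, the relapse clone carries private variants and a 39-locus
alternative haplotype observed with coverage probability 0.5 and per-locus
match probability 0.95 (non-carriers match at the chance rate 0.5).

What the generator deliberately does **not** emulate: batch effects,
doublets, ambient RNA, gene-gene correlation within a program beyond the
tree structure, or realistic dropout curves. It exists to give the methods
planted ground truth, not to mimic a particular instrument.

## 8. Numerical choices

- Pseudobulk means are computed as a sparse selection matrix product, and
  statistics are evaluated in batches (ranked via `scipy.stats.rankdata`
  row-wise; AUC via a stable argsort and clipped rank contributions), which
  makes the 10,000-resample default tractable on one CPU.
- PCA uses the covariance eigendecomposition path when cells > genes, exact
  SVD otherwise.
- Posterior products are accumulated in log space and renormalized after
  subtracting the maximum, avoiding underflow with many channels or extreme
  likelihood ratios.
- All Monte-Carlo streams come from `numpy.random.Generator` seeded through
  `SeedSequence`; no global RNG state is used.

## 9. Open design decisions

- The composite formula is read as a product over measurement channels of
  per-channel posteriors for each reference; other index conventions would
  conflict with per-measurement score definitions.
- The likelihood estimator (best-candidate tail fraction) is one defensible
  choice among several; kernel density estimates were rejected as
  bandwidth-sensitive. Whether to renormalize the product (we do) or report
  the raw product is a convention; renormalization makes the output a
  probability vector.
- Priors over references default to uniform; the CLI accepts a prior table.

## 10. Limitations

- Mapping is per-population, not per-cell; heterogeneous query clusters
  should be subclustered first.
- The posterior is conditional on the four chosen channels and the resampling
  scheme; it is calibrated in the Monte-Carlo sense but is not a formal joint
  likelihood (channels share draws and are correlated).
- With fewer than 30 cells in a population, pseudobulks sample with
  replacement and the empirical nulls narrow artificially; a warning is
  emitted.
- The enrichment channel is dropped (with a warning) when no gene sets are
  supplied.
- Plug-in MI on 10 bins is biased upward for small cell numbers; the
  permutation null absorbs this for target counting, but reported `c` and
  `m` values retain the bias.
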
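import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from ccimap.core import ExpressionMatrix, FormatError
from ccimap.io import read_counts, read_gmt, write_counts, write_gmt, read_tree, write_tree
from ccimap.preprocess import QCThresholds, apply_qc, normalize_umi, select_hvg
from ccimap.simulate import AtlasSpec, simulate_atlas, simulate_gene_sets

from conftest import make_labels


class TestReadCounts:
    def test_triplet_round_trip_is_lossless(self, tmp_path, tiny_em):
        write_counts(tiny_em, tmp_path / "trip")
        back = read_counts(tmp_path / "trip")
        assert list(back.barcodes) == list(tiny_em.barcodes)
        assert list(back.genes) == list(tiny_em.genes)
        assert (back.counts != tiny_em.counts).nnz == 0

    def test_synthetic_matrix_round_trip(self, tmp_path):
        atlas = simulate_atlas(AtlasSpec(seed=3, n_genes=120, cells_per_population=15))
        write_counts(atlas.em, tmp_path / "atlas")
        back = read_counts(tmp_path / "atlas")
        assert (back.counts != atlas.em.counts).nnz == 0

    def test_dense_table(self, tmp_path):
        frame = pd.DataFrame(
            [[1, 0], [2, 3]], index=["c1", "c2"], columns=["G1", "MT-G2"]
        )
        frame.to_csv(tmp_path / "dense.tsv", sep="\t")
        em = read_counts(tmp_path / "dense.tsv")
        assert em.counts.toarray().tolist() == [[1, 0], [2, 3]]
        assert em.mito.tolist() == [False, True]

    def test_dimension_mismatch_names_file(self, tmp_path, tiny_em):
        write_counts(tiny_em, tmp_path / "bad")
        (tmp_path / "bad" / "barcodes.tsv").write_text("c1\nc2\n")  # one short
        with pytest.raises(FormatError, match="matrix.mtx"):
            read_counts(tmp_path / "bad")

    def test_empty_matrix_file_is_format_error(self, tmp_path):
        d = tmp_path / "empty"
        d.mkdir()
        (d / "matrix.mtx").write_text("")
        (d / "barcodes.tsv").write_text("c1\n")
        (d / "features.tsv").write_text("G1\n")
        with pytest.raises(FormatError):
            read_counts(d)

    def test_duplicate_barcodes_rejected(self, tmp_path, tiny_em):
        write_counts(tiny_em, tmp_path / "dup")
        (tmp_path / "dup" / "barcodes.tsv").write_text("c1\nc1\nc3\n")
        with pytest.raises(FormatError, match="duplicate"):
            read_counts(tmp_path / "dup")


class TestExpressionMatrixInvariants:
    def test_negative_counts_rejected(self):
        with pytest.raises(FormatError):
            ExpressionMatrix(["c1"], ["G1"], sp.csr_matrix(np.array([[-1.0]])))

    def test_fractional_counts_rejected(self):
        with pytest.raises(FormatError):
            ExpressionMatrix(["c1"], ["G1"], sp.csr_matrix(np.array([[0.5]])))


class TestQC:
    @staticmethod
    def _matrix_with(detected, mito_umis=0, total=None):
        """One cell over 600 genes (first is mitochondrial) with exact stats."""
        from ccimap.io import mito_flags

        n_genes = 600
        counts = np.zeros(n_genes, dtype=int)
        counts[0] = mito_umis
        counts[1:detected] = 1
        if total is not None:
            assert counts.sum() <= total
            counts[1] += total - counts.sum()
        genes = ["MT-0"] + [f"G{i}" for i in range(1, n_genes)]
        return ExpressionMatrix(
            ["cell"], genes, sp.csr_matrix(counts[None, :]), mito=mito_flags(genes)
        )

    @pytest.mark.parametrize(
        "detected,retained",
        [(499, False), (500, True), (4000, True)],
    )
    def test_gene_detection_boundaries(self, detected, retained):
        n_genes = 4100
        counts = np.zeros(n_genes, dtype=int)
        counts[:detected] = 1
        genes = [f"G{i}" for i in range(n_genes)]
        em = ExpressionMatrix(["cell"], genes, sp.csr_matrix(counts[None, :]))
        filtered, report = apply_qc(em)
        assert (filtered.n_cells == 1) is retained
        if not retained:
            assert "genes_detected" in report.removed["reason"].iloc[0]

    @pytest.mark.parametrize("mito_umis,retained", [(100, True), (101, False)])
    def test_mito_fraction_boundary(self, mito_umis, retained):
        em = self._matrix_with(detected=600, mito_umis=mito_umis, total=1000)
        assert em.total_counts()[0] == 1000
        filtered, _ = apply_qc(em)
        assert (filtered.n_cells == 1) is retained

    def test_all_pass_is_identity_and_idempotent(self, small_atlas):
        em = small_atlas.em
        loose = QCThresholds(min_genes_per_cell=1, max_genes_per_cell=10**6, max_mito_fraction=1.0)
        once, report = apply_qc(em, loose)
        assert report.n_retained == em.n_cells
        twice, _ = apply_qc(once, loose)
        assert (twice.counts != em.counts).nnz == 0

    def test_all_removed_warns_not_raises(self, tiny_em):
        with pytest.warns(UserWarning, match="every cell"):
            filtered, _ = apply_qc(tiny_em)  # tiny cells < 500 genes
        assert filtered.n_cells == 0


class TestNormalize:
    def test_stated_scaling_example(self):
        # cell totals (4, 8, 12) -> median 8; first cell (3,1,0) scales to (6,2,0)
        counts = np.array([[3, 1, 0], [8, 0, 0], [12, 0, 0]])
        em = ExpressionMatrix(["a", "b", "c"], ["G1", "G2", "G3"], sp.csr_matrix(counts))
        norm = normalize_umi(em).normalized.toarray()
        assert np.allclose(norm[0], [np.log(7), np.log(3), 0.0])

    def test_identical_totals_scale_factor_one(self):
        counts = np.array([[2, 2], [1, 3]])
        em = ExpressionMatrix(["a", "b"], ["G1", "G2"], sp.csr_matrix(counts))
        norm = normalize_umi(em).normalized.toarray()
        assert np.allclose(norm, np.log1p(counts))

    def test_zero_total_cell_is_error(self):
        counts = np.array([[1, 0], [0, 0]])
        em = ExpressionMatrix(["a", "b"], ["G1", "G2"], sp.csr_matrix(counts))
        with pytest.raises(ValueError, match="apply_qc"):
            normalize_umi(em)

    def test_zeros_and_rank_order_preserved(self, small_atlas):
        em = small_atlas.em
        raw = em.counts[:5].toarray()
        norm = em.normalized[:5].toarray()
        assert np.array_equal(raw == 0, norm == 0)
        for c in range(5):
            order_raw = np.argsort(raw[c], kind="stable")
            assert np.all(np.diff(norm[c][order_raw]) >= -1e-12)


class TestHVG:
    def test_planted_high_variance_genes_recovered(self):
        rng = np.random.default_rng(42)
        n_cells, n_genes, n_planted = 300, 2000, 50
        # heterogeneous negative-binomial baseline so every mean bin carries a
        # realistic spread of dispersions
        lam = rng.uniform(1.0, 8.0, n_genes)
        theta = rng.uniform(1.5, 50.0, n_genes)
        base = rng.negative_binomial(
            theta[None, :], theta / (theta + lam), size=(n_cells, n_genes)
        )
        planted = rng.permutation(n_genes)[:n_planted]
        # bursty expression: normalized means spanning the full baseline
        # range, far higher variance than the baseline at the same mean
        p_burst = 0.35
        mu_target = rng.uniform(0.7, 2.1, n_planted)
        burst_level = np.expm1(mu_target / p_burst)
        burst = rng.random((n_cells, n_planted)) < p_burst
        base[:, planted] = np.where(
            burst, rng.poisson(burst_level[None, :], (n_cells, n_planted)), 0
        )
        em = normalize_umi(
            ExpressionMatrix(
                [f"c{i}" for i in range(n_cells)],
                [f"G{i:04d}" for i in range(n_genes)],
                sp.csr_matrix(base),
            )
        )
        top = select_hvg(em, n_planted)
        hits = len(set(top) & {f"G{i:04d}" for i in planted})
        assert hits >= 45

    def test_fewer_expressed_than_requested_warns(self, tiny_em):
        em = normalize_umi(tiny_em)
        with pytest.warns(UserWarning, match="expressed genes"):
            out = select_hvg(em, n_top=10)
        assert set(out) <= set(tiny_em.genes)

    def test_constant_ties_break_lexicographically(self):
        counts = np.ones((30, 5), dtype=int)
        em = normalize_umi(
            ExpressionMatrix(
                [f"c{i}" for i in range(30)], ["B", "A", "E", "C", "D"], sp.csr_matrix(counts)
            )
        )
        assert select_hvg(em, 3) == ["A", "B", "C"]


class TestGMT:
    def test_round_trip_and_dedup(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("S1\tdesc\tG1\tG2\tG2\nS2\tdesc\tG3\n")
        coll = read_gmt(path)
        assert coll.names() == ["S1", "S2"]
        assert coll.sets["S1"] == ["G1", "G2"]  # duplicate counted once

    def test_empty_line_skipped_with_warning(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("S1\tdesc\tG1\nS2\tdesc\n")
        with pytest.warns(UserWarning, match="empty"):
            coll = read_gmt(path)
        assert coll.names() == ["S1"]

    def test_synthetic_hallmark_like_collection(self, tmp_path):
        coll = simulate_gene_sets([f"G{i}" for i in range(500)], n_sets=50, seed=5)
        write_gmt(coll, tmp_path / "h.gmt")
        back = read_gmt(tmp_path / "h.gmt")
        assert len(back) == 50
        assert back.sets == coll.sets


class TestTreeIO:
    def test_round_trip_and_root_detection(self, tmp_path):
        edges = [("HSC", "MPP"), ("MPP", "GMP")]
        write_tree(edges, tmp_path / "tree.tsv")
        back_edges, root = read_tree(tmp_path / "tree.tsv")
        assert back_edges == edges and root == "HSC"


class TestLabels:
    def test_unknown_barcode_rejected(self, tiny_em):
        labels = make_labels(["c1", "cX"], ["P1", "P1"])
        with pytest.raises(FormatError, match="absent"):
            labels.validate_against(tiny_em)
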
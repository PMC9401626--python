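"""Single-cell QC, normalization, signature scoring and condition comparison."""

import math

import numpy as np
import pytest

from tcellopt.scqc import (
    NOTCH_SIGNATURE,
    CountMatrix,
    QCThresholds,
    apply_qc,
    compare_conditions,
    normalize_log,
    score_signature,
)
from tcellopt.synth import ExpressionTruth, gen_expression


def small_matrix(counts, conditions=None, prefix="c"):
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    return CountMatrix(
        counts=counts,
        gene_names=[f"G{j}" for j in range(n_genes)],
        cell_ids=[f"{prefix}{i}" for i in range(n_cells)],
        cell_condition=conditions or ["A"] * n_cells,
    )


def make_scored(scores_a, scores_b):
    """Wrap two score vectors in a result object for comparison tests."""
    from tcellopt.scqc import SignatureScoreResult

    scores = np.array(list(scores_a) + list(scores_b), dtype=float)
    cond = ["A"] * len(scores_a) + ["B"] * len(scores_b)
    return SignatureScoreResult(
        per_cell_score=scores,
        cell_ids=[f"c{i}" for i in range(len(scores))],
        cell_condition=cond,
        signature_genes=["S"],
        control_genes=[],
        n_ctrl_per_gene=0,
        n_bins=1,
        seed=0,
    )


class TestQC:
    def fixture_matrix(self):
        """Four cells: high-count, high-gene, high-mito, and one clean cell."""
        n_genes = 7000
        X = np.zeros((4, n_genes), dtype=int)
        X[0, :100] = 400  # 40,000 total counts
        X[1, :6500] = 1  # 6,500 detected genes
        X[2, 0] = 80  # mito: 20 / 100 = 20% of reads
        X[2, 1:21] = 1
        X[3, :50] = 20  # clean: 1000 counts, 50 genes, no mito
        genes = ["MT-ND1"] + [f"G{j}" for j in range(n_genes - 1)]
        # route mito counts through the MT- gene for the high-mito cell
        X[2, 0] = 80
        mat = CountMatrix(
            counts=X,
            gene_names=genes,
            cell_ids=["high_count", "high_gene", "high_mito", "clean"],
            cell_condition=["A"] * 4,
        )
        return mat

    def test_crafted_fixture_removals(self):
        mat = self.fixture_matrix()
        # mito cell: gene0 (MT-ND1) has 80 of 100 counts -> 80% mito
        mat.counts[2, 0] = 25
        mat.counts[2, 1:101] = 1  # 25/125 = 20% mito
        filtered, report = apply_qc(mat, QCThresholds(min_cells_per_gene=1))
        assert filtered.cell_ids == ["clean"]
        assert report.removed_high_counts == ["high_count"]
        assert report.removed_high_genes == ["high_gene"]
        assert report.removed_high_mito == ["high_mito"]
        assert report.n_cells_removed == 3

    def test_thresholds_are_strict_inequalities(self):
        X = np.zeros((3, 7000), dtype=int)
        X[0, :9] = 4000  # exactly 36,000 counts: kept
        X[1, :6000] = 1  # exactly 6,000 genes: kept
        X[2, 0] = 18  # exactly 18% mito: kept
        X[2, 1:83] = 1
        mat = CountMatrix(
            counts=X,
            gene_names=["MT-ND1"] + [f"G{j}" for j in range(6999)],
            cell_ids=["a", "b", "c"],
            cell_condition=["A"] * 3,
        )
        filtered, report = apply_qc(mat, QCThresholds(min_cells_per_gene=1))
        assert filtered.n_cells == 3
        assert report.n_cells_removed == 0

    def test_clean_matrix_unchanged(self):
        mat = small_matrix(np.ones((5, 10), dtype=int) * 3)
        filtered, report = apply_qc(mat)
        np.testing.assert_array_equal(filtered.counts, mat.counts)
        assert report.n_cells_removed == 0 and report.removed_genes == []

    def test_sparse_gene_boundary(self):
        X = np.ones((5, 3), dtype=int)
        X[2:, 1] = 0  # gene 1 detected in exactly 2 cells
        mat = small_matrix(X)
        filtered, report = apply_qc(mat, QCThresholds(min_cells_per_gene=3))
        assert report.removed_genes == ["G1"]
        assert filtered.gene_names == ["G0", "G2"]

    def test_idempotent(self):
        rngm = np.random.default_rng(0)
        X = rngm.poisson(3.0, size=(30, 40))
        mat = small_matrix(X)
        once, _ = apply_qc(mat)
        twice, rep2 = apply_qc(once)
        np.testing.assert_array_equal(once.counts, twice.counts)
        assert rep2.n_cells_removed == 0 and rep2.removed_genes == []

    def test_all_cells_filtered_raises(self):
        mat = small_matrix(np.full((2, 10), 40_000, dtype=int))
        with pytest.raises(ValueError, match="all cells filtered"):
            apply_qc(mat)


class TestNormalize:
    def test_hand_calculation(self):
        # cell total 5,000 with a gene at 5 -> scaled 10, ln(11)
        X = np.zeros((1, 2), dtype=int)
        X[0] = [5, 4995]
        norm = normalize_log(small_matrix(X))
        assert norm.counts[0, 0] == pytest.approx(math.log(11))

    def test_target_total_is_identity_scaling(self):
        X = np.array([[2_000, 8_000]])
        norm = normalize_log(small_matrix(X))
        np.testing.assert_allclose(norm.counts[0], np.log1p([2000, 8000]))

    def test_zeros_preserved_and_cells_kept(self):
        X = np.array([[0, 10, 0, 5], [3, 0, 0, 9]])
        norm = normalize_log(small_matrix(X))
        assert norm.n_cells == 2
        assert np.all((norm.counts == 0) == (X == 0))

    def test_zero_cell_named_in_error(self):
        X = np.array([[1, 2], [0, 0]])
        with pytest.raises(ValueError, match="c1"):
            normalize_log(small_matrix(X))


class TestSignatureScore:
    def null_matrix(self, rng, n_cells=400, n_genes=600):
        """Signature genes drawn from the same distribution as background."""
        X = rng.poisson(5.0, size=(n_cells, n_genes))
        genes = NOTCH_SIGNATURE + [f"G{j}" for j in range(n_genes - 6)]
        return CountMatrix(
            counts=X,
            gene_names=genes,
            cell_ids=[f"c{i}" for i in range(n_cells)],
            cell_condition=["A"] * n_cells,
        )

    def test_null_score_near_zero(self, rng):
        norm = normalize_log(self.null_matrix(rng))
        res = score_signature(norm, seed=1)
        se = res.per_cell_score.std(ddof=1) / math.sqrt(len(res.per_cell_score))
        assert abs(res.per_cell_score.mean()) < 3 * se + 1e-3

    def test_exact_shift_detected(self, rng):
        norm = normalize_log(self.null_matrix(rng))
        res0 = score_signature(norm, seed=1)
        delta = 0.75
        shifted = norm.counts.copy()
        sig_idx = [norm.gene_names.index(g) for g in NOTCH_SIGNATURE]
        shifted[:, sig_idx] += delta
        # keep ranking-based bins fixed by reusing the same seed and bins:
        # a uniform shift moves the score by exactly delta when bin
        # assignments and control draws coincide; enforce by scoring the
        # shifted matrix with identical bin structure (same gene ranking)
        from dataclasses import replace

        norm2 = replace(norm, counts=shifted)
        res1 = score_signature(norm2, seed=1, n_bins=1)
        res0b = score_signature(norm, seed=1, n_bins=1)
        np.testing.assert_allclose(
            res1.per_cell_score - res0b.per_cell_score, delta, atol=1e-10
        )

    def test_seed_determinism_and_gene_permutation_invariance(self, rng):
        norm = normalize_log(self.null_matrix(rng))
        r1 = score_signature(norm, seed=3)
        r2 = score_signature(norm, seed=3)
        np.testing.assert_array_equal(r1.per_cell_score, r2.per_cell_score)
        assert r1.control_genes == r2.control_genes

    def test_small_bin_samples_with_replacement_and_flags(self, rng):
        X = rng.poisson(5.0, size=(50, 30))
        genes = NOTCH_SIGNATURE + [f"G{j}" for j in range(24)]
        mat = CountMatrix(
            counts=X, gene_names=genes,
            cell_ids=[f"c{i}" for i in range(50)],
            cell_condition=["A"] * 50,
        )
        res = score_signature(normalize_log(mat), n_bins=2, n_ctrl=50, seed=0)
        assert res.sampled_with_replacement

    def test_absent_signature_genes_dropped_with_warning(self, rng):
        norm = normalize_log(self.null_matrix(rng))
        with pytest.warns(UserWarning, match="NOSUCH"):
            res = score_signature(norm, ["HES1", "NOSUCH"], seed=0)
        assert res.signature_genes == ["HES1"]
        assert res.dropped_signature_genes == ["NOSUCH"]

    def test_condition_effect_detected_under_generative_model(self):
        rng0 = np.random.default_rng(7)
        base = rng0.gamma(2.0, 2.5, size=800)
        truth = ExpressionTruth(
            n_cells_per_condition={"A": 500, "B": 500},
            n_genes=800,
            baseline_means=base,
            signature_genes=NOTCH_SIGNATURE,
            signature_effect={"A": 1.0, "B": 2.0},
        )
        mat = gen_expression(truth, seed=8)
        filtered, _ = apply_qc(mat)
        res = score_signature(normalize_log(filtered), seed=9)
        assert res.per_condition_mean["B"] > res.per_condition_mean["A"]
        _, p = compare_conditions(res, ("A", "B"))
        assert p < 0.01


class TestCompareConditions:
    def test_identical_groups_fold_one(self):
        res = make_scored([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        fold, p = compare_conditions(res, ("A", "B"))
        assert fold == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_exact_separated_groups(self):
        # U = 0; exact two-sided p = 2 / C(6,3) = 0.1
        res = make_scored([0.1, 0.2, 0.3], [0.4, 0.5, 0.6])
        fold, p = compare_conditions(res, ("A", "B"))
        assert p == pytest.approx(0.1)
        assert fold == pytest.approx(2.5)

    def test_nonpositive_mean_flags_fold_undefined(self):
        res = make_scored([-0.2, -0.1], [0.3, 0.4])
        fold, p = compare_conditions(res, ("A", "B"))
        assert fold is None
        assert not res.fold_change_defined
        assert 0 < p <= 1

    def test_missing_group_raises(self):
        res = make_scored([0.1, 0.2], [0.3, 0.4])
        with pytest.raises(KeyError):
            compare_conditions(res, ("A", "C"))

    def test_tiny_group_rejected(self):
        res = make_scored([0.1], [0.3, 0.4])
        with pytest.raises(ValueError):
            compare_conditions(res, ("A", "B"))


def test_scanpy_score_cross_check():
    """Independent check: per-cell scores track scanpy's bin-matched scorer."""
    sc = pytest.importorskip("scanpy")
    import anndata as ad

    rng0 = np.random.default_rng(42)
    n_cells, n_genes = 300, 500
    X = rng0.poisson(4.0, size=(n_cells, n_genes)).astype(float)
    genes = NOTCH_SIGNATURE + [f"G{j}" for j in range(n_genes - 6)]
    sig_idx = list(range(6))
    X[:, sig_idx] += rng0.poisson(3.0, size=(n_cells, 6))  # elevate the signature
    mat = CountMatrix(
        counts=X.astype(int),
        gene_names=genes,
        cell_ids=[f"c{i}" for i in range(n_cells)],
        cell_condition=["A"] * n_cells,
    )
    norm = normalize_log(mat)
    ours = score_signature(norm, seed=0, n_bins=25)

    adata = ad.AnnData(X=norm.counts.copy())
    adata.var_names = genes
    adata.obs_names = mat.cell_ids
    sc.tl.score_genes(
        adata, NOTCH_SIGNATURE, ctrl_size=50, n_bins=25, score_name="sc", random_state=0
    )
    r = np.corrcoef(ours.per_cell_score, adata.obs["sc"].to_numpy())[0, 1]
    assert r > 0.9
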
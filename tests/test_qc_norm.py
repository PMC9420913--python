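import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tfscout.qc_norm import (
    CountMatrix,
    QcError,
    QcParams,
    decompose_variance,
    detect_empty_droplets,
    exclude_cells_by_markers,
    flag_ambient_genes,
    log_normalize,
    scaled_cell_sums,
)

from .conftest import make_count_matrix


class TestDetectEmptyDroplets:
    def test_49_is_empty_50_is_not(self):
        matrix = make_count_matrix([[49, 50]])
        empties = detect_empty_droplets(matrix)
        assert empties == {"BC0"}

    def test_brute_force_totals(self):
        # totals 10, 49, 50, 100, 0 -> barcodes 0, 1, 4 flagged
        matrix = make_count_matrix([[10, 40, 30, 60, 0], [0, 9, 20, 40, 0]])
        empties = detect_empty_droplets(matrix)
        assert empties == {"BC0", "BC1", "BC4"}

    def test_custom_threshold(self):
        matrix = make_count_matrix([[10, 40]])
        empties = detect_empty_droplets(matrix, QcParams(empty_umi_threshold=11))
        assert empties == {"BC0"}


class TestFlagAmbientGenes:
    def test_forty_percent_flagged(self):
        # gene0: 40 of 100 counts in the empty droplet
        matrix = make_count_matrix([[40, 60], [0, 100]])
        flagged = flag_ambient_genes(matrix, {"BC0"})
        assert flagged == {"G0"}

    def test_zero_in_empties_not_flagged(self):
        matrix = make_count_matrix([[0, 100]])
        assert flag_ambient_genes(matrix, {"BC0"}) == set()

    def test_exactly_thirty_percent_not_flagged(self):
        matrix = make_count_matrix([[30, 70]])
        assert flag_ambient_genes(matrix, {"BC0"}) == set()

    def test_zero_total_gene_never_flagged(self):
        matrix = make_count_matrix([[0, 0], [10, 1]])
        assert flag_ambient_genes(matrix, {"BC0"}) == {"G1"}

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(0, 20, size=(8, 10))
        matrix = make_count_matrix(counts)
        empties = {"BC1", "BC4"}
        baseline = flag_ambient_genes(matrix, empties)
        perm_g = rng.permutation(8)
        perm_b = rng.permutation(10)
        shuffled = make_count_matrix(
            counts[np.ix_(perm_g, perm_b)],
            genes=[f"G{i}" for i in perm_g],
            barcodes=[f"BC{i}" for i in perm_b],
        )
        assert flag_ambient_genes(shuffled, empties) == baseline

    def test_unknown_empty_barcode_rejected(self):
        matrix = make_count_matrix([[1, 2]])
        with pytest.raises(ValueError, match="unknown"):
            flag_ambient_genes(matrix, {"NOPE"})


class TestExcludeCellsByMarkers:
    def test_hemoglobin_like_cell_excluded(self):
        matrix = make_count_matrix([[3, 0], [5, 5]], genes=["HBB", "OTHER"])
        kept = exclude_cells_by_markers(matrix, {"rbc": ["HBB"]}, min_detected=1)
        assert list(kept.barcode_ids) == ["BC1"]

    def test_zero_marker_cell_retained(self):
        matrix = make_count_matrix([[0, 1], [9, 9]], genes=["HBB", "OTHER"])
        kept = exclude_cells_by_markers(matrix, {"rbc": ["HBB"]})
        assert "BC0" in kept.barcode_ids

    def test_six_cell_toy_exact_gating(self):
        # cells 1 and 4 detect both RBC genes; min_detected=2 removes exactly them
        counts = np.zeros((4, 6), dtype=int)
        counts[0, [1, 4]] = 2  # HBB
        counts[1, [1, 4]] = 1  # HBE1
        counts[1, 2] = 1       # one RBC gene only in cell 2
        counts[2:, :] = 3
        matrix = make_count_matrix(counts, genes=["HBB", "HBE1", "A", "B"])
        kept = exclude_cells_by_markers(matrix, {"rbc": ["HBB", "HBE1"]},
                                        min_detected=2)
        assert list(kept.barcode_ids) == ["BC0", "BC2", "BC3", "BC5"]

    def test_absent_symbol_warns_and_is_ignored(self):
        matrix = make_count_matrix([[1, 1]], genes=["A"])
        with pytest.warns(UserWarning, match="absent"):
            kept = exclude_cells_by_markers(matrix, {"x": ["NOTAGENE"]})
        assert kept.n_barcodes == 2

    def test_all_cells_removed_errors(self):
        matrix = make_count_matrix([[1, 1]], genes=["HBB"])
        with pytest.raises(QcError):
            exclude_cells_by_markers(matrix, {"rbc": ["HBB"]})

    def test_original_untouched(self):
        matrix = make_count_matrix([[3, 0], [1, 1]], genes=["HBB", "A"])
        exclude_cells_by_markers(matrix, {"rbc": ["HBB"]})
        assert matrix.n_barcodes == 2


class TestExcludeClustersByMarkers:
    def test_marker_heavy_cluster_removed_whole(self):
        from tfscout.qc_norm import exclude_clusters_by_markers

        # cluster 0: 3 of 4 cells HBB+; cluster 1: 0 of 2 HBB+
        counts = np.array([[2, 1, 3, 0, 0, 0], [1, 1, 1, 1, 1, 1]])
        matrix = make_count_matrix(counts, genes=["HBB", "A"])
        labels = np.array([0, 0, 0, 0, 1, 1])
        kept = exclude_clusters_by_markers(
            matrix, labels, {"rbc": ["HBB"]}, min_positive_fraction=0.5
        )
        assert list(kept.barcode_ids) == ["BC4", "BC5"]

    def test_below_fraction_cluster_kept(self):
        from tfscout.qc_norm import exclude_clusters_by_markers

        counts = np.array([[2, 0, 0, 0], [1, 1, 1, 1]])
        matrix = make_count_matrix(counts, genes=["HBB", "A"])
        kept = exclude_clusters_by_markers(
            matrix, np.zeros(4, dtype=int), {"rbc": ["HBB"]},
            min_positive_fraction=0.5,
        )
        assert kept.n_barcodes == 4


class TestLogNormalize:
    def test_single_gene_cell(self):
        matrix = make_count_matrix([[7, 1], [0, 1]])
        norm = log_normalize(matrix)
        assert norm.dense()[0, 0] == pytest.approx(math.log(1 + 10_000))
        assert norm.dense()[1, 0] == 0.0

    def test_two_by_two_hand_computed(self):
        matrix = make_count_matrix([[1, 0], [1, 10]])
        norm = log_normalize(matrix).dense()
        sf = 10_000
        expected = [
            [math.log(1 + sf * 1 / 2), 0.0],
            [math.log(1 + sf * 1 / 2), math.log(1 + sf * 10 / 10)],
        ]
        np.testing.assert_allclose(norm, expected, rtol=1e-12)

    def test_zero_count_stays_exactly_zero(self):
        matrix = make_count_matrix([[5, 0], [0, 3]])
        norm = log_normalize(matrix)
        assert norm.values[0, 1] == 0.0
        assert norm.values[1, 0] == 0.0

    def test_zero_total_cell_names_barcode(self):
        matrix = make_count_matrix([[1, 0]])
        with pytest.raises(QcError, match="BC1"):
            log_normalize(matrix)

    @given(st.integers(min_value=1, max_value=50), st.integers(min_value=0, max_value=3))
    @settings(max_examples=25, deadline=None)
    def test_scaled_sums_conserve_scale_factor(self, a, b):
        matrix = make_count_matrix([[a, b + 1], [b, a]])
        sums = scaled_cell_sums(matrix)
        np.testing.assert_allclose(sums, 10_000.0, rtol=1e-12)


class TestDecomposeVariance:
    def test_constant_gene_never_selected(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 30, size=(40, 20))
        counts[5, :] = 7  # constant gene
        norm = log_normalize(make_count_matrix(counts))
        table = decompose_variance(norm, params=QcParams(n_hvgs=10))
        assert not table.loc["G5", "selected"]
        assert table.loc["G5", "biological"] <= 0

    def test_identity_biological_plus_technical(self, small_norm):
        norm, _ = small_norm
        table = decompose_variance(norm, params=QcParams(n_hvgs=50))
        np.testing.assert_allclose(
            table["biological"] + table["technical"], table["total"], rtol=1e-12
        )

    def test_inflated_variance_genes_rank_top(self):
        # 200 genes spread over a mean range; 20 of them (scattered across
        # that range) get 5x inflated variance at their own fixed mean
        import scipy.sparse as sp

        from tfscout.qc_norm import NormalizedMatrix

        rng = np.random.default_rng(1)
        n_genes, n_cells = 200, 300
        means = rng.uniform(1.0, 5.0, size=n_genes)
        values = rng.normal(means[:, None], 0.2, size=(n_genes, n_cells))
        inflated_idx = rng.choice(n_genes, size=20, replace=False)
        values[inflated_idx] = rng.normal(
            means[inflated_idx][:, None], 0.2 * np.sqrt(5), size=(20, n_cells)
        )
        norm = NormalizedMatrix(
            values=sp.csr_matrix(np.clip(values, 0, None)),
            gene_symbols=np.array([f"G{i}" for i in range(n_genes)], dtype=object),
            barcode_ids=np.array([f"BC{i}" for i in range(n_cells)], dtype=object),
            batch_of_barcode=np.array(["b0"] * n_cells, dtype=object),
        )
        table = decompose_variance(norm, params=QcParams(n_hvgs=20))
        selected = set(table.index[table["selected"]])
        inflated = {f"G{i}" for i in inflated_idx}
        assert len(selected & inflated) >= 18

    def test_ambient_gene_excluded_despite_rank(self):
        import scipy.sparse as sp

        from tfscout.qc_norm import NormalizedMatrix

        rng = np.random.default_rng(2)
        n_genes, n_cells = 60, 150
        means = rng.uniform(1.0, 4.0, size=n_genes)
        values = rng.normal(means[:, None], 0.15, size=(n_genes, n_cells))
        values[30] = rng.normal(means[30], 0.6, size=n_cells)  # top-variance gene
        norm = NormalizedMatrix(
            values=sp.csr_matrix(np.clip(values, 0, None)),
            gene_symbols=np.array([f"G{i}" for i in range(n_genes)], dtype=object),
            barcode_ids=np.array([f"BC{i}" for i in range(n_cells)], dtype=object),
            batch_of_barcode=np.array(["b0"] * n_cells, dtype=object),
        )
        with_g30 = decompose_variance(norm, params=QcParams(n_hvgs=5))
        assert with_g30.loc["G30", "selected"]
        without = decompose_variance(norm, ambient={"G30"}, params=QcParams(n_hvgs=5))
        assert not without.loc["G30", "selected"]
        assert without["selected"].sum() == 5

    def test_too_few_genes_selects_all_and_warns(self):
        rng = np.random.default_rng(3)
        norm = log_normalize(make_count_matrix(rng.poisson(5, size=(6, 10)) + 1))
        with pytest.warns(UserWarning, match="selecting all"):
            table = decompose_variance(norm, params=QcParams(n_hvgs=100))
        assert table["selected"].sum() <= 6

    def test_trend_tracks_lowess_oracle(self):
        # independent local-regression check of the fitted technical component
        from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

        rng = np.random.default_rng(4)
        counts = rng.poisson(rng.uniform(1, 40, size=(80, 1)), size=(80, 100))
        norm = log_normalize(make_count_matrix(counts))
        table = decompose_variance(norm, params=QcParams(n_hvgs=10))
        oracle = sm_lowess(
            table["total"].to_numpy(), table["mean"].to_numpy(),
            frac=0.3, it=3, return_sorted=False,
        )
        np.testing.assert_allclose(table["technical"], oracle, rtol=1e-8)


class TestCountMatrixValidation:
    def test_duplicate_symbols_after_uppercasing_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            make_count_matrix([[1, 1], [2, 2]], genes=["abc", "ABC"])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            make_count_matrix([[-1, 2]])

    def test_symbols_uppercased(self):
        matrix = make_count_matrix([[1, 1]], genes=["sox2"])
        assert matrix.gene_symbols[0] == "SOX2"
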
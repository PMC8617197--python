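import numpy as np
import pytest
import scipy.sparse as sp

from bcellflow.preprocess import (
    community_cluster,
    filter_cells_genes,
    knn_graph,
    merge_by_de,
    normalize,
    run_pca,
)
from bcellflow.simulate import CountsBundle

from oracles import knn_sets_direct


def _bundle(rna, mito_mask=None):
    rna = np.asarray(rna)
    g, c = rna.shape
    return CountsBundle(
        rna=sp.csr_matrix(rna),
        hto=np.zeros((2, c), dtype=int),
        adt=np.zeros((1, c), dtype=int),
        gene_names=[f"g{i}" for i in range(g)],
        cell_barcodes=[f"c{i}" for i in range(c)],
        hashtag_names=["HTO-1", "HTO-2"],
        adt_names=["A1"],
        mito_mask=np.zeros(g, dtype=bool) if mito_mask is None else np.asarray(mito_mask),
    )


class TestFilter:
    def test_cell_below_min_genes_dropped(self):
        rna = np.array([[1, 1, 0], [0, 2, 0], [0, 3, 1], [1, 1, 0]])
        out, rep = filter_cells_genes(_bundle(rna), min_genes=1, min_cells=0, mito_top_frac=0)
        assert rep.n_cells_out == 2  # the cell expressing only 1 gene is dropped
        assert rep.removed_low_genes == ["c2"]

    def test_mito_top_frac_zero_removes_no_cells(self):
        rna = np.ones((5, 4), dtype=int)
        mask = np.array([True, False, False, False, False])
        _, rep = filter_cells_genes(_bundle(rna, mask), min_genes=0, min_cells=0, mito_top_frac=0)
        assert rep.removed_for_mito == []

    def test_report_matches_independent_scan(self, rng):
        rna = rng.integers(0, 3, size=(60, 40))
        mask = np.zeros(60, dtype=bool)
        mask[:3] = True
        out, rep = filter_cells_genes(_bundle(rna, mask), min_genes=20, min_cells=5, mito_top_frac=0.1)
        # independent recomputation
        keep_cells = (rna > 0).sum(axis=0) > 20
        step1 = rna[:, keep_cells]
        keep_genes = (step1 > 0).sum(axis=1) > 5
        step2 = step1[keep_genes]
        frac = step2[mask[keep_genes]].sum(axis=0) / step2.sum(axis=0)
        cutoff = np.quantile(frac, 0.9)
        n_final = int((frac < cutoff).sum())
        assert rep.n_cells_out == n_final
        assert rep.n_genes_out == int(keep_genes.sum())

    def test_all_cells_removed_is_error(self):
        with pytest.raises(ValueError):
            filter_cells_genes(_bundle(np.ones((3, 2), dtype=int)), min_genes=10)


class TestNormalize:
    def test_log_cpm_median_closed_form(self):
        # count 3 in a cell whose total equals the median total → ln(4)
        counts = np.array([[3, 3, 3], [7, 7, 7]])  # all totals 10 = median
        out = normalize(counts, "log_cpm_median")
        assert np.allclose(out[0], np.log(4))

    def test_pearson_residual_zero_gene_row(self):
        counts = np.array([[0, 0, 0], [5, 6, 7]])
        out = normalize(counts, "pearson_residual")
        assert np.allclose(out[0], 0)

    def test_covariate_equal_to_gene_gives_zero_residual(self, rng):
        counts = rng.integers(1, 50, size=(10, 30))
        base = normalize(counts, "log_cpm_median")
        out = normalize(counts, "log_cpm_median", covariates=base[4])
        assert np.allclose(out[4], 0, atol=1e-10)

    def test_zero_total_cell_rejected(self):
        with pytest.raises(ValueError):
            normalize(np.array([[0, 1], [0, 2]]) * np.array([0, 1]), "log_cpm_median")


class TestPCA:
    def test_collinear_points_one_component(self):
        t = np.linspace(0, 1, 50)
        data = np.vstack([t, 2 * t])  # 2 genes x 50 cells, perfectly collinear
        scores = run_pca(data, n_components=2, scale=False)
        assert scores[:, 1].var() < 1e-10
        assert scores[:, 0].var() > 0

    def test_matches_dense_svd_oracle(self, rng):
        data = rng.normal(size=(20, 15))
        scores = run_pca(data, n_components=5)
        # oracle: standardise rows, SVD of the cells x genes matrix
        X = data - data.mean(axis=1, keepdims=True)
        X /= X.std(axis=1, keepdims=True)
        u, s_, vt = np.linalg.svd(X.T, full_matrices=False)
        oracle = u[:, :5] * s_[:5]
        for k in range(5):
            col = oracle[:, k]
            load = vt[k]
            if load[np.abs(load).argmax()] < 0:
                col = -col
            assert np.allclose(scores[:, k], col, atol=1e-8)

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(ValueError):
            run_pca(rng.normal(size=(5, 4)), n_components=10)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError):
            run_pca(np.ones((5, 6)), n_components=2)


class TestKnnGraph:
    def test_three_collinear_points_k1_path(self):
        pts = np.array([[0.0], [1.0], [2.0]])
        g = knn_graph(pts, k=1)
        assert g.connectivity.nnz == 4  # 2 undirected edges
        assert g.connectivity[0, 1] == 1 and g.connectivity[1, 2] == 1
        assert g.connectivity[0, 2] == 0

    def test_matches_brute_force_neighbour_sets(self, rng):
        pts = rng.normal(size=(40, 3))
        k = 5
        g = knn_graph(pts, k=k)
        expected = knn_sets_direct(pts, k)
        # the union-symmetrised graph must contain each point's kNN set
        for i in range(40):
            neigh = set(g.connectivity[i].indices)
            assert expected[i] <= neigh

    def test_k_equals_n_minus_1_complete(self, rng):
        pts = rng.normal(size=(8, 2))
        g = knn_graph(pts, k=7)
        assert g.connectivity.nnz == 8 * 7

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError):
            knn_graph(rng.normal(size=(5, 2)), k=5)


class TestCommunityCluster:
    def _two_cliques_graph(self):
        n = 10
        conn = np.zeros((2 * n, 2 * n))
        conn[:n, :n] = 1
        conn[n:, n:] = 1
        np.fill_diagonal(conn, 0)
        from bcellflow.preprocess import CellGraph

        c = sp.csr_matrix(conn)
        return CellGraph(connectivity=c, distances=c.copy())

    def test_two_cliques_two_clusters(self):
        g = self._two_cliques_graph()
        labels = community_cluster(g, resolution=0.5, seed=0).labels
        assert len(set(labels.tolist())) == 2
        assert len(set(labels[:10].tolist())) == 1 and len(set(labels[10:].tolist())) == 1

    def test_same_seed_identical(self):
        g = self._two_cliques_graph()
        a = community_cluster(g, resolution=0.5, seed=3).labels
        b = community_cluster(g, resolution=0.5, seed=3).labels
        assert np.array_equal(a, b)


class TestMergeByDE:
    def test_identically_distributed_clusters_merge(self, rng):
        norm = np.log1p(rng.poisson(1.0, size=(500, 200)))
        labels = np.repeat([0, 1], 100)
        merged = merge_by_de(norm, labels)
        assert merged.labels.max() == 0
        assert len(merged.merge_log) == 1

    def test_planted_4fold_shift_prevents_merge(self, rng):
        norm = np.log1p(rng.poisson(1.0, size=(500, 200)).astype(float))
        norm[:10, 100:] = np.log1p(rng.poisson(4.0, size=(10, 100)))
        labels = np.repeat([0, 1], 100)
        merged = merge_by_de(norm, labels)
        assert merged.labels.max() == 1
        assert merged.merge_log == []

    def test_min_de_zero_is_identity(self, rng):
        norm = rng.normal(size=(50, 60))
        labels = np.repeat([0, 1, 2], 20)
        merged = merge_by_de(norm, labels, min_de=0)
        assert np.array_equal(merged.labels, labels)

    def test_terminates_within_k_minus_1_merges(self, rng):
        norm = np.log1p(rng.poisson(1.0, size=(300, 120)))
        labels = np.repeat(np.arange(6), 20)
        merged = merge_by_de(norm, labels)
        assert len(merged.merge_log) <= 5

    def test_label_permutation_invariance(self, rng):
        norm = np.log1p(rng.poisson(1.0, size=(400, 150)).astype(float))
        norm[:15, :50] = np.log1p(rng.poisson(5.0, size=(15, 50)))
        labels = np.repeat([0, 1, 2], 50)
        perm = {0: 2, 1: 0, 2: 1}
        m1 = merge_by_de(norm, labels)
        m2 = merge_by_de(norm, np.vectorize(perm.get)(labels))
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(m1.labels, m2.labels) == 1.0
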
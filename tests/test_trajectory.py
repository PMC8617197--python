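import numpy as np
import pytest
import scipy.sparse as sp

from bcellflow.preprocess import CellGraph, knn_graph
from bcellflow.trajectory import (
    autocorrelated_genes,
    gene_modules,
    geodesic_pseudotime,
    morans_i,
    regress_cycle,
)

from oracles import bh_qvalues_direct, morans_i_direct


def _graph_from_dense(conn, dist=None):
    c = sp.csr_matrix(conn)
    d = sp.csr_matrix(dist) if dist is not None else c.copy()
    return CellGraph(connectivity=c, distances=d)


class TestRegressCycle:
    def test_linear_function_of_scores_residual_zero(self, rng):
        s = rng.normal(size=80)
        g = rng.normal(size=80)
        mat = np.vstack([2 * s + 1, g - 3, rng.normal(size=80)])
        out = regress_cycle(mat, s, g)
        assert np.allclose(out[0], 0, atol=1e-10)
        assert np.allclose(out[1], 0, atol=1e-10)

    def test_zero_scores_center_only(self, rng):
        mat = rng.normal(size=(4, 50))
        out = regress_cycle(mat, np.zeros(50), np.zeros(50))
        assert np.allclose(out, mat - mat.mean(axis=1, keepdims=True), atol=1e-10)

    def test_residuals_orthogonal_to_covariates(self, rng):
        s, g = rng.normal(size=60), rng.normal(size=60)
        out = regress_cycle(rng.normal(size=(10, 60)), s, g)
        assert np.all(np.abs(out @ s) < 1e-8)
        assert np.all(np.abs(out @ g) < 1e-8)

    def test_collinear_scores_drop_second(self, rng):
        s = rng.normal(size=40)
        with pytest.warns(UserWarning, match="collinear"):
            out = regress_cycle(rng.normal(size=(3, 40)), s, 2 * s)
        assert np.all(np.abs(out @ s) < 1e-8)


class TestGeodesicPseudotime:
    def test_path_graph_distances(self):
        conn = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        dist = np.array([[0, 1, 0], [1, 0, 2], [0, 2, 0]], dtype=float)
        g = _graph_from_dense(conn, dist)
        emb = np.array([[0.0], [1.0], [3.0]])
        pt = geodesic_pseudotime(g, [0, 1, 1], 0, ["a", "b", "c"], emb)
        assert pt.pseudotime.tolist() == [0.0, 1.0, 3.0]
        assert pt.root_cell == "a"

    def test_root_cell_zero_and_unreachable_flagged(self):
        conn = np.zeros((3, 3))
        conn[0, 1] = conn[1, 0] = 1
        g = _graph_from_dense(conn)
        pt = geodesic_pseudotime(g, [0, 0, 1], 0, ["a", "b", "c"], np.zeros((3, 1)))
        assert pt.pseudotime[0] == 0
        assert pt.unreachable == {"c"}

    def test_empty_root_cluster_rejected(self):
        g = _graph_from_dense(np.eye(2))
        with pytest.raises(ValueError):
            geodesic_pseudotime(g, [0, 0], 9, ["a", "b"], np.zeros((2, 1)))

    def test_monotone_along_trajectory(self, noncycling_sim):
        """Spearman >= 0.8 between pseudotime and the planted latent order."""
        import scipy.stats

        from bcellflow.preprocess import community_cluster, filter_cells_genes, normalize, run_pca

        bundle, gt = noncycling_sim
        fb, _ = filter_cells_genes(bundle)
        kept = set(fb.cell_barcodes)
        lat = gt.latent_time[[bc in kept for bc in bundle.cell_barcodes]]
        norm = normalize(fb.rna, "pearson_residual")
        pca = run_pca(norm, 30, scale=False)
        g = knn_graph(pca, 20)
        labels = community_cluster(g, 0.4, seed=0).labels
        root = min(set(labels.tolist()), key=lambda c: lat[labels == c].mean())
        pt = geodesic_pseudotime(g, labels, root, fb.cell_barcodes, pca)
        rho = scipy.stats.spearmanr(pt.pseudotime, lat).statistic
        assert rho >= 0.8


class TestMoransI:
    def test_complete_graph_identity(self, rng):
        n = 12
        conn = np.ones((n, n)) - np.eye(n)
        g = _graph_from_dense(conn)
        for _ in range(5):
            x = rng.normal(size=n)
            I, _, _ = morans_i(g, x)
            assert I == pytest.approx(-1 / (n - 1), abs=1e-12)

    def test_two_cliques_high_autocorrelation(self):
        n = 10
        conn = np.zeros((2 * n, 2 * n))
        conn[:n, :n] = 1
        conn[n:, n:] = 1
        np.fill_diagonal(conn, 0)
        x = np.repeat([0.0, 5.0], n)
        I, z, p = morans_i(_graph_from_dense(conn), x)
        assert I > 0.9 and p < 1e-6

    def test_matches_double_sum_oracle(self, rng):
        n = 15
        conn = (rng.uniform(size=(n, n)) < 0.3).astype(float)
        conn = np.maximum(conn, conn.T)
        np.fill_diagonal(conn, 0)
        x = rng.normal(size=n)
        I, _, _ = morans_i(_graph_from_dense(conn), x)
        assert I == pytest.approx(morans_i_direct(conn, x), abs=1e-12)

    def test_affine_invariance(self, rng):
        n = 20
        conn = (rng.uniform(size=(n, n)) < 0.4).astype(float)
        conn = np.maximum(conn, conn.T)
        np.fill_diagonal(conn, 0)
        x = rng.normal(size=n)
        g = _graph_from_dense(conn)
        assert morans_i(g, x)[0] == pytest.approx(morans_i(g, 3 * x - 7)[0], abs=1e-10)

    def test_constant_vector_rejected(self):
        g = _graph_from_dense(np.array([[0, 1], [1, 0]], dtype=float))
        with pytest.raises(ValueError):
            morans_i(g, np.array([2.0, 2.0]))


class TestAutocorrelatedGenes:
    def test_bh_hand_example(self):
        qs = bh_qvalues_direct([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(qs, [0.04, 0.04, 0.04, 0.04])

    def test_bh_qvalues_match_hand_computation(self, rng):
        """The per-gene q-values must equal a hand-rolled BH step-up."""
        n = 30
        pts = rng.normal(size=(n, 2))
        g = knn_graph(pts, 4)
        X = rng.normal(size=(25, n))
        X[:5] += pts[:, 0][None, :]  # smooth genes follow the embedding
        df = autocorrelated_genes(g, X, [f"g{i}" for i in range(25)])
        assert np.allclose(df["q"], bh_qvalues_direct(df["p"]), atol=1e-12)
        assert (df["q"] >= df["p"] - 1e-15).all()

    def test_planted_smooth_genes_recovered_noise_controlled(self, rng):
        """All smooth genes pass; the noise false-positive rate stays within
        binomial tolerance of the BH level."""
        n = 400
        t = np.sort(rng.uniform(size=n))
        emb = np.column_stack([t, rng.normal(scale=0.02, size=n)])
        g = knn_graph(emb, 10)
        n_smooth, n_noise = 20, 300
        X = rng.normal(size=(n_smooth + n_noise, n)) * 0.5
        for i in range(n_smooth):
            X[i] += np.sin(2 * np.pi * (t + i / n_smooth))
        names = [f"s{i}" for i in range(n_smooth)] + [f"n{i}" for i in range(n_noise)]
        df = autocorrelated_genes(g, X, names)
        sig = set(df.loc[df.significant, "gene"])
        assert all(f"s{i}" in sig for i in range(n_smooth))
        fp = sum(1 for g_ in sig if g_.startswith("n")) / n_noise
        assert fp <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_noise)

    def test_constant_gene_skipped(self, rng):
        pts = rng.normal(size=(20, 2))
        g = knn_graph(pts, 3)
        X = np.vstack([np.ones(20), rng.normal(size=20)])
        df = autocorrelated_genes(g, X, ["const", "ok"])
        assert not df.loc[df.gene == "const", "tested"].iloc[0]
        assert df.loc[df.gene == "const", "q"].isna().all()


class TestGeneModules:
    def test_two_anticorrelated_blocks_two_modules(self, rng):
        """Two planted anti-correlated gene programs come back as exactly
        two modules matching the blocks."""
        n_cells = 200
        labels = np.repeat(np.arange(4), 50)
        base = np.array([1.0, 2.0, 3.0, 4.0])
        X = np.zeros((20, n_cells))
        for i in range(10):
            X[i] = base[labels] + rng.normal(scale=0.1, size=n_cells)
        for i in range(10, 20):
            X[i] = base[::-1][labels] + rng.normal(scale=0.1, size=n_cells)
        names = [f"g{i}" for i in range(20)]
        gm = gene_modules(X, names, names, labels, knn_k=5, resolution=0.5, seed=0)
        assert len(gm.modules) == 2
        sets = sorted(tuple(sorted(v)) for v in gm.modules.values())
        assert sets[0] == tuple(sorted(names[:10])) or sets[0] == tuple(sorted(names[10:]))

    def test_module_matrix_rows_zero_mean(self, rng):
        labels = np.repeat(np.arange(5), 30)
        X = rng.normal(size=(12, 150)) + np.arange(12)[:, None] * 0.1
        names = [f"g{i}" for i in range(12)]
        gm = gene_modules(X, names, names, labels, knn_k=4, seed=0)
        means = gm.module_cluster_matrix.mean(axis=1)
        assert np.all(np.abs(means) < 1e-8)

    def test_same_seed_same_modules(self, rng):
        labels = np.repeat(np.arange(4), 25)
        X = rng.normal(size=(15, 100))
        names = [f"g{i}" for i in range(15)]
        a = gene_modules(X, names, names, labels, seed=2)
        b = gene_modules(X, names, names, labels, seed=2)
        assert a.modules == b.modules

    def test_too_few_genes_rejected(self, rng):
        with pytest.raises(ValueError):
            gene_modules(rng.normal(size=(3, 20)), ["a", "b", "c"], ["a"], [0] * 10 + [1] * 10)
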
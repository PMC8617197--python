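import numpy as np
import pandas as pd
import pytest

from bcellflow.enrichment import (
    aggregate_replicates,
    build_enrichment_grid,
    gene_zscores,
    hclust,
    log2_cpm,
    shc_test,
    signature_scores,
)
from bcellflow.simulate import BulkSimConfig, simulate_bulk_subtypes

from oracles import complete_linkage_direct, log2_cpm_direct


class TestAggregate:
    def test_replicate_sum(self):
        counts = pd.DataFrame([[1, 2], [3, 4]], index=["r1", "r2"], columns=["g1", "g2"])
        out = aggregate_replicates(counts, {"r1": "A", "r2": "A"})
        assert out.loc["A"].tolist() == [4, 6]

    def test_single_replicate_identity(self):
        counts = pd.DataFrame([[5, 7]], index=["r1"], columns=["g1", "g2"])
        out = aggregate_replicates(counts, {"r1": "A"})
        assert out.loc["A"].tolist() == [5, 7]

    def test_column_sums_conserved(self, rng):
        counts = pd.DataFrame(rng.integers(0, 50, size=(6, 10)),
                              index=[f"r{i}" for i in range(6)])
        mapping = {f"r{i}": f"S{i % 2}" for i in range(6)}
        out = aggregate_replicates(counts, mapping)
        assert np.array_equal(out.sum(axis=0).values, counts.sum(axis=0).values)

    def test_unmapped_sample_rejected(self):
        counts = pd.DataFrame([[1]], index=["r1"], columns=["g"])
        with pytest.raises(ValueError, match="r1"):
            aggregate_replicates(counts, {"other": "A"})


class TestLog2Cpm:
    def test_closed_form(self):
        counts = pd.DataFrame([[3, 10**6 - 3]], index=["A"], columns=["g1", "g2"])
        out = log2_cpm(counts)
        assert out.loc["A", "g1"] == pytest.approx(2.0)

    def test_zero_count_is_zero(self):
        counts = pd.DataFrame([[0, 10]], index=["A"], columns=["g1", "g2"])
        assert log2_cpm(counts).loc["A", "g1"] == 0.0

    def test_matches_direct_evaluation(self, rng):
        counts = pd.DataFrame(rng.integers(1, 1000, size=(4, 8)))
        assert np.allclose(log2_cpm(counts).values, log2_cpm_direct(counts.values), atol=1e-12)

    def test_zero_total_subtype_rejected(self):
        with pytest.raises(ValueError):
            log2_cpm(pd.DataFrame([[0, 0]], index=["A"]))


class TestGeneZscores:
    def test_closed_form_row(self):
        df = pd.DataFrame({"g": [1.0, 2.0, 3.0]}, index=["A", "B", "C"])
        assert gene_zscores(df)["g"].tolist() == [-1.0, 0.0, 1.0]

    def test_constant_gene_zeroed_with_warning(self):
        df = pd.DataFrame({"g": [2.0, 2.0], "h": [1.0, 3.0]}, index=["A", "B"])
        with pytest.warns(UserWarning):
            z = gene_zscores(df)
        assert (z["g"] == 0).all()

    def test_rows_mean_zero_sd_one(self, rng):
        df = pd.DataFrame(rng.normal(size=(5, 12)))
        z = gene_zscores(df)
        assert np.all(np.abs(z.mean(axis=0)) < 1e-12)
        assert np.allclose(z.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_single_subtype_rejected(self):
        with pytest.raises(ValueError):
            gene_zscores(pd.DataFrame([[1.0, 2.0]], index=["A"]))


class TestSignatureScores:
    def test_cancelling_rows_zero(self):
        z = pd.DataFrame([[-1, 0, 1], [1, 0, -1]], index=["A", "B"], columns=["s1", "s2", "s3"]).T
        grid = signature_scores(z, {"sig": ["A", "B"]}, min_genes=2)
        assert np.allclose(grid.scores.loc["sig"], 0)

    def test_all_gene_signature_sums_to_zero(self, rng):
        z = gene_zscores(pd.DataFrame(rng.normal(size=(4, 9))))
        grid = signature_scores(z, {"all": list(z.columns)})
        assert grid.scores.loc["all"].sum() == pytest.approx(0, abs=1e-10)

    def test_linearity_in_disjoint_unions(self, rng):
        z = gene_zscores(pd.DataFrame(rng.normal(size=(4, 10))))
        a, b = list(z.columns[:4]), list(z.columns[4:10])
        grid = signature_scores(z, {"a": a, "b": b, "ab": a + b})
        weighted = (4 * grid.scores.loc["a"] + 6 * grid.scores.loc["b"]) / 10
        assert np.allclose(grid.scores.loc["ab"], weighted, atol=1e-12)

    def test_sparse_signatures_dropped_and_error_when_none_left(self, rng):
        z = gene_zscores(pd.DataFrame(rng.normal(size=(3, 5))))
        with pytest.warns(UserWarning, match="dropped"):
            grid = signature_scores(z, {"small": [z.columns[0]], "ok": list(z.columns[:4])})
        assert list(grid.scores.index) == ["ok"]
        with pytest.raises(ValueError):
            with pytest.warns(UserWarning):
                signature_scores(z, {"small": [z.columns[0]]})


class TestHclust:
    def test_1d_points_complete_linkage_heights(self):
        d = hclust(np.array([[0.0], [1.0], [10.0]]))
        heights = d.linkage[:, 2].tolist()
        assert heights[0] == pytest.approx(1.0)
        assert heights[1] == pytest.approx(10.0)

    def test_duplicate_rows_merge_at_zero(self):
        d = hclust(np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]]))
        assert d.linkage[0, 2] == pytest.approx(0.0)

    def test_matches_bruteforce_agglomeration(self, rng):
        data = rng.normal(size=(6, 4))
        d = hclust(data)
        oracle = complete_linkage_direct(data)
        assert np.allclose(sorted(d.linkage[:, 2]), sorted(m[2] for m in oracle), atol=1e-10)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            hclust(np.array([[np.nan, 1.0], [0.0, 2.0]]))


class TestSHC:
    def test_small_nodes_not_tested(self, rng):
        data = rng.normal(size=(8, 3))
        rep = shc_test(data, min_n=3, n_sim=25, seed=0)
        small = rep.table[rep.table.n_leaves < 6]
        assert (small.decision == "too small").all()

    def test_well_separated_clusters_minimum_p(self, rng):
        data = rng.normal(size=(20, 5))
        data[10:, 0] += 20
        rep = shc_test(data, min_n=3, n_sim=100, seed=1)
        root = rep.table.iloc[0]
        assert root.decision == "rejected"
        assert root.p == pytest.approx(1 / 101)

    def test_n_sim_too_small_rejected(self, rng):
        with pytest.raises(ValueError):
            shc_test(rng.normal(size=(10, 3)), n_sim=5)

    def test_p_bounded_below_by_resolution(self, rng):
        data = rng.normal(size=(12, 4))
        rep = shc_test(data, n_sim=25, seed=3)
        tested = rep.table.dropna(subset=["p"])
        assert (tested.p >= 1 / 26 - 1e-12).all()


class TestBuildGrid:
    def _planted(self, seed=0, lfc=2.0):
        sigs = {f"sig{k}": [f"HG{k}_{i}" for i in range(20)] for k in range(4)}
        cfg = BulkSimConfig(n_subtypes=4, replicates_per_subtype=3, planted_lfc=lfc, seed=seed)
        counts, smap, truth = simulate_bulk_subtypes(cfg, sigs)
        return sigs, counts, smap, truth

    def test_planted_argmax_and_root_rejection(self):
        sigs, counts, smap, truth = self._planted()
        grid, row_rep, col_rep = build_enrichment_grid(counts, smap, sigs, min_n=2, seed=0)
        inv = {v: k for k, v in truth.planted_bulk_enrichment.items()}
        for sig_name in grid.scores.index:
            assert grid.scores.loc[sig_name].idxmax() == inv[sig_name]
        assert row_rep.table.iloc[0].decision == "rejected"

    def test_column_permutation_equivariance(self):
        sigs, counts, smap, truth = self._planted()
        grid1, r1, _ = build_enrichment_grid(counts, smap, sigs, min_n=2, seed=5)
        perm = counts.iloc[::-1]
        grid2, r2, _ = build_enrichment_grid(perm, smap, sigs, min_n=2, seed=5)
        assert np.allclose(grid1.scores.values, grid2.scores[grid1.scores.columns].values)
        assert np.allclose(r1.table.p.dropna(), r2.table.p.dropna())

    def test_empty_signature_set_rejected(self):
        _, counts, smap, _ = self._planted()
        with pytest.raises(ValueError):
            build_enrichment_grid(counts, smap, {}, seed=0)
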
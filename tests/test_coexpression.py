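import numpy as np
import pandas as pd
import pytest
import scipy.stats
from sklearn.metrics import adjusted_rand_score

from immunotme import coexpression as cx
from immunotme import synthetic
from immunotme.io import ExpressionMatrix


class TestSizeFactors:
    def test_scalar_multiple_columns_recovered(self, rng):
        base = rng.integers(5, 100, size=40).astype(float)
        scalars = np.array([0.5, 1.0, 2.0, 4.0])
        counts = base[:, None] * scalars
        sf = cx.size_factors(counts)
        np.testing.assert_allclose(sf / sf[1], scalars / scalars[1], rtol=1e-12)


class TestDifferentialExpression:
    def _cohort(self, rng, shift_gene=None, fold=4.0, n=8):
        vals = rng.poisson(30, size=(50, 2 * n)).astype(float)
        if shift_gene is not None:
            vals[shift_gene, :n] = rng.poisson(30 * fold, size=n)
        expr = ExpressionMatrix([f"g{i}" for i in range(50)],
                                [f"s{j}" for j in range(2 * n)], vals, "counts")
        groups = pd.Series(["high"] * n + ["low"] * n, index=expr.sample_ids)
        return expr, groups

    def test_null_p_values_approximately_uniform(self, rng):
        ps = []
        for _ in range(10):
            expr, groups = self._cohort(rng)
            de = cx.differential_expression(expr, groups)
            ps.extend(de["p"].tolist())
        ks = scipy.stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_planted_fourfold_shift_called_up(self, rng):
        hits = 0
        for _ in range(20):
            expr, groups = self._cohort(rng, shift_gene=7)
            de = cx.differential_expression(expr, groups)
            if de.loc[de.gene == "g7", "direction"].iloc[0] == "up":
                hits += 1
        assert hits >= 19

    def test_group_size_floor(self, rng):
        expr, groups = self._cohort(rng, n=2)
        with pytest.raises(ValueError):
            cx.differential_expression(expr, groups)

    def test_padj_at_least_p(self, rng):
        expr, groups = self._cohort(rng, shift_gene=3)
        de = cx.differential_expression(expr, groups)
        assert (de["p_adj"] >= de["p"] - 1e-12).all()


class TestPcaCheck:
    def test_rank_one_data_passes(self):
        u = np.arange(1.0, 9.0)
        v = np.array([2.0, -1.0, 0.5, 3.0])
        expr = ExpressionMatrix([f"g{i}" for i in range(4)],
                                [f"s{j}" for j in range(8)],
                                np.outer(v, u))
        out = cx.pca_cluster_check(expr)
        assert out["pass"]
        assert out["variance_fractions"][0] == pytest.approx(1.0)

    def test_variance_fractions_sum_to_one(self, small_expr):
        out = cx.pca_cluster_check(small_expr)
        assert out["variance_fractions"].sum() == pytest.approx(1.0)

    def test_isotropic_noise_fails(self, rng):
        fails = 0
        for _ in range(10):
            vals = rng.standard_normal((100, 16))
            expr = ExpressionMatrix([f"g{i}" for i in range(100)],
                                    [f"s{j}" for j in range(16)], vals)
            if not cx.pca_cluster_check(expr)["pass"]:
                fails += 1
        assert fails >= 9


class TestSignedAdjacency:
    def test_endpoints_and_closed_form(self):
        x = np.arange(10.0)
        vals = np.vstack([x, 2 * x + 1, -x + 3])
        expr = ExpressionMatrix(["a", "b", "c"], [f"s{i}" for i in range(10)], vals)
        adj = cx.signed_adjacency(expr, beta=6)
        assert adj[0, 1] == pytest.approx(1.0)       # cor +1
        assert adj[0, 2] == pytest.approx(0.0)       # cor -1
        assert np.all(np.diag(adj) == 1.0)

    def test_zero_correlation_closed_form(self):
        # two orthogonal patterns: cor 0 -> ((1+0)/2)^6
        vals = np.array([[1.0, -1, 1, -1], [1.0, 1, -1, -1]])
        expr = ExpressionMatrix(["a", "b"], list("wxyz"), vals)
        adj = cx.signed_adjacency(expr, beta=6)
        assert adj[0, 1] == pytest.approx(0.5 ** 6, abs=1e-12)

    def test_matches_elementwise_brute_force(self, rng):
        vals = rng.standard_normal((5, 30))
        expr = ExpressionMatrix([f"g{i}" for i in range(5)],
                                [f"s{j}" for j in range(30)], vals)
        adj = cx.signed_adjacency(expr, beta=4)
        for i in range(5):
            for j in range(5):
                if i == j:
                    continue
                c = np.corrcoef(vals[i], vals[j])[0, 1]
                assert adj[i, j] == pytest.approx(((1 + c) / 2) ** 4, abs=1e-10)

    def test_constant_gene_rejected(self):
        vals = np.vstack([np.ones(5), np.arange(5.0)])
        expr = ExpressionMatrix(["a", "b"], [f"s{i}" for i in range(5)], vals)
        with pytest.raises(ValueError, match="constant"):
            cx.signed_adjacency(expr, beta=6)


def tom_brute_force(adj):
    n = adj.shape[0]
    A = adj.copy()
    np.fill_diagonal(A, 0.0)
    tom = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(A[i, u] * A[u, j] for u in range(n) if u not in (i, j))
            ki = sum(A[i, u] for u in range(n) if u != i)
            kj = sum(A[j, u] for u in range(n) if u != j)
            tom[i, j] = (shared + A[i, j]) / (min(ki, kj) + 1 - A[i, j])
    return tom


class TestTOM:
    def test_identical_neighborhood_unit_overlap(self):
        adj = np.ones((4, 4))
        tom = cx.topological_overlap(adj)
        np.testing.assert_allclose(tom, 1.0)

    def test_isolated_pair_equals_adjacency(self):
        adj = np.eye(4)
        adj[0, 1] = adj[1, 0] = 0.6
        tom = cx.topological_overlap(adj)
        assert tom[0, 1] == pytest.approx(0.6)

    def test_matches_triple_loop_brute_force(self, rng):
        for _ in range(10):
            raw = rng.uniform(0, 1, (6, 6))
            adj = (raw + raw.T) / 2
            np.fill_diagonal(adj, 1.0)
            np.testing.assert_allclose(cx.topological_overlap(adj),
                                       tom_brute_force(adj), atol=1e-10)

    def test_non_symmetric_rejected(self):
        adj = np.eye(3)
        adj[0, 1] = 0.5
        with pytest.raises(ValueError):
            cx.topological_overlap(adj)


class TestSoftPower:
    def test_single_candidate_returned(self, rng):
        expr, _, _ = synthetic.generate_module_blocks(60, [20], 0.8, 50, seed=1)
        power, fit = cx.pick_soft_power(expr, candidate_powers=(7,))
        assert power == 7 and len(fit) == 1

    def test_mean_adjacency_nonincreasing_in_power(self, rng):
        expr, _, _ = synthetic.generate_module_blocks(60, [20], 0.8, 50, seed=2)
        means = [cx.signed_adjacency(expr, b).mean() for b in (1, 2, 4, 8)]
        assert all(a >= b - 1e-12 for a, b in zip(means, means[1:]))


class TestDetectModules:
    def test_planted_blocks_recovered(self):
        expr, labels, _ = synthetic.generate_module_blocks(
            200, [50, 50, 50], 0.9, 200, seed=11)
        mods = cx.build_modules(expr, min_size=10)
        ari = adjusted_rand_score(labels, pd.factorize(mods.labels.to_numpy())[0])
        assert ari >= 0.9

    def test_min_size_above_n_genes_all_grey(self, rng):
        expr, _, _ = synthetic.generate_module_blocks(30, [10, 10], 0.9, 60, seed=3)
        adj = cx.signed_adjacency(expr, 6)
        tom = cx.topological_overlap(adj)
        labels = cx.detect_modules(tom, expr.gene_ids, min_size=40)
        assert (labels == cx.GREY).all()

    def test_gene_permutation_equivariance(self):
        expr, _, _ = synthetic.generate_module_blocks(60, [20, 20], 0.9, 100, seed=4)
        adj = cx.topological_overlap(cx.signed_adjacency(expr, 6))
        lab1 = cx.detect_modules(adj, expr.gene_ids, min_size=5)
        perm = np.random.default_rng(0).permutation(60)
        adj_p = adj[np.ix_(perm, perm)]
        genes_p = [expr.gene_ids[i] for i in perm]
        lab2 = cx.detect_modules(adj_p, genes_p, min_size=5)
        # co-membership must be preserved under gene reordering
        for a in range(0, 60, 7):
            for b in range(1, 60, 11):
                ga, gb = expr.gene_ids[a], expr.gene_ids[b]
                assert (lab1[ga] == lab1[gb]) == (lab2[ga] == lab2[gb])


class TestEigengenes:
    def test_identical_genes_kme_one(self):
        profile = np.sin(np.arange(20.0))
        vals = np.vstack([profile * c for c in (1.0, 2.0, 3.0)])
        expr = ExpressionMatrix(["a", "b", "c"], [f"s{i}" for i in range(20)], vals)
        labels = pd.Series(["M1"] * 3, index=expr.gene_ids)
        eig, kme, assigned = cx.module_eigengenes(expr, labels)
        np.testing.assert_allclose(kme["M1"].to_numpy(), 1.0, atol=1e-9)
        zp = (profile - profile.mean()) / profile.std()
        np.testing.assert_allclose(np.abs(eig["M1"].to_numpy()), np.abs(zp),
                                   atol=1e-9)

    def test_sign_orientation_positive_for_members(self):
        expr, labels_true, _ = synthetic.generate_module_blocks(
            40, [20], 0.9, 80, seed=5)
        neg = expr.values.copy()
        neg[:20] *= -1.0
        expr_neg = ExpressionMatrix(expr.gene_ids, expr.sample_ids, neg, "lognorm")
        labels = pd.Series(np.where(labels_true == 0, "M1", cx.GREY),
                           index=expr.gene_ids)
        _, kme, _ = cx.module_eigengenes(expr_neg, labels)
        members = labels.index[labels == "M1"]
        assert (kme.loc[members, "M1"] > 0).all()

    def test_background_gene_goes_grey(self):
        expr, labels_true, _ = synthetic.generate_module_blocks(
            50, [20], 0.9, 100, seed=6)
        labels = pd.Series(np.where(labels_true == 0, "M1", cx.GREY),
                           index=expr.gene_ids)
        _, _, assigned = cx.module_eigengenes(expr, labels)
        background = expr.gene_ids[20:]
        assert (assigned[background] == cx.GREY).mean() >= 0.95


class TestModuleTrait:
    def test_trait_equal_to_eigengene(self, rng):
        eig = pd.DataFrame({"M1": rng.normal(size=12)},
                           index=[f"s{i}" for i in range(12)])
        traits = pd.DataFrame({"t": eig["M1"]})
        out = cx.module_trait_correlation(eig, traits)
        assert out["r"].iloc[0] == pytest.approx(1.0)
        assert out["strong"].iloc[0]

    def test_matches_brute_force_correlations(self, rng):
        eig = pd.DataFrame(rng.normal(size=(15, 4)),
                           columns=[f"M{i}" for i in range(1, 5)],
                           index=[f"s{i}" for i in range(15)])
        traits = pd.DataFrame(rng.normal(size=(15, 2)), columns=["a", "b"],
                              index=eig.index)
        out = cx.module_trait_correlation(eig, traits)
        for _, row in out.iterrows():
            expected = np.corrcoef(eig[row["module"]], traits[row["trait"]])[0, 1]
            assert row["r"] == pytest.approx(expected, abs=1e-12)

    def test_constant_trait_rejected(self, rng):
        eig = pd.DataFrame({"M1": rng.normal(size=5)}, index=range(5))
        with pytest.raises(ValueError):
            cx.module_trait_correlation(eig, pd.DataFrame({"t": np.ones(5)},
                                                          index=range(5)))
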
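import itertools

import numpy as np
import pandas as pd
import pytest

from immunotme import single_cell as sc
from immunotme.io import ExpressionMatrix, GeneSetCollection


def _qc_fixture():
    """150 normal cells expressing all 600 genes, plus engineered failures:
    12 cells with 200 features, 5 with 400 features, 3 with 30% mito reads."""
    rng = np.random.default_rng(5)
    n_genes, n_normal = 600, 150
    genes = [f"G{i}" for i in range(n_genes - 10)] + [f"MT-{i}" for i in range(10)]
    normal = rng.poisson(2.0, size=(n_genes, n_normal)) + 1.0
    low = np.zeros((n_genes, 12)); low[:200] = 1.0
    mid = np.zeros((n_genes, 5)); mid[:400] = 1.0
    mito = rng.poisson(2.0, size=(n_genes, 3)) + 1.0
    mito[-10:] = 60.0
    vals = np.concatenate([normal, low, mid, mito], axis=1)
    cells = ([f"c{i}" for i in range(n_normal)]
             + [f"low{i}" for i in range(12)]
             + [f"mid{i}" for i in range(5)]
             + [f"mito{i}" for i in range(3)])
    return ExpressionMatrix(genes, cells, vals, "counts")


class TestQCFilter:
    def test_engineered_counts_reported_exactly(self):
        counts = _qc_fixture()
        filtered, rep = sc.qc_filter(counts)
        assert rep.n_removed_gene_filter == 0
        assert rep.n_removed_feature_300 == 12
        assert rep.n_removed_feature_500 == 5
        assert rep.n_removed_mito == 3
        assert rep.n_cells_out == 150
        assert rep.n_cells_in - rep.n_cells_out == 12 + 5 + 3

    def test_zero_thresholds_identity(self):
        counts = _qc_fixture()
        filtered, rep = sc.qc_filter(counts, min_cells_per_gene=0,
                                     min_features_create=0,
                                     min_features_filter=0,
                                     max_mito_fraction=1.0)
        assert filtered.values.shape == counts.values.shape
        assert rep.n_cells_out == rep.n_cells_in

    def test_six_percent_mito_cell_removed_at_step_four(self):
        genes = [f"G{i}" for i in range(20)] + ["MT-0"]
        ok = np.concatenate([np.full(20, 10.0), [2.0]])        # ~1% mito
        bad = np.concatenate([np.full(20, 10.0), [12.77]])     # 6% mito
        bad = np.round(bad); bad[-1] = 13.0                    # 13/213 = 6.1%
        vals = np.column_stack([ok] * 4 + [bad])
        counts = ExpressionMatrix(genes, [f"c{i}" for i in range(5)], vals,
                                  "counts")
        _, rep = sc.qc_filter(counts, min_cells_per_gene=0,
                              min_features_create=0, min_features_filter=0)
        assert rep.n_removed_mito == 1

    def test_requires_counts(self):
        m = ExpressionMatrix(["a"], ["c"], np.array([[1.0]]), "lognorm")
        with pytest.raises(ValueError):
            sc.qc_filter(m)


class TestLogNormalize:
    def test_closed_form_two_gene_cell(self):
        counts = ExpressionMatrix(["a", "b"], ["c"], np.array([[1.0], [1.0]]),
                                  "counts")
        out = sc.log_normalize(counts, scale_factor=10_000)
        np.testing.assert_allclose(out.values, np.log(1 + 5000.0), atol=1e-12)
        assert out.unit == "lognorm"

    def test_depth_invariance(self, rng):
        v = rng.integers(0, 20, size=(30, 1)).astype(float)
        a = ExpressionMatrix([f"g{i}" for i in range(30)], ["c"], v, "counts")
        b = ExpressionMatrix([f"g{i}" for i in range(30)], ["c"], 2 * v, "counts")
        np.testing.assert_allclose(sc.log_normalize(a).values,
                                   sc.log_normalize(b).values, atol=1e-12)

    def test_matches_elementwise_recomputation(self, rng):
        v = rng.integers(1, 30, size=(4, 3)).astype(float)
        m = ExpressionMatrix(list("abcd"), list("xyz"), v, "counts")
        out = sc.log_normalize(m, scale_factor=1000)
        for i in range(4):
            for j in range(3):
                exp = np.log1p(v[i, j] * 1000 / v[:, j].sum())
                assert out.values[i, j] == pytest.approx(exp, abs=1e-12)

    def test_refuses_lognorm_input_and_zero_total_cells(self):
        m = ExpressionMatrix(["a"], ["c"], np.array([[1.0]]), "lognorm")
        with pytest.raises(ValueError, match="unit=counts"):
            sc.log_normalize(m)
        z = ExpressionMatrix(["a"], ["c"], np.array([[0.0]]), "counts")
        with pytest.raises(ValueError, match="zero-total"):
            sc.log_normalize(z)


class TestHVG:
    def _lognorm(self, rng, hot=()):
        v = rng.normal(1.0, 0.1, size=(50, 80))
        for g in hot:
            # mean-matched but far more dispersed than the background
            v[g] = rng.normal(1.0, 0.5, size=80)
        return ExpressionMatrix([f"g{i:02d}" for i in range(50)],
                                [f"c{j}" for j in range(80)], np.abs(v),
                                "lognorm")

    def test_planted_high_dispersion_selected(self, rng):
        hits = 0
        for _ in range(10):
            m = self._lognorm(rng, hot=(3, 17, 31))
            sel = sc.select_hvg(m, n=5)
            hits += {"g03", "g17", "g31"} <= set(sel)
        assert hits >= 9

    def test_n_equal_to_gene_count_returns_all(self, rng):
        m = self._lognorm(rng)
        assert sorted(sc.select_hvg(m, n=50)) == sorted(m.gene_ids)

    def test_invariant_to_cell_order(self, rng):
        m = self._lognorm(rng, hot=(5,))
        perm = list(reversed(m.sample_ids))
        assert sc.select_hvg(m, 10) == sc.select_hvg(m.subset_samples(perm), 10)


def _two_type_lognorm(rng, n_per=60, n_genes=40, sep=3.0):
    mu = np.ones(n_genes)
    mu2 = mu.copy()
    mu2[: n_genes // 2] += sep
    a = rng.normal(mu[:, None], 0.3, size=(n_genes, n_per))
    b = rng.normal(mu2[:, None], 0.3, size=(n_genes, n_per))
    vals = np.concatenate([a, b], axis=1)
    cells = [f"a{i}" for i in range(n_per)] + [f"b{i}" for i in range(n_per)]
    m = ExpressionMatrix([f"g{i}" for i in range(n_genes)], cells,
                         np.abs(vals), "lognorm")
    truth = np.array([0] * n_per + [1] * n_per)
    return m, truth


class TestEmbedAndCluster:
    def test_pc1_separates_two_planted_types(self, rng):
        m, truth = _two_type_lognorm(rng)
        emb, frac = sc.embed_cells(m, m.gene_ids, n_pcs=5, seed=1)
        pc1 = emb["PC1"].to_numpy()
        pred = (pc1 > np.median(pc1)).astype(int)
        acc = max((pred == truth).mean(), (1 - pred == truth).mean())
        assert acc >= 0.95
        assert frac.sum() <= 1.0 + 1e-9

    def test_clip_limits_outlier_influence(self, rng):
        m, _ = _two_type_lognorm(rng)
        v = m.values.copy()
        v[0, 0] = 1e6
        m2 = ExpressionMatrix(m.gene_ids, m.sample_ids, v, "lognorm")
        emb, _ = sc.embed_cells(m2, m2.gene_ids, n_pcs=3, seed=1, clip=10.0)
        # the outlier cell must not be arbitrarily far from the rest
        d = np.linalg.norm(emb.to_numpy() - emb.to_numpy().mean(axis=0), axis=1)
        assert d[0] <= 20 * np.median(d)

    def test_three_types_clustered(self, rng):
        from sklearn.metrics import adjusted_rand_score
        mu = np.ones(30)
        blocks, truth = [], []
        for t in range(3):
            m = mu.copy()
            m[t * 10:(t + 1) * 10] += 3.0
            blocks.append(rng.normal(m[:, None], 0.3, size=(30, 50)))
            truth += [t] * 50
        vals = np.abs(np.concatenate(blocks, axis=1))
        m = ExpressionMatrix([f"g{i}" for i in range(30)],
                             [f"c{i}" for i in range(150)], vals, "lognorm")
        emb, _ = sc.embed_cells(m, m.gene_ids, n_pcs=5, seed=2)
        labels = sc.cluster_cells(emb, k_neighbors=15)
        assert adjusted_rand_score(truth, labels.to_numpy()) >= 0.9

    def test_tiny_resolution_single_cluster(self, rng):
        # weakly separated types keep the SNN graph connected; vanishing
        # resolution must then merge everything into one community
        m, _ = _two_type_lognorm(rng, n_per=30, sep=0.3)
        emb, _ = sc.embed_cells(m, m.gene_ids, n_pcs=3, seed=3)
        labels = sc.cluster_cells(emb, k_neighbors=20, resolution=1e-4)
        assert labels.nunique() == 1


class TestAnnotation:
    def test_planted_markers_label_cluster(self, rng):
        m, truth = _two_type_lognorm(rng)
        clusters = pd.Series(truth, index=m.sample_ids)
        sets = GeneSetCollection({
            "typeB": [f"g{i}" for i in range(20)],       # elevated in type 1
            "typeA": [f"g{i}" for i in range(20, 40)]})
        ann = sc.annotate_clusters(m, clusters, sets)
        assert ann.cluster_labels[1] == "typeB"
        assert ann.cluster_labels[0] == "typeA"

    def test_identical_marker_sets_tie_flagged(self, rng):
        m, truth = _two_type_lognorm(rng)
        clusters = pd.Series(truth, index=m.sample_ids)
        sets = GeneSetCollection({"beta": [f"g{i}" for i in range(10)],
                                  "alpha": [f"g{i}" for i in range(10)]})
        ann = sc.annotate_clusters(m, clusters, sets)
        assert ann.cluster_labels[1] == "alpha"   # lexicographic tie-break
        assert set(ann.uncertain) == {0, 1}


def _ranksum_exact(a, b):
    import scipy.stats
    pooled = np.concatenate([a, b])
    ranks = scipy.stats.rankdata(pooled)
    n = len(a)
    obs = ranks[:n].sum()
    mu = n * (len(pooled) + 1) / 2
    cnt = tot = 0
    for comb in itertools.combinations(range(len(pooled)), n):
        s = ranks[list(comb)].sum()
        cnt += abs(s - mu) >= abs(obs - mu) - 1e-9
        tot += 1
    return cnt / tot


class TestClusterMarkers:
    def test_planted_marker_top_ranked(self, rng):
        hits = 0
        for _ in range(10):
            m, truth = _two_type_lognorm(rng, n_per=40, sep=0.0)
            v = m.values.copy()
            v[7, truth == 1] += 3.0                      # 1 marker for cluster 1
            m2 = ExpressionMatrix(m.gene_ids, m.sample_ids, v, "lognorm")
            clusters = pd.Series(truth, index=m.sample_ids)
            markers = sc.cluster_markers(m2, clusters)
            hits += markers[1].iloc[0]["gene"] == "g7"
        assert hits >= 9

    def test_exact_rank_sum_for_small_clusters(self, rng):
        v = rng.normal(1.0, 0.5, size=(6, 11))
        m = ExpressionMatrix([f"g{i}" for i in range(6)],
                             [f"c{i}" for i in range(11)], np.abs(v), "lognorm")
        clusters = pd.Series([0] * 5 + [1] * 6, index=m.sample_ids)
        markers = sc.cluster_markers(m, clusters)
        tab = markers[0].set_index("gene")
        for i in range(6):
            a, b = v[i, :5], v[i, 5:]
            assert tab.loc[f"g{i}", "p"] == pytest.approx(
                _ranksum_exact(a, b), abs=1e-9)

    def test_singleton_cluster_rejected(self, rng):
        m, _ = _two_type_lognorm(rng, n_per=4)
        clusters = pd.Series([0] * 7 + [1], index=m.sample_ids)
        with pytest.raises(ValueError):
            sc.cluster_markers(m, clusters)
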
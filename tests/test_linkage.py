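import numpy as np
import pandas as pd
import pytest

from immunotme import linkage, survival as surv
from immunotme.io import ExpressionMatrix
from immunotme.single_cell import CellAnnotation
from conftest import make_clinical


class TestCellBulkCorrelation:
    def _pair(self, rng, n_genes=120):
        genes = [f"g{i}" for i in range(n_genes)]
        sc_vals = np.abs(rng.normal(1, 0.5, size=(n_genes, 5)))
        bulk_vals = np.abs(rng.normal(1, 0.5, size=(n_genes, 4)))
        sc_m = ExpressionMatrix(genes, [f"c{i}" for i in range(5)],
                                sc_vals, "lognorm")
        bulk = ExpressionMatrix(genes, [f"s{i}" for i in range(4)],
                                bulk_vals, "lognorm")
        return sc_m, bulk

    def test_proportional_profiles_correlate_one(self, rng):
        sc_m, bulk = self._pair(rng)
        b2 = bulk.values.copy()
        b2[:, 0] = 3.0 * sc_m.values[:, 2] + 1.0
        bulk2 = ExpressionMatrix(bulk.gene_ids, bulk.sample_ids, b2, "lognorm")
        out = linkage.cell_bulk_correlation(sc_m, bulk2)
        assert out.S.loc["c2", "s0"] == pytest.approx(1.0)

    def test_antiproportional_minus_one(self, rng):
        sc_m, bulk = self._pair(rng)
        b2 = bulk.values.copy()
        b2[:, 1] = -2.0 * sc_m.values[:, 0] + 10.0
        bulk2 = ExpressionMatrix(bulk.gene_ids, bulk.sample_ids, b2, "lognorm")
        out = linkage.cell_bulk_correlation(sc_m, bulk2)
        assert out.S.loc["c0", "s1"] == pytest.approx(-1.0)

    def test_matches_pairwise_brute_force(self, rng):
        sc_m, bulk = self._pair(rng)
        out = linkage.cell_bulk_correlation(sc_m, bulk)
        for i in range(5):
            for j in range(4):
                expected = np.corrcoef(sc_m.values[:, i], bulk.values[:, j])[0, 1]
                assert out.S.iloc[i, j] == pytest.approx(expected, abs=1e-10)

    def test_insufficient_overlap_rejected(self, rng):
        sc_m, bulk = self._pair(rng, n_genes=120)
        small = bulk.subset_genes(bulk.gene_ids[:50])
        with pytest.raises(ValueError, match="shared genes"):
            linkage.cell_bulk_correlation(sc_m, small)


class TestCellGraph:
    def test_complete_graph_spectrum(self):
        emb = pd.DataFrame(np.eye(3), index=["a", "b", "c"])
        L = linkage.build_cell_graph(emb, k_neighbors=2)
        eig = np.sort(np.linalg.eigvalsh(L))
        np.testing.assert_allclose(eig, [0, 3, 3], atol=1e-9)

    def test_row_sums_zero_and_quadratic_form_identity(self, rng):
        emb = pd.DataFrame(rng.normal(size=(10, 3)),
                           index=[f"c{i}" for i in range(10)])
        L = linkage.build_cell_graph(emb, k_neighbors=3)
        np.testing.assert_allclose(L.sum(axis=1), 0.0, atol=1e-12)
        x = rng.normal(size=10)
        A = np.diag(np.diag(L)) - L
        quad = sum(A[i, j] * (x[i] - x[j]) ** 2
                   for i in range(10) for j in range(i + 1, 10))
        assert x @ L @ x == pytest.approx(quad, abs=1e-9)

    def test_positive_semidefinite(self, rng):
        emb = pd.DataFrame(rng.normal(size=(15, 4)),
                           index=[f"c{i}" for i in range(15)])
        L = linkage.build_cell_graph(emb, k_neighbors=4)
        assert np.linalg.eigvalsh(L).min() >= -1e-8


def _selection_problem(rng, n_cells=30, n_samples=40, signal_cells=5):
    """Cells x samples correlation-like design with planted positive-risk
    signal on the first cells."""
    risk = rng.normal(size=n_samples)
    S = rng.normal(0, 0.2, size=(n_cells, n_samples))
    S[:signal_cells] += 0.5 * risk
    S = np.tanh(S)
    tte = rng.exponential(scale=np.exp(-risk))
    clin = make_clinical(tte, np.ones(n_samples),
                         ids=[f"s{i}" for i in range(n_samples)])
    Sdf = pd.DataFrame(S, index=[f"c{i}" for i in range(n_cells)],
                       columns=clin.sample_ids)
    return Sdf, clin


class TestPenalizedCox:
    def test_large_lambda_full_shrinkage(self, rng):
        S, clin = _selection_problem(rng)
        res = linkage.penalized_cox_select(S, clin, lam=1e6, alpha_mix=1.0)
        assert (res.beta == 0).all()
        assert (res.classes() == "background").all()

    def test_lambda_zero_single_feature_matches_unpenalized_cox(self, rng):
        n = 50
        risk = rng.normal(size=n)
        tte = rng.exponential(scale=np.exp(-risk))
        clin = make_clinical(tte, np.ones(n))
        S = pd.DataFrame(risk[None, :], index=["c0"], columns=clin.sample_ids)
        res = linkage.penalized_cox_select(S, clin, lam=0.0, alpha_mix=1.0,
                                           tol=1e-10, max_iter=5000)
        cov = pd.DataFrame({"c0": risk}, index=clin.sample_ids)
        fit = surv.fit_cox(clin, cov)
        assert np.sign(res.beta["c0"]) == np.sign(fit.coef["c0"]) == 1.0
        # standardized coefficients agree
        assert res.beta["c0"] == pytest.approx(
            fit.coef["c0"] * risk.std(), rel=1e-2)

    def test_objective_monotone_decrease(self, rng):
        S, clin = _selection_problem(rng)
        L = np.diag(np.full(30, 2.0)) - np.diag(np.ones(29), 1) \
            - np.diag(np.ones(29), -1)
        L[0, 0] = L[-1, -1] = 1.0
        res = linkage.penalized_cox_select(S, clin, lam=1.0, alpha_mix=0.3,
                                           L=L)
        diffs = np.diff(res.objective_path)
        assert (diffs <= 1e-9).all()

    def test_nonzero_count_nonincreasing_along_path(self, rng):
        S, clin = _selection_problem(rng)
        lams = linkage.lambda_path(S, clin, alpha_mix=1.0, n_lambdas=10)
        counts = []
        for lam in sorted(lams):
            res = linkage.penalized_cox_select(S, clin, lam, alpha_mix=1.0)
            counts.append(int((res.beta != 0).sum()))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_pure_l1_matches_coordinate_descent_oracle(self, rng):
        """With L = 0 and alpha_mix = 1 the selector is plain L1 Cox; a
        from-scratch proximal coordinate-descent solver must agree."""
        S, clin = _selection_problem(rng, n_cells=10, n_samples=30,
                                     signal_cells=3)
        lam = 2.0
        res = linkage.penalized_cox_select(S, clin, lam, alpha_mix=1.0,
                                           tol=1e-12, max_iter=20000)
        time, event, X = linkage._prep_survival(S, clin)

        beta = np.zeros(10)
        for _ in range(3000):                    # cyclic coordinate descent
            for k in range(10):
                g = surv.breslow_gradient(beta, time, event, X)
                step = 1e-3
                bk = beta[k] + step * g[k]
                beta[k] = np.sign(bk) * max(abs(bk) - step * lam, 0.0)
        obj_cd = (-surv.breslow_loglik(beta, time, event, X)
                  + lam * np.abs(beta).sum())
        obj_pg = (-surv.breslow_loglik(res.beta.to_numpy(), time, event, X)
                  + lam * np.abs(res.beta.to_numpy()).sum())
        assert obj_pg <= obj_cd + 1e-3
        np.testing.assert_allclose(res.beta.to_numpy(), beta, atol=5e-2)

    def test_negative_lambda_rejected(self, rng):
        S, clin = _selection_problem(rng)
        with pytest.raises(ValueError):
            linkage.penalized_cox_select(S, clin, lam=-1.0)


def _annotation(cells, types):
    clusters = pd.Series(range(len(cells)), index=cells)
    # one cluster per cell keeps the mapping trivial
    labels = {i: t for i, t in enumerate(types)}
    return CellAnnotation(clusters=clusters, cluster_labels=labels,
                          margins={i: 1.0 for i in range(len(cells))},
                          uncertain=set())


class TestCalls:
    def _scores(self, beta_dict):
        beta = pd.Series(beta_dict)
        return linkage.CellPhenotypeScores(beta=beta, lam=1.0, alpha_mix=0.5,
                                           converged=True, n_iter=1)

    def test_all_zero_empty_calls(self):
        sc_scores = self._scores({"c1": 0.0, "c2": 0.0})
        ann = _annotation(["c1", "c2"], ["B", "T"])
        assert linkage.classify_and_call(sc_scores, ann, "low") == []

    def test_two_types_two_calls_with_composed_names(self):
        sc_scores = self._scores({"c1": 0.5, "c2": 0.3, "c3": -0.2})
        ann = _annotation(["c1", "c2", "c3"], ["B", "B", "T"])
        calls = linkage.classify_and_call(sc_scores, ann, "low")
        names = {c.name for c in calls}
        assert names == {"BLp", "TLn"}
        blp = next(c for c in calls if c.name == "BLp")
        assert sorted(blp.members) == ["c1", "c2"]
        assert blp.flagged_small

    def test_union_context_letters_follow_sign(self):
        sc_scores = self._scores({"c1": 0.5, "c2": -0.2})
        ann = _annotation(["c1", "c2"], ["B", "T"])
        calls = linkage.classify_and_call(sc_scores, ann, "union")
        assert {c.name for c in calls} == {"BLp", "THn"}


class TestSignatureIntersection:
    def test_set_algebra_invariants(self, rng):
        genes = [f"g{i}" for i in range(40)]
        vals = np.abs(rng.normal(1, 0.3, size=(40, 30)))
        vals[:8, :10] += 2.0                       # members elevated in 8 genes
        m = ExpressionMatrix(genes, [f"c{i}" for i in range(30)], vals,
                             "lognorm")
        members = [f"c{i}" for i in range(10)]
        ann = CellAnnotation(
            clusters=pd.Series(0, index=m.sample_ids),
            cluster_labels={0: "B"}, margins={0: 1.0}, uncertain=set())
        call = linkage.SubpopulationCall(name="BLp", parent_type="B",
                                         sign="plus", members=members)
        module_genes = genes[4:20]
        out = linkage.subpopulation_signature(call, m, ann, module_genes)
        assert set(out.module_intersection) <= set(out.signature_genes)
        assert set(out.module_intersection) <= set(module_genes)
        assert set(out.signature_genes) & set(genes[:8])

    def test_disjoint_module_genes_empty_intersection(self, rng):
        genes = [f"g{i}" for i in range(40)]
        vals = np.abs(rng.normal(1, 0.3, size=(40, 20)))
        vals[:5, :8] += 2.0
        m = ExpressionMatrix(genes, [f"c{i}" for i in range(20)], vals,
                             "lognorm")
        ann = CellAnnotation(
            clusters=pd.Series(0, index=m.sample_ids),
            cluster_labels={0: "B"}, margins={0: 1.0}, uncertain=set())
        call = linkage.SubpopulationCall(name="BLp", parent_type="B",
                                         sign="plus",
                                         members=[f"c{i}" for i in range(8)])
        out = linkage.subpopulation_signature(call, m, ann, ["zzz1", "zzz2"])
        assert out.module_intersection == []

    def test_small_call_flagged_not_crashed(self, rng):
        genes = [f"g{i}" for i in range(12)]
        m = ExpressionMatrix(genes, ["c0", "c1", "c2"],
                             np.abs(rng.normal(1, 0.3, (12, 3))), "lognorm")
        ann = CellAnnotation(clusters=pd.Series(0, index=m.sample_ids),
                             cluster_labels={0: "B"}, margins={0: 1.0},
                             uncertain=set())
        call = linkage.SubpopulationCall(name="BLp", parent_type="B",
                                         sign="plus", members=["c0"])
        out = linkage.subpopulation_signature(call, m, ann, genes)
        assert out.flagged_small and out.signature_genes == []
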
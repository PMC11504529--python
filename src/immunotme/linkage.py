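"""Phenotype-guided single-cell selection (Scissor-style joint analysis).

Single cells are linked to bulk samples through the Pearson correlation of
their expression profiles on shared genes. The resulting cell-by-sample
matrix S becomes the design of a Cox regression of bulk survival: each
cell c contributes a coefficient beta_c to the per-sample linear predictor
``sum_c beta_c * S[c, sample]``, and the fit is penalized by an elastic
mix of an L1 sparsity term and a graph-Laplacian smoothness term over the
cell-cell KNN graph:

    minimize  -loglik_Breslow(S' beta)
              + lambda * [ alpha * ||beta||_1 + (1 - alpha) * beta' L beta ]

solved by proximal gradient descent with backtracking. Cells with
beta_c > 0 are "plus" cells (associated with poor survival), beta_c < 0
"minus" (good survival), and exact zeros from the soft-threshold step are
background — no post-hoc threshold is needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse

from .io import ClinicalTable, ExpressionMatrix
from .single_cell import CellAnnotation, cluster_markers
from .deconvolution import spearman_with_p
from .survival import breslow_gradient, breslow_loglik


# ---------------------------------------------------------------------------
# Cell-bulk correlation
# ---------------------------------------------------------------------------

@dataclass
class CellBulkCorrelation:
    S: pd.DataFrame                  # cells x samples, entries in [-1, 1]
    n_shared_genes: int


def cell_bulk_correlation(sc_lognorm: ExpressionMatrix,
                          bulk: ExpressionMatrix,
                          min_shared: int = 100) -> CellBulkCorrelation:
    """Pearson correlation of every (cell, bulk sample) pair on the shared
    gene set. Bulk counts are log-transformed first."""
    shared = [g for g in sc_lognorm.gene_ids if g in set(bulk.gene_ids)]
    if len(shared) < min_shared:
        raise ValueError(f"only {len(shared)} shared genes (need >= {min_shared})")
    A = sc_lognorm.subset_genes(shared).values.T          # cells x genes
    B = bulk.subset_genes(shared).values.T                # samples x genes
    if bulk.unit in ("counts", "normalized"):
        B = np.log1p(B)
    for name, M, ids in (("cell", A, sc_lognorm.sample_ids),
                         ("sample", B, bulk.sample_ids)):
        sd = M.std(axis=1)
        if np.any(sd == 0):
            bad = [i for i, s in zip(ids, sd) if s == 0]
            raise ValueError(f"zero-variance {name}(s): {bad[:3]}")
    Az = (A - A.mean(axis=1, keepdims=True)) / A.std(axis=1, keepdims=True)
    Bz = (B - B.mean(axis=1, keepdims=True)) / B.std(axis=1, keepdims=True)
    S = Az @ Bz.T / len(shared)
    return CellBulkCorrelation(
        pd.DataFrame(S, index=sc_lognorm.sample_ids, columns=bulk.sample_ids),
        n_shared_genes=len(shared))


# ---------------------------------------------------------------------------
# Cell graph
# ---------------------------------------------------------------------------

def build_cell_graph(embedding: pd.DataFrame, k_neighbors: int = 10) -> np.ndarray:
    """Symmetrized KNN graph Laplacian ``L = D - A`` over the cell
    embedding; positive semidefinite by construction."""
    from sklearn.neighbors import kneighbors_graph
    if k_neighbors < 2:
        raise ValueError("k_neighbors must be at least 2")
    A = kneighbors_graph(embedding.to_numpy(), n_neighbors=k_neighbors,
                         mode="connectivity", include_self=False)
    A = A.maximum(A.T).toarray()
    L = np.diag(A.sum(axis=1)) - A
    return L


# ---------------------------------------------------------------------------
# Penalized Cox selection
# ---------------------------------------------------------------------------

@dataclass
class CellPhenotypeScores:
    beta: pd.Series                  # cell -> coefficient
    lam: float
    alpha_mix: float
    converged: bool
    n_iter: int
    objective_path: list[float] = field(default_factory=list)

    def classes(self) -> pd.Series:
        return pd.Series(
            np.where(self.beta > 0, "plus",
                     np.where(self.beta < 0, "minus", "background")),
            index=self.beta.index, name="class")

    @property
    def nonzero_fraction(self) -> float:
        return float((self.beta != 0).mean())


def _soft_threshold(x: np.ndarray, t: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - t, 0.0)


def _prep_survival(S: pd.DataFrame, clinical: ClinicalTable,
                   center_cells: bool = True):
    df = clinical.table.set_index("sample_id").loc[S.columns]
    time = df["time"].to_numpy(dtype=float)
    event = df["event"].to_numpy(dtype=float)
    if event.sum() < 1:
        raise ValueError("no events in the clinical data")
    X = S.to_numpy(dtype=float).T                      # samples x cells
    if center_cells:
        # remove the component every cell shares with a sample (library /
        # composition effects) so coefficients reflect cell-specific signal
        X = X - X.mean(axis=1, keepdims=True)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return time, event, (X - mu) / sd


def penalized_cox_select(S: pd.DataFrame, clinical: ClinicalTable,
                         lam: float, alpha_mix: float = 0.05,
                         L: np.ndarray | None = None,
                         tol: float = 1e-6, max_iter: int = 2000,
                         beta0: np.ndarray | None = None,
                         center_cells: bool = True) -> CellPhenotypeScores:
    """Proximal-gradient solver for the graph-regularized sparse Cox cell
    selector. The objective (tracked on every iterate) decreases
    monotonically; convergence is declared when its relative change falls
    below ``tol``. ``center_cells`` removes the per-sample mean over cells
    before standardizing (set False for designs with very few cells)."""
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    if not 0 <= alpha_mix <= 1:
        raise ValueError("alpha_mix outside [0, 1]")
    time, event, X = _prep_survival(S, clinical,
                                    center_cells=center_cells and len(S) >= 3)
    n_cells = X.shape[1]
    if L is None:
        L = np.zeros((n_cells, n_cells))
    L = np.asarray(L, dtype=float)
    lam_l1 = lam * alpha_mix
    lam_graph = lam * (1.0 - alpha_mix)

    def smooth(beta: np.ndarray) -> float:
        return -breslow_loglik(beta, time, event, X) + lam_graph * float(beta @ L @ beta)

    def smooth_grad(beta: np.ndarray) -> np.ndarray:
        g = breslow_gradient(beta, time, event, X)
        return -g + 2.0 * lam_graph * (L @ beta)

    def objective(beta: np.ndarray) -> float:
        return smooth(beta) + lam_l1 * float(np.abs(beta).sum())

    beta = np.zeros(n_cells) if beta0 is None else beta0.astype(float).copy()
    step = 1.0
    obj = objective(beta)
    path = [obj]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        g = smooth_grad(beta)
        f = smooth(beta)
        # backtracking on the smooth part's quadratic upper bound
        while True:
            cand = _soft_threshold(beta - step * g, step * lam_l1)
            diff = cand - beta
            quad = f + g @ diff + (diff @ diff) / (2.0 * step)
            if smooth(cand) <= quad + 1e-12:
                break
            step *= 0.5
            if step < 1e-14:
                cand = beta
                break
        new_obj = objective(cand)
        if new_obj > obj + 1e-10:
            # should not happen with a valid backtracking step
            cand, new_obj = beta, obj
        beta = cand
        path.append(new_obj)
        if abs(obj - new_obj) <= tol * max(1.0, abs(obj)):
            obj = new_obj
            converged = True
            break
        obj = new_obj
        step = min(step * 2.0, 1.0)
    return CellPhenotypeScores(
        beta=pd.Series(beta, index=S.index, name="beta"),
        lam=lam, alpha_mix=alpha_mix, converged=converged, n_iter=it,
        objective_path=path)


def lambda_path(S: pd.DataFrame, clinical: ClinicalTable, alpha_mix: float = 0.5,
                n_lambdas: int = 10, min_ratio: float = 0.01) -> np.ndarray:
    """Log-spaced lambda path from the smallest value that zeroes every
    coefficient (under pure L1 this is ||grad(0)||_inf / alpha) downward."""
    time, event, X = _prep_survival(S, clinical)
    g0 = breslow_gradient(np.zeros(X.shape[1]), time, event, X)
    lam_max = float(np.max(np.abs(g0))) / max(alpha_mix, 1e-3)
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambdas)


def select_lambda_cv(S: pd.DataFrame, clinical: ClinicalTable,
                     alpha_mix: float = 0.05, L: np.ndarray | None = None,
                     n_lambdas: int = 10, n_folds: int = 5,
                     max_nonzero_fraction: float = 0.35,
                     min_plus_fraction: float = 0.05,
                     seed: int | np.random.Generator = 0,
                     tol: float = 1e-5, max_iter: int = 500
                     ) -> tuple[float, pd.DataFrame]:
    """Small path search: pick the lambda maximizing the cross-validated
    partial likelihood (Verweij-van Houwelingen: ll_all(beta) - ll_train(beta))
    among lambdas whose full-data fit (a) selects at most
    ``max_nonzero_fraction`` of the cells and (b) gives at least
    ``min_plus_fraction`` of the cells a positive (poor-survival)
    coefficient — a reliability guard against near-null fits, which the CV
    statistic alone cannot rule out with few bulk samples. Falls back to the
    densest fit under the cap when no lambda qualifies."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lams = lambda_path(S, clinical, alpha_mix, n_lambdas)
    samples = list(S.columns)
    n = len(samples)
    folds = np.array(list(range(n_folds)) * (n // n_folds + 1))[:n]
    rng.shuffle(folds)
    df = clinical.table.set_index("sample_id").loc[samples]
    time_all = df["time"].to_numpy(dtype=float)
    event_all = df["event"].to_numpy(dtype=float)
    _, _, X_all = _prep_survival(S, clinical)
    rows = []
    best_lam, best_cv = None, -np.inf
    for lam in lams:
        full = penalized_cox_select(S, clinical, lam, alpha_mix, L,
                                    tol=tol, max_iter=max_iter)
        nz = full.nonzero_fraction
        plus_frac = float((full.beta > 0).mean())
        cv_ll = 0.0
        for f in range(n_folds):
            train = [s for s, ff in zip(samples, folds) if ff != f]
            if df.loc[train, "event"].sum() < 1:
                continue
            fit = penalized_cox_select(S[train], clinical, lam, alpha_mix, L,
                                       tol=tol, max_iter=max_iter)
            beta = fit.beta.to_numpy()
            tr_idx = [samples.index(s) for s in train]
            ll_all = breslow_loglik(beta, time_all, event_all, X_all)
            ll_train = breslow_loglik(beta, time_all[tr_idx], event_all[tr_idx],
                                      X_all[tr_idx])
            cv_ll += ll_all - ll_train
        rows.append({"lambda": lam, "cv_partial_loglik": cv_ll,
                     "nonzero_fraction": nz, "plus_fraction": plus_frac})
        if (0 < nz <= max_nonzero_fraction and plus_frac >= min_plus_fraction
                and cv_ll > best_cv):
            best_lam, best_cv = float(lam), cv_ll
    path_df = pd.DataFrame(rows)
    if best_lam is None:
        below = path_df[(path_df["nonzero_fraction"] > 0)
                        & (path_df["nonzero_fraction"] <= max_nonzero_fraction)]
        if len(below):
            best_lam = float(below.iloc[-1]["lambda"])
        else:
            best_lam = float(lams[len(lams) // 2])
    return best_lam, path_df


# ---------------------------------------------------------------------------
# Subpopulation calls
# ---------------------------------------------------------------------------

@dataclass
class SubpopulationCall:
    name: str
    parent_type: str
    sign: str                        # "plus" | "minus"
    members: list[str]
    flagged_small: bool = False
    signature_genes: list[str] = field(default_factory=list)
    module_intersection: list[str] = field(default_factory=list)


def classify_and_call(scores: CellPhenotypeScores, annotation: CellAnnotation,
                      group_context: str, min_members: int = 3) -> list[SubpopulationCall]:
    """Group nonzero-coefficient cells by (parent cell type, sign) and name
    them by composition: parent type + group letter (L/H) + sign letter
    (p = plus/poor survival, n = minus/good survival), e.g. "BLp".

    With ``group_context="union"`` (selection run on the pooled low+high
    samples) the group letter follows the sign: poor-survival cells belong
    to the low-immunoactivity side (L), good-survival cells to the high
    side (H)."""
    if group_context not in ("low", "high", "union"):
        raise ValueError("group_context must be 'low', 'high' or 'union'")
    cell_types = annotation.cell_types()
    missing = set(scores.beta.index) - set(cell_types.index)
    if missing:
        raise ValueError(f"annotation does not cover cell(s): {sorted(missing)[:3]}")
    classes = scores.classes()
    calls: list[SubpopulationCall] = []
    for sign, letter in (("plus", "p"), ("minus", "n")):
        if group_context == "union":
            group_letter = "L" if sign == "plus" else "H"
        else:
            group_letter = "L" if group_context == "low" else "H"
        sel = classes.index[classes == sign]
        if len(sel) == 0:
            continue
        by_type: dict[str, list[str]] = {}
        for cell in sel:
            by_type.setdefault(str(cell_types[cell]), []).append(cell)
        for ptype in sorted(by_type):
            members = sorted(by_type[ptype])
            calls.append(SubpopulationCall(
                name=f"{ptype}{group_letter}{letter}",
                parent_type=ptype, sign=sign, members=members,
                flagged_small=len(members) < min_members))
    return calls


def subpopulation_signature(call: SubpopulationCall, lognorm: ExpressionMatrix,
                            annotation: CellAnnotation, module_genes: list[str],
                            lfc_thresh: float = 0.1,
                            padj_thresh: float = 0.05) -> SubpopulationCall:
    """Marker genes of the call's members against the other cells of its
    parent type, intersected with the co-expression module gene list."""
    if len(call.members) < 3:
        call.flagged_small = True
        return call
    cell_types = annotation.cell_types()
    parent_cells = [c for c in lognorm.sample_ids
                    if cell_types.get(c) == call.parent_type]
    others = [c for c in parent_cells if c not in set(call.members)]
    if len(others) < 3:
        call.flagged_small = True
        return call
    sub = lognorm.subset_samples(call.members + others)
    labels = pd.Series([0] * len(call.members) + [1] * len(others),
                       index=call.members + others)
    markers = cluster_markers(sub, labels)[0]
    sig = markers[(markers["p_adj"] < padj_thresh) &
                  (markers["log2fc"] > lfc_thresh)]["gene"].tolist()
    call.signature_genes = sorted(sig)
    call.module_intersection = sorted(set(sig) & set(module_genes))
    return call


def score_trend(sc_lognorm: ExpressionMatrix, call: SubpopulationCall,
                bulk_immune_scores: pd.Series, S: pd.DataFrame) -> dict:
    """Spearman trend between each member cell's mean signature expression
    and the immune score of its best-correlated bulk sample."""
    if not call.members:
        raise ValueError("empty call")
    genes = call.signature_genes or call.module_intersection
    if not genes:
        raise ValueError("call has no signature genes")
    sub = sc_lognorm.subset_genes([g for g in genes if g in set(sc_lognorm.gene_ids)])
    cidx = {c: i for i, c in enumerate(sub.sample_ids)}
    mean_expr = np.array([sub.values[:, cidx[c]].mean() for c in call.members])
    best_sample = S.loc[call.members].idxmax(axis=1)
    scores = bulk_immune_scores.reindex(best_sample.to_numpy()).to_numpy(dtype=float)
    rho, p = spearman_with_p(mean_expr, scores)
    return {"rho": rho, "p": p, "n": len(call.members),
            "direction": "down" if rho < 0 else ("up" if rho > 0 else "flat")}
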
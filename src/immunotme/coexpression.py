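"""Differential expression and signed co-expression module discovery.

Differential expression between the low and high immunoactivity groups uses
median-of-ratios size-factor normalization followed by a per-gene Welch
t-test on log2(normalized + 1) with Benjamini-Hochberg adjustment. This is
a deliberately simple, fully auditable substitute for a negative-binomial
Wald test: the downstream network analysis consumes only a ranked DE gene
list.

The co-expression network follows the signed weighted-correlation recipe:
adjacency ``a_ij = ((1 + cor_ij) / 2) ** beta`` with the soft power chosen
by a scale-free topology criterion, topological overlap (TOM) as the
clustering similarity, average-linkage hierarchical clustering of 1 - TOM
with a simplified dynamic-hybrid cut (static height cut, small clusters
reassigned to the nearest module by mean TOM or dropped to "grey"), module
eigengenes as first principal components, and kME-based final assignment at
the 0.75 membership threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy
import scipy.spatial.distance
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

GREY = "grey"


# ---------------------------------------------------------------------------
# Differential expression
# ---------------------------------------------------------------------------

def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (computed over genes with all-positive
    counts, against the geometric-mean pseudo-reference)."""
    pos = np.all(counts > 0, axis=1)
    if not pos.any():
        raise ValueError("no gene with all-positive counts for size factors")
    logc = np.log(counts[pos])
    ref = logc.mean(axis=1, keepdims=True)
    return np.exp(np.median(logc - ref, axis=0))


def differential_expression(expr: ExpressionMatrix, groups: pd.Series,
                            lfc_thresh: float = 1.0,
                            padj_thresh: float = 0.05) -> pd.DataFrame:
    """Welch t-test per gene on log2(size-factor-normalized counts + 1),
    high vs low group, with BH adjustment and up/down/ns direction calls.

    All-zero genes are dropped with a logged count.
    """
    if expr.unit != "counts":
        raise ValueError("differential expression expects unit=counts")
    groups = groups.reindex(expr.sample_ids)
    hi = [s for s, g in groups.items() if g == "high"]
    lo = [s for s, g in groups.items() if g == "low"]
    if len(hi) < 3 or len(lo) < 3:
        raise ValueError("need at least 3 samples per group")
    sub = expr.subset_samples(hi + lo)
    keep = sub.values.sum(axis=1) > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d all-zero gene(s)", n_dropped)
    values = sub.values[keep]
    genes = [g for g, k in zip(sub.gene_ids, keep) if k]
    sf = size_factors(values)
    logv = np.log2(values / sf + 1.0)
    a = logv[:, :len(hi)]
    b = logv[:, len(hi):]
    stat, p = scipy.stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    stat = np.where(np.isnan(stat), 0.0, stat)
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    padj = multipletests(p, method="fdr_bh")[1]
    direction = np.where((log2fc >= lfc_thresh) & (padj < padj_thresh), "up",
                         np.where((log2fc <= -lfc_thresh) & (padj < padj_thresh),
                                  "down", "ns"))
    return pd.DataFrame({"gene": genes, "log2fc": log2fc, "stat": stat,
                         "p": p, "p_adj": padj, "direction": direction})


def differential_expression_lognorm(expr: ExpressionMatrix, groups: pd.Series,
                                    lfc_thresh: float = 1.0,
                                    padj_thresh: float = 0.05) -> pd.DataFrame:
    """Welch t-test per gene for linear/log-scale input (no size-factor
    step): used when the cohort is already normalized."""
    groups = groups.reindex(expr.sample_ids)
    hi = [s for s, g in groups.items() if g == "high"]
    lo = [s for s, g in groups.items() if g == "low"]
    if len(hi) < 3 or len(lo) < 3:
        raise ValueError("need at least 3 samples per group")
    sub = expr.subset_samples(hi + lo)
    values = np.log2(sub.values + 1.0) if sub.unit != "lognorm" else sub.values
    a = values[:, :len(hi)]
    b = values[:, len(hi):]
    stat, p = scipy.stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    padj = multipletests(p, method="fdr_bh")[1]
    direction = np.where((log2fc >= lfc_thresh) & (padj < padj_thresh), "up",
                         np.where((log2fc <= -lfc_thresh) & (padj < padj_thresh),
                                  "down", "ns"))
    return pd.DataFrame({"gene": sub.gene_ids, "log2fc": log2fc,
                         "stat": np.where(np.isnan(stat), 0.0, stat),
                         "p": p, "p_adj": padj, "direction": direction})


# ---------------------------------------------------------------------------
# PCA cluster validation
# ---------------------------------------------------------------------------

def pca_cluster_check(expr: ExpressionMatrix, gene_subset: list[str] | None = None,
                      cum_threshold: float = 0.75) -> dict:
    """PCA of the standardized gene subset across samples; passes when the
    cumulative PC1-3 variance fraction reaches ``cum_threshold``."""
    genes = gene_subset if gene_subset is not None else expr.gene_ids
    if len(genes) < 3:
        raise ValueError("need at least 3 genes")
    if expr.n_samples < 3:
        raise ValueError("need at least 3 samples")
    sub = expr.subset_genes(genes)
    X = sub.values.T                                    # samples x genes
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    Xs = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    _, svals, vt = np.linalg.svd(Xs - Xs.mean(axis=0), full_matrices=False)
    var = svals ** 2
    frac = var / var.sum()
    coords = (Xs - Xs.mean(axis=0)) @ vt.T
    cum3 = float(frac[:3].sum())
    return {
        "coordinates": pd.DataFrame(coords[:, :min(3, coords.shape[1])],
                                    index=sub.sample_ids,
                                    columns=[f"PC{i+1}" for i in range(min(3, coords.shape[1]))]),
        "variance_fractions": frac,
        "cumulative_pc1_3": cum3,
        "pass": cum3 >= cum_threshold,
    }


# ---------------------------------------------------------------------------
# Signed network
# ---------------------------------------------------------------------------

def _gene_correlation(expr: ExpressionMatrix) -> np.ndarray:
    sd = expr.values.std(axis=1, ddof=0)
    if np.any(sd == 0):
        bad = [g for g, s in zip(expr.gene_ids, sd) if s == 0]
        raise ValueError(f"constant gene(s): {bad[:3]}")
    return np.corrcoef(expr.values)


def signed_adjacency(expr: ExpressionMatrix, beta: float) -> np.ndarray:
    """Signed weighted adjacency ``((1 + cor) / 2) ** beta`` with unit
    diagonal."""
    if beta < 1:
        raise ValueError("beta must be at least 1")
    cor = _gene_correlation(expr)
    adj = ((1.0 + cor) / 2.0) ** beta
    np.fill_diagonal(adj, 1.0)
    return np.clip(adj, 0.0, 1.0)


def pick_soft_power(expr: ExpressionMatrix,
                    candidate_powers: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 10, 12, 14, 16),
                    r2_target: float = 0.8, default_power: int = 6,
                    n_bins: int = 10) -> tuple[int, pd.DataFrame]:
    """Smallest candidate power whose connectivity distribution fits a
    scale-free law with R^2 >= ``r2_target`` (log-log regression of binned
    degree frequency, requiring a negative slope). Falls back to
    ``default_power`` with a warning when none qualifies.
    """
    if not candidate_powers:
        raise ValueError("no candidate powers")
    cor = _gene_correlation(expr)
    base = (1.0 + cor) / 2.0
    np.fill_diagonal(base, 0.0)
    rows = []
    chosen = None
    for beta in candidate_powers:
        k = (base ** beta).sum(axis=1)
        hist, edges = np.histogram(k, bins=n_bins)
        centers = (edges[:-1] + edges[1:]) / 2.0
        ok = (hist > 0) & (centers > 0)
        if ok.sum() < 3:
            r2, slope = 0.0, 0.0
        else:
            lx, ly = np.log10(centers[ok]), np.log10(hist[ok])
            slope, _, r, _, _ = scipy.stats.linregress(lx, ly)
            r2 = r ** 2 if slope < 0 else 0.0
        rows.append({"power": beta, "scale_free_r2": r2, "slope": slope,
                     "mean_connectivity": float(k.mean())})
        if chosen is None and r2 >= r2_target:
            chosen = beta
    fit = pd.DataFrame(rows)
    if len(candidate_powers) == 1:
        return candidate_powers[0], fit
    if chosen is None:
        logger.warning("no candidate power reached scale-free R^2 %.2f; "
                       "falling back to %d", r2_target, default_power)
        chosen = default_power
    return chosen, fit


def topological_overlap(adj: np.ndarray) -> np.ndarray:
    """Topological overlap matrix.

    ``TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    the numerator sum over u distinct from i and j and connectivity
    ``k_i = sum_{u != i} a_iu``; diagonal set to 1.
    """
    adj = np.asarray(adj, dtype=float)
    if not np.allclose(adj, adj.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    if adj.min() < -1e-12 or adj.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    A = adj.copy()
    d = np.diag(A).copy()
    np.fill_diagonal(A, 0.0)
    k = A.sum(axis=1)
    shared = A @ A                                     # sum over all u != i,j
    num = shared + A
    den = np.minimum.outer(k, k) + 1.0 - A
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = num / den
    tom = np.where(den > 0, tom, 0.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    np.fill_diagonal(tom, 1.0)
    return tom


# ---------------------------------------------------------------------------
# Module detection
# ---------------------------------------------------------------------------

def detect_modules(tom: np.ndarray, gene_ids: list[str], min_size: int = 10,
                   cut_height_quantile: float = 0.99,
                   reassign_quantile: float = 0.9,
                   validity_ratio: float = 1.5) -> pd.Series:
    """Average-linkage clustering of 1 - TOM with a simplified dynamic
    hybrid cut.

    The tree is cut statically at the ``cut_height_quantile`` quantile of
    its merge heights. Clusters of at least ``min_size`` genes become
    modules (labeled M1, M2, ... by decreasing size, ties broken by first
    gene) provided they are cohesive: their mean internal TOM must reach
    ``validity_ratio`` times the overall mean off-diagonal TOM, which
    rejects the incidental large clusters a noise-only network produces.
    Each remaining cluster is reassigned wholesale to the module with the
    highest mean inter-cluster TOM when that similarity reaches the
    ``reassign_quantile`` quantile of the overall off-diagonal TOM;
    otherwise its genes are left unassigned ("grey"). Deterministic.
    """
    if min_size < 3:
        raise ValueError("min_size must be at least 3")
    n = len(gene_ids)
    if tom.shape != (n, n):
        raise ValueError("TOM shape does not match gene list")
    diss = 1.0 - tom
    np.fill_diagonal(diss, 0.0)
    if np.ptp(diss) == 0:
        raise ValueError("degenerate dissimilarity (all equal)")
    condensed = scipy.spatial.distance.squareform(diss, checks=False)
    Z = scipy.cluster.hierarchy.linkage(condensed, method="average")
    heights = Z[:, 2]
    cut = float(np.quantile(heights, cut_height_quantile))
    raw = scipy.cluster.hierarchy.fcluster(Z, t=cut, criterion="distance")

    clusters: dict[int, np.ndarray] = {
        c: np.flatnonzero(raw == c) for c in np.unique(raw)
    }
    off_mean = float(tom[~np.eye(n, dtype=bool)].mean())
    abs_floor = 0.15                      # strong overlap is cohesive outright

    def cohesive(idx: np.ndarray) -> bool:
        sub = tom[np.ix_(idx, idx)]
        internal = float(sub[~np.eye(len(idx), dtype=bool)].mean())
        return internal >= min(validity_ratio * off_mean, abs_floor)

    big = [c for c, idx in clusters.items()
           if len(idx) >= min_size and cohesive(idx)]
    big.sort(key=lambda c: (-len(clusters[c]), int(clusters[c][0])))
    labels = np.full(n, GREY, dtype=object)
    module_idx: dict[str, np.ndarray] = {}
    for rank, c in enumerate(big, start=1):
        name = f"M{rank}"
        labels[clusters[c]] = name
        module_idx[name] = clusters[c]

    off = tom[~np.eye(n, dtype=bool)]
    threshold = float(np.quantile(off, reassign_quantile)) if module_idx else np.inf
    for c, idx in clusters.items():
        if c in big or not module_idx:
            continue
        best_name, best_sim = None, -np.inf
        for name, midx in sorted(module_idx.items()):
            sim = float(tom[np.ix_(idx, midx)].mean())
            if sim > best_sim:
                best_name, best_sim = name, sim
        if best_sim >= threshold:
            labels[idx] = best_name
    return pd.Series(labels, index=gene_ids, name="module")


@dataclass
class CoexpressionModules:
    """Module labels, eigengenes, kME table and soft power of one network."""

    labels: pd.Series                # gene -> module (grey = unassigned)
    soft_power: int
    eigengenes: pd.DataFrame         # samples x modules, unit variance
    kme: pd.DataFrame                # genes x modules
    module_trait: pd.DataFrame = field(default_factory=pd.DataFrame)

    def module_genes(self, exclude_grey: bool = True) -> list[str]:
        mask = self.labels != GREY if exclude_grey else slice(None)
        return list(self.labels[mask].index)


def module_eigengenes(expr: ExpressionMatrix, labels: pd.Series,
                      kme_threshold: float = 0.75) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Module eigengenes, kME, and the kME-threshold final assignment.

    The eigengene of a module is the first principal component of its
    standardized expression across samples, scaled to unit variance and
    sign-oriented to correlate positively with the module's mean expression
    profile. kME is the Pearson correlation of every gene with every
    eigengene. The final assignment sends each gene to its maximum-kME
    module when that kME reaches ``kme_threshold``, otherwise to grey.
    """
    modules = sorted(m for m in labels.unique() if m != GREY)
    if not modules:
        raise ValueError("no modules to summarize")
    gidx = {g: i for i, g in enumerate(expr.gene_ids)}
    X = expr.values
    sd = X.std(axis=1, ddof=0)
    mean = X.mean(axis=1)
    eig = {}
    for m in modules:
        genes = [g for g in labels.index[labels == m]]
        if len(genes) < 3:
            raise ValueError(f"module {m} has fewer than 3 genes")
        idx = [gidx[g] for g in genes]
        Z = (X[idx] - mean[idx, None]) / np.where(sd[idx] > 0, sd[idx], 1.0)[:, None]
        u, s, vt = np.linalg.svd(Z - Z.mean(axis=1, keepdims=True), full_matrices=False)
        pc1 = vt[0]
        profile = Z.mean(axis=0)
        if np.corrcoef(pc1, profile)[0, 1] < 0:
            pc1 = -pc1
        pc1 = (pc1 - pc1.mean()) / pc1.std(ddof=0)
        eig[m] = pc1
    eigengenes = pd.DataFrame(eig, index=expr.sample_ids)

    Zall = (X - mean[:, None]) / np.where(sd > 0, sd, 1.0)[:, None]
    E = eigengenes.to_numpy()
    Ez = (E - E.mean(axis=0)) / E.std(axis=0, ddof=0)
    kme_vals = (Zall @ Ez) / expr.n_samples
    kme = pd.DataFrame(kme_vals, index=expr.gene_ids, columns=modules)

    best = kme.idxmax(axis=1)
    best_val = kme.max(axis=1)
    assigned = pd.Series(np.where(best_val >= kme_threshold, best, GREY),
                         index=expr.gene_ids, name="module")
    return eigengenes, kme, assigned


def module_trait_correlation(eigengenes: pd.DataFrame, traits: pd.DataFrame,
                             strong_r: float = 0.85) -> pd.DataFrame:
    """Pearson r and two-sided p per (module, trait); modules with
    |r| >= ``strong_r`` are flagged as strongly associated."""
    rows = []
    for m in eigengenes.columns:
        for t in traits.columns:
            tv = traits[t].to_numpy(dtype=float)
            if np.ptp(tv) == 0:
                raise ValueError(f"constant trait {t!r}")
            r, p = scipy.stats.pearsonr(eigengenes[m].to_numpy(), tv)
            rows.append({"module": m, "trait": t, "r": float(r), "p": float(p),
                         "strong": abs(r) >= strong_r})
    return pd.DataFrame(rows)


def build_modules(expr: ExpressionMatrix,
                  candidate_powers: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 10, 12, 14, 16),
                  min_size: int = 10, kme_threshold: float = 0.75,
                  cut_height_quantile: float = 0.99,
                  traits: pd.DataFrame | None = None,
                  strong_r: float = 0.85) -> CoexpressionModules:
    """End-to-end module discovery: soft power, signed adjacency, TOM,
    tree cut, eigengenes, kME assignment and optional trait correlation."""
    power, _ = pick_soft_power(expr, candidate_powers)
    adj = signed_adjacency(expr, power)
    tom = topological_overlap(adj)
    raw_labels = detect_modules(tom, expr.gene_ids, min_size=min_size,
                                cut_height_quantile=cut_height_quantile)
    if (raw_labels == GREY).all():
        return CoexpressionModules(labels=raw_labels, soft_power=power,
                                   eigengenes=pd.DataFrame(index=expr.sample_ids),
                                   kme=pd.DataFrame(index=expr.gene_ids))
    eigengenes, kme, assigned = module_eigengenes(expr, raw_labels, kme_threshold)
    mt = pd.DataFrame()
    if traits is not None:
        mt = module_trait_correlation(eigengenes, traits, strong_r)
    return CoexpressionModules(labels=assigned, soft_power=power,
                               eigengenes=eigengenes, kme=kme, module_trait=mt)
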
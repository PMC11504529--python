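"""Single-cell QC, normalization, feature selection, clustering and
marker-based annotation.

The QC contract is sequential and its order is pinned, because the removal
counts depend on it: (1) drop genes detected in fewer than 100 cells,
(2) drop cells with fewer than 300 detected features, (3) drop cells with
fewer than 500 detected features, (4) drop cells whose mitochondrial read
fraction exceeds 5% (mitochondrial genes identified by prefix). Every
removal count is reported.

Normalization is the log-normalize rule ``ln(1 + x * scale / cell_total)``
with scale factor 10,000. Highly variable genes are ranked by standardized
dispersion after a mean-variance trend fit. Clustering builds a KNN graph
on the PC embedding, reweights edges by the Jaccard similarity of neighbor
sets (shared nearest neighbors), and optimizes modularity greedily.
Clusters are annotated by the cell-type marker set with the highest mean
z-scored expression; reference-atlas classifiers are deliberately not used
so the stage stays self-contained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import networkx as nx
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass
class QCReport:
    n_cells_in: int
    n_genes_in: int
    n_removed_gene_filter: int
    n_removed_feature_300: int
    n_removed_feature_500: int
    n_removed_mito: int
    n_cells_out: int
    n_genes_out: int

    def as_dict(self) -> dict[str, int]:
        return self.__dict__.copy()


def qc_filter(counts: ExpressionMatrix, mito_prefix: str = "MT-",
              min_cells_per_gene: int = 100, min_features_create: int = 300,
              min_features_filter: int = 500,
              max_mito_fraction: float = 0.05) -> tuple[ExpressionMatrix, QCReport]:
    """Sequential QC filter with a full removal report. See module docstring
    for the pinned rule order. An empty matrix after any step is an error
    naming the step."""
    if counts.unit != "counts":
        raise ValueError("qc_filter expects unit=counts")
    X = counts.values                                 # genes x cells
    n_genes_in, n_cells_in = X.shape

    detected_cells = (X > 0).sum(axis=1)
    keep_genes = detected_cells >= min_cells_per_gene
    n_gene_removed = int((~keep_genes).sum())
    if not keep_genes.any():
        raise ValueError("no genes left after the gene-detection filter")
    X = X[keep_genes]
    genes = [g for g, k in zip(counts.gene_ids, keep_genes) if k]

    features = (X > 0).sum(axis=0)
    keep1 = features >= min_features_create
    n_feat300 = int((~keep1).sum())
    if not keep1.any():
        raise ValueError("no cells left after the 300-feature filter")
    X = X[:, keep1]
    cells = [c for c, k in zip(counts.sample_ids, keep1) if k]

    features = (X > 0).sum(axis=0)
    keep2 = features >= min_features_filter
    n_feat500 = int((~keep2).sum())
    if not keep2.any():
        raise ValueError("no cells left after the 500-feature filter")
    X = X[:, keep2]
    cells = [c for c, k in zip(cells, keep2) if k]

    mito_rows = np.array([g.startswith(mito_prefix) for g in genes])
    totals = X.sum(axis=0)
    mito_frac = (X[mito_rows].sum(axis=0) / np.where(totals > 0, totals, 1.0)
                 if mito_rows.any() else np.zeros(X.shape[1]))
    keep3 = mito_frac <= max_mito_fraction
    n_mito = int((~keep3).sum())
    if not keep3.any():
        raise ValueError("no cells left after the mitochondrial filter")
    X = X[:, keep3]
    cells = [c for c, k in zip(cells, keep3) if k]

    report = QCReport(
        n_cells_in=n_cells_in, n_genes_in=n_genes_in,
        n_removed_gene_filter=n_gene_removed,
        n_removed_feature_300=n_feat300,
        n_removed_feature_500=n_feat500,
        n_removed_mito=n_mito,
        n_cells_out=len(cells), n_genes_out=len(genes),
    )
    return ExpressionMatrix(genes, cells, X, unit="counts"), report


def log_normalize(counts: ExpressionMatrix, scale_factor: float = 10_000.0) -> ExpressionMatrix:
    """Per cell: ``x -> ln(1 + x * scale_factor / cell_total)``.

    Refuses non-count input (never silent double-normalization) and
    zero-total cells.
    """
    if counts.unit != "counts":
        raise ValueError(f"log_normalize expects unit=counts, got {counts.unit!r}")
    totals = counts.values.sum(axis=0)
    if np.any(totals == 0):
        bad = [c for c, t in zip(counts.sample_ids, totals) if t == 0]
        raise ValueError(f"zero-total cell(s): {bad[:3]}")
    vals = np.log1p(counts.values * scale_factor / totals)
    return ExpressionMatrix(list(counts.gene_ids), list(counts.sample_ids),
                            vals, unit="lognorm")


def select_hvg(lognorm: ExpressionMatrix, n: int = 2000) -> list[str]:
    """Top-n genes by standardized dispersion.

    Per-gene variance is divided by a mean-variance trend — a linear fit of
    log variance on log mean, iteratively refit after discarding the genes
    with the largest positive residuals so that genuinely hypervariable
    genes do not drag the trend toward themselves. Genes are ranked by the
    resulting standardized dispersion, descending, ties broken by gene id.
    """
    if n > lognorm.n_genes:
        raise ValueError("n exceeds the number of genes")
    mean = lognorm.values.mean(axis=1)
    var = lognorm.values.var(axis=1, ddof=1)
    ok = (mean > 0) & (var > 0)
    disp = np.zeros(lognorm.n_genes)
    if ok.sum() >= 5:
        lm = np.log10(mean[ok])
        lv = np.log10(var[ok])
        X = np.column_stack([np.ones_like(lm), lm])
        keep = np.ones(len(lm), dtype=bool)
        coef = np.zeros(2)
        for _ in range(3):
            coef, *_ = np.linalg.lstsq(X[keep], lv[keep], rcond=None)
            resid = lv - X @ coef
            new_keep = resid <= np.quantile(resid[keep], 0.9)
            if new_keep.sum() < 5 or new_keep.sum() == keep.sum():
                break
            keep = new_keep
        trend = X @ coef
        disp[ok] = var[ok] / (10.0 ** trend)
    else:
        disp[ok] = var[ok]
    order = sorted(range(lognorm.n_genes),
                   key=lambda i: (-disp[i], lognorm.gene_ids[i]))
    return [lognorm.gene_ids[i] for i in order[:n]]


def embed_cells(lognorm: ExpressionMatrix, hvg: list[str], n_pcs: int = 10,
                clip: float = 10.0, select_pcs: bool = False,
                n_permutations: int = 20, perm_gene_fraction: float = 0.1,
                seed: int | np.random.Generator = 0) -> tuple[pd.DataFrame, np.ndarray]:
    """Z-score the HVGs (clipped at +/- ``clip``), run PCA over cells, and
    optionally retain only the PCs whose explained variance exceeds the
    permutation null (a JackStraw-style check permuting a fraction of genes).

    Returns (cell x PC coordinates, variance fractions of the kept PCs).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sub = lognorm.subset_genes(hvg)
    if n_pcs >= min(sub.n_samples, sub.n_genes):
        raise ValueError("n_pcs must be below min(n_cells, n_hvg)")
    X = sub.values.T                                   # cells x genes
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = np.clip((X - mu) / sd, -clip, clip)
    pca = PCA(n_components=n_pcs, svd_solver="full")
    coords = pca.fit_transform(Z)
    var_frac = pca.explained_variance_ratio_
    if select_pcs:
        n_perm_genes = max(1, int(perm_gene_fraction * Z.shape[1]))
        null_max = np.zeros(n_permutations)
        for b in range(n_permutations):
            Zp = Z.copy()
            cols = rng.choice(Z.shape[1], size=n_perm_genes, replace=False)
            for c in cols:
                Zp[:, c] = rng.permutation(Zp[:, c])
            pp = PCA(n_components=n_pcs, svd_solver="full").fit(Zp)
            null_max[b] = pp.explained_variance_ratio_[n_pcs - 1]
        keep = var_frac > np.quantile(null_max, 0.95)
        k = max(2, int(keep.sum()))
        coords = coords[:, :k]
        var_frac = var_frac[:k]
    cols = [f"PC{i+1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=sub.sample_ids, columns=cols), var_frac


def snn_graph(embedding: pd.DataFrame, k_neighbors: int = 20,
              prune: float = 1.0 / 15.0) -> nx.Graph:
    """KNN graph with shared-nearest-neighbor (Jaccard) edge weights."""
    n = len(embedding)
    if k_neighbors >= n:
        raise ValueError("k_neighbors must be below the number of cells")
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(embedding.to_numpy())
    _, idx = nn.kneighbors(embedding.to_numpy())
    neigh = [set(row) for row in idx]                 # includes self
    G = nx.Graph()
    G.add_nodes_from(range(n))
    for i in range(n):
        for j in idx[i]:
            j = int(j)
            if j <= i:
                continue
            inter = len(neigh[i] & neigh[j])
            union = len(neigh[i] | neigh[j])
            w = inter / union
            if w >= prune:
                G.add_edge(i, j, weight=w)
    return G


def cluster_cells(embedding: pd.DataFrame, k_neighbors: int = 20,
                  resolution: float = 1.0) -> pd.Series:
    """SNN clustering: greedy modularity communities on the Jaccard-weighted
    KNN graph. Deterministic; cluster ids ordered by decreasing size."""
    if len(embedding) < 3:
        raise ValueError("need at least 3 cells")
    G = snn_graph(embedding, k_neighbors=k_neighbors)
    comms = nx.community.greedy_modularity_communities(
        G, weight="weight", resolution=resolution)
    comms = sorted((sorted(c) for c in comms), key=lambda c: (-len(c), c[0]))
    labels = np.zeros(len(embedding), dtype=int)
    for cid, members in enumerate(comms):
        labels[list(members)] = cid
    return pd.Series(labels, index=embedding.index, name="cluster")


@dataclass
class CellAnnotation:
    """Cluster membership, per-cluster cell-type labels and marker tables."""

    clusters: pd.Series               # cell -> cluster id
    cluster_labels: dict[int, str]    # cluster id -> cell-type label
    margins: dict[int, float]         # top-1 minus top-2 marker score
    uncertain: set[int]
    markers: dict[int, pd.DataFrame] | None = None

    def cell_types(self) -> pd.Series:
        return self.clusters.map(self.cluster_labels)


def annotate_clusters(lognorm: ExpressionMatrix, clusters: pd.Series,
                      marker_sets: GeneSetCollection,
                      margin_threshold: float = 0.1) -> CellAnnotation:
    """Label each cluster by the marker set with the highest mean z-scored
    expression; ties break lexicographically and are flagged uncertain,
    as are labels won by less than ``margin_threshold``."""
    if not marker_sets.sets:
        raise ValueError("empty marker collection")
    gidx = {g: i for i, g in enumerate(lognorm.gene_ids)}
    X = lognorm.values
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    Z = (X - mu) / np.where(sd > 0, sd, 1.0)
    set_rows = {}
    for name, genes in marker_sets.sets.items():
        rows = [gidx[g] for g in genes if g in gidx]
        if not rows:
            raise ValueError(f"marker set {name!r} has no genes in the matrix")
        set_rows[name] = np.array(rows)
    cidx = {c: i for i, c in enumerate(lognorm.sample_ids)}
    labels: dict[int, str] = {}
    margins: dict[int, float] = {}
    uncertain: set[int] = set()
    for cl in sorted(clusters.unique()):
        cols = np.array([cidx[c] for c in clusters.index[clusters == cl]])
        scores = {name: float(Z[np.ix_(rows, cols)].mean())
                  for name, rows in sorted(set_rows.items())}
        ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        labels[cl] = ranked[0][0]
        margin = ranked[0][1] - ranked[1][1] if len(ranked) > 1 else np.inf
        margins[cl] = margin
        if margin < margin_threshold:
            uncertain.add(cl)
    return CellAnnotation(clusters=clusters, cluster_labels=labels,
                          margins=margins, uncertain=uncertain)


def cluster_markers(lognorm: ExpressionMatrix, clusters: pd.Series,
                    eps: float = 1e-9) -> dict[int, pd.DataFrame]:
    """One-vs-rest Wilcoxon rank-sum marker test per cluster with BH
    adjustment within the cluster and log2 fold change of mean expression."""
    cidx = {c: i for i, c in enumerate(lognorm.sample_ids)}
    X = lognorm.values
    out: dict[int, pd.DataFrame] = {}
    for cl in sorted(clusters.unique()):
        inside = np.array([cidx[c] for c in clusters.index[clusters == cl]])
        outside = np.array([cidx[c] for c in clusters.index[clusters != cl]])
        if len(inside) < 3:
            raise ValueError(f"cluster {cl} has fewer than 3 cells")
        a = X[:, inside]
        b = X[:, outside]
        stat, p = scipy.stats.mannwhitneyu(a, b, axis=1, alternative="two-sided")
        mean_in = a.mean(axis=1)
        mean_out = b.mean(axis=1)
        log2fc = np.log2((mean_in + eps) / (mean_out + eps))
        padj = multipletests(p, method="fdr_bh")[1]
        df = pd.DataFrame({"gene": lognorm.gene_ids, "log2fc": log2fc,
                           "p": p, "p_adj": padj})
        out[cl] = df.sort_values(["p_adj", "p", "gene"]).reset_index(drop=True)
    return out
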
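"""Signature-based immune-cell deconvolution of bulk expression.

Per sample, relative cell-type proportions are estimated by nonnegative
least squares of the sample's signature-gene vector against the signature
columns, renormalized to sum to one. This is a deliberate, deterministic
replacement for the nu-SVR used by CIBERSORT: the downstream analysis only
consumes relative proportions, ranks and group comparisons, for which the
constrained least-squares solution is sufficient and fully reproducible.

A per-sample permutation p-value (gene labels of the sample shuffled,
statistic = relative residual-norm improvement over the null) flags samples
whose mixture fit is no better than chance, mirroring the p < 0.05 sample
filter applied by CIBERSORT users.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix


@dataclass
class SignatureMatrix:
    """Gene-by-cell-type matrix of nonnegative mean expression profiles."""

    gene_ids: list[str]
    celltype_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.celltype_ids)):
            raise ValueError("signature shape mismatch")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate signature genes")
        if np.any(self.values < 0):
            raise ValueError("negative signature values")
        if np.any(self.values.sum(axis=0) == 0):
            raise ValueError("all-zero signature column")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SignatureMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.celltype_ids)


@dataclass
class CellFractions:
    """Sample-by-cell-type relative proportions with per-sample fit stats."""

    fractions: pd.DataFrame          # rows sum to 1, nonnegative
    fit_stats: pd.DataFrame          # residual_norm, p_value, flagged

    def __post_init__(self) -> None:
        vals = self.fractions.to_numpy()
        if np.any(vals < -1e-12):
            raise ValueError("negative fraction")
        if np.max(np.abs(vals.sum(axis=1) - 1.0)) > 1e-9:
            raise ValueError("fractions do not sum to 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.fractions.index)

    @property
    def celltype_ids(self) -> list[str]:
        return list(self.fractions.columns)


def _cpm(values: np.ndarray) -> np.ndarray:
    totals = values.sum(axis=0)
    if np.any(totals == 0):
        raise ValueError("zero-total sample cannot be scaled to CPM")
    return values / totals * 1e6


def estimate_fractions(expr: ExpressionMatrix, sig: SignatureMatrix,
                       n_perm: int = 100, p_cutoff: float = 0.05,
                       seed: int | np.random.Generator = 0) -> CellFractions:
    """Nonnegative least-squares deconvolution with permutation fit p-values.

    Requires at least 50% of the signature genes to be present in ``expr``.
    Counts input is scaled to CPM internally. The permutation p-value is
    ``(1 + #better) / (1 + n_perm)`` where "better" means a permuted gene
    vector achieving at least the observed relative residual improvement
    ``1 - ||r|| / ||y||``. Samples with p >= ``p_cutoff`` are flagged.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shared = [g for g in sig.gene_ids if g in set(expr.gene_ids)]
    if len(shared) < 0.5 * len(sig.gene_ids):
        raise ValueError(
            f"only {len(shared)}/{len(sig.gene_ids)} signature genes present "
            "in the expression matrix (need at least 50%)")
    S = sig.to_frame().loc[shared].to_numpy()
    if np.linalg.matrix_rank(S) < S.shape[1]:
        raise ValueError("rank-deficient signature on the shared gene set")
    values = expr.values
    if expr.unit == "counts":
        values = _cpm(values)
    elif expr.unit == "lognorm":
        raise ValueError("deconvolution expects linear-scale expression")
    gidx = {g: i for i, g in enumerate(expr.gene_ids)}
    Y = values[[gidx[g] for g in shared], :]

    n_ct = len(sig.celltype_ids)
    fracs = np.zeros((expr.n_samples, n_ct))
    resid = np.zeros(expr.n_samples)
    pvals = np.ones(expr.n_samples)
    for j in range(expr.n_samples):
        y = Y[:, j]
        coef, rnorm = scipy.optimize.nnls(S, y)
        total = coef.sum()
        fracs[j] = coef / total if total > 0 else np.full(n_ct, 1.0 / n_ct)
        resid[j] = rnorm
        ynorm = np.linalg.norm(y)
        stat = 1.0 - rnorm / ynorm if ynorm > 0 else 0.0
        better = 0
        for _ in range(n_perm):
            yp = rng.permutation(y)
            _, rp = scipy.optimize.nnls(S, yp)
            if 1.0 - rp / ynorm >= stat:
                better += 1
        pvals[j] = (1.0 + better) / (1.0 + n_perm)

    fractions = pd.DataFrame(fracs, index=expr.sample_ids, columns=sig.celltype_ids)
    fit_stats = pd.DataFrame({
        "residual_norm": resid,
        "p_value": pvals,
        "flagged": pvals >= p_cutoff,
    }, index=expr.sample_ids)
    return CellFractions(fractions, fit_stats)


def compare_fraction_groups(fr: CellFractions, states: pd.Series) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum test per cell type, tumor vs control,
    with Benjamini-Hochberg adjustment across cell types."""
    states = states.reindex(fr.sample_ids)
    tumor = fr.fractions.loc[states == "tumor"]
    control = fr.fractions.loc[states == "control"]
    if len(tumor) < 3 or len(control) < 3:
        raise ValueError("need at least 3 samples per group")
    rows = []
    for ct in fr.celltype_ids:
        res = scipy.stats.mannwhitneyu(tumor[ct], control[ct], alternative="two-sided")
        direction = "up" if tumor[ct].median() > control[ct].median() else "down"
        rows.append({"celltype": ct, "p_wilcoxon": res.pvalue, "direction": direction})
    out = pd.DataFrame(rows)
    out["p_adj_BH"] = multipletests(out["p_wilcoxon"], method="fdr_bh")[1]
    return out[["celltype", "p_wilcoxon", "p_adj_BH", "direction"]]


def rank_abundance(fr: CellFractions, subset: list[str] | None = None) -> pd.DataFrame:
    """Cell types ordered by descending median fraction over ``subset``
    (default: all samples); ties broken lexicographically by cell type."""
    ids = list(subset) if subset is not None else fr.sample_ids
    if not ids:
        raise ValueError("empty sample subset")
    missing = set(ids) - set(fr.sample_ids)
    if missing:
        raise ValueError(f"unknown sample id(s): {sorted(missing)[:3]}")
    med = fr.fractions.loc[ids].median(axis=0)
    order = sorted(med.index, key=lambda ct: (-med[ct], ct))
    return pd.DataFrame({"celltype": order,
                         "median_fraction": [med[ct] for ct in order]})


def _exact_spearman_p(xr: np.ndarray, yr: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p-value for Spearman's rho (n <= 9)."""
    n = len(xr)
    xc = xr - xr.mean()
    denom = np.sqrt((xc ** 2).sum())
    count = 0
    total = 0
    abs_obs = abs(rho_obs) - 1e-12
    for perm in itertools.permutations(range(n)):
        yp = yr[list(perm)]
        yc = yp - yp.mean()
        d = denom * np.sqrt((yc ** 2).sum())
        rho = (xc * yc).sum() / d if d > 0 else 0.0
        if abs(rho) >= abs_obs:
            count += 1
        total += 1
    return count / total


def spearman_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with midranks; exact permutation p for n <= 9, otherwise
    the t approximation with n-2 degrees of freedom. Returns (nan, nan) for
    a constant input vector."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    xr = scipy.stats.rankdata(x)
    yr = scipy.stats.rankdata(y)
    rho = float(np.corrcoef(xr, yr)[0, 1])
    n = len(x)
    if n <= 9:
        return rho, _exact_spearman_p(xr, yr, rho)
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * scipy.stats.t.sf(abs(t), df=n - 2)
    return rho, float(min(p, 1.0))


def gene_infiltration_correlation(expr: ExpressionMatrix, fr: CellFractions,
                                  genes: list[str] | None = None) -> pd.DataFrame:
    """Spearman correlation of each gene's expression with each cell type's
    estimated infiltration level across shared samples."""
    shared = [s for s in expr.sample_ids if s in set(fr.sample_ids)]
    if not shared:
        raise ValueError("no shared samples")
    sub = expr.subset_samples(shared)
    fracs = fr.fractions.loc[shared]
    genes = genes if genes is not None else sub.gene_ids
    gidx = {g: i for i, g in enumerate(sub.gene_ids)}
    rows = []
    for g in genes:
        gv = sub.values[gidx[g]]
        for ct in fr.celltype_ids:
            rho, p = spearman_with_p(gv, fracs[ct].to_numpy())
            rows.append({"gene": g, "celltype": ct, "spearman_rho": rho, "p": p})
    return pd.DataFrame(rows)
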
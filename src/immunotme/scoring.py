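"""Single-sample gene-set activity scores.

The ssGSEA score of a set in a sample is a weighted Kolmogorov-Smirnov-like
running sum over the sample's expression-ranked gene list: walking the genes
from highest to lowest expression, the score accumulates the difference
between the in-set cumulative distribution (weighted by rank^alpha,
normalized to 1 over the set) and the uniform out-of-set cumulative
distribution. Ties receive midranks. Scores depend on a sample's expression
only through its within-sample ranks.

StromalScore / ImmuneScore are unnormalized ssGSEA scores of two dedicated
sets; their sum is the composite microenvironment (ESTIMATE-style) score.
The tumor-purity calibration polynomial of the original ESTIMATE tool is
intentionally out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .io import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass
class ActivityScore:
    """Sample-by-set enrichment scores with the weighting exponent used."""

    scores: pd.DataFrame             # samples x sets
    alpha: float
    normalized: bool

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def set_names(self) -> list[str]:
        return list(self.scores.columns)


def _sample_ranks(values: np.ndarray) -> np.ndarray:
    """Within-sample ranks, highest expression -> rank n_genes (midranks)."""
    return np.apply_along_axis(scipy.stats.rankdata, 0, values)


def ssgsea_score(expr: ExpressionMatrix, sets: GeneSetCollection,
                 alpha: float = 0.25, normalize: bool = True,
                 min_genes: int = 2) -> ActivityScore:
    """ssGSEA enrichment score per sample and gene set.

    Sets with fewer than ``min_genes`` genes present in ``expr`` are skipped
    with a warning; an empty overlap across all sets is an error. With
    ``normalize``, the full score matrix is divided by its range so all
    scores lie in an interval of width 1.
    """
    gidx = {g: i for i, g in enumerate(expr.gene_ids)}
    n_genes = expr.n_genes
    ranks = _sample_ranks(expr.values)               # genes x samples
    order = np.argsort(-expr.values, axis=0, kind="stable")  # descending walk

    kept: list[str] = []
    cols: list[np.ndarray] = []
    for name, genes in sets.sets.items():
        members = [gidx[g] for g in genes if g in gidx]
        if len(members) < min_genes:
            logger.warning("set %r: only %d gene(s) matched, skipped", name, len(members))
            continue
        in_set = np.zeros(n_genes, dtype=bool)
        in_set[members] = True
        n_out = n_genes - len(members)
        scores = np.empty(expr.n_samples)
        for j in range(expr.n_samples):
            walk = order[:, j]
            in_walk = in_set[walk]
            w = np.where(in_walk, ranks[walk, j] ** alpha, 0.0)
            p_in = np.cumsum(w)
            p_in /= p_in[-1]
            if n_out:
                p_out = np.cumsum(~in_walk) / n_out
            else:
                p_out = np.zeros(n_genes)
            scores[j] = float(np.sum(p_in - p_out))
        kept.append(name)
        cols.append(scores)
    if not kept:
        raise ValueError("no gene set had sufficient overlap with the expression matrix")
    mat = np.column_stack(cols)
    if normalize:
        rng_ = mat.max() - mat.min()
        if rng_ > 0:
            mat = mat / rng_
    return ActivityScore(pd.DataFrame(mat, index=expr.sample_ids, columns=kept),
                         alpha=alpha, normalized=normalize)


def estimate_scores(expr: ExpressionMatrix, stromal_set: list[str],
                    immune_set: list[str], alpha: float = 0.25) -> pd.DataFrame:
    """StromalScore, ImmuneScore (unnormalized ssGSEA) and their sum."""
    coll = GeneSetCollection({"stromal": list(stromal_set), "immune": list(immune_set)})
    act = ssgsea_score(expr, coll, alpha=alpha, normalize=False)
    missing = {"stromal", "immune"} - set(act.set_names)
    if missing:
        raise ValueError(f"gene set(s) {sorted(missing)} not represented in expression")
    out = pd.DataFrame({
        "StromalScore": act.scores["stromal"],
        "ImmuneScore": act.scores["immune"],
    })
    out["ESTIMATEScore"] = out["StromalScore"] + out["ImmuneScore"]
    out.index.name = "sample_id"
    return out


def composite_immunoactivity(act: ActivityScore,
                             set_subset: list[str] | None = None) -> pd.Series:
    """Per-sample composite immunoactivity: the mean of z-scored set scores.

    Zero-variance set columns are dropped with a warning. Higher values mean
    a more immunocompetent sample.
    """
    names = list(set_subset) if set_subset is not None else act.set_names
    if not names:
        raise ValueError("empty set subset")
    missing = set(names) - set(act.set_names)
    if missing:
        raise ValueError(f"unknown set name(s): {sorted(missing)[:3]}")
    cols = []
    for name in names:
        col = act.scores[name].to_numpy(dtype=float)
        sd = col.std(ddof=0)
        if sd == 0:
            logger.warning("set %r has zero score variance, dropped from composite", name)
            continue
        cols.append((col - col.mean()) / sd)
    if not cols:
        raise ValueError("all selected sets have zero variance")
    comp = np.mean(np.column_stack(cols), axis=1)
    return pd.Series(comp, index=act.sample_ids, name="immunoactivity")
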
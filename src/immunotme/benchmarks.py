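"""Planted-truth recovery experiments.

Each function runs one self-contained study at stated conditions —
generate synthetic data with a known truth, run the corresponding pipeline
stage, measure recovery — and returns a small dict of summary numbers.
They back both the acceptance test suite and the reproduction script.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import scipy.stats

from . import coexpression as cx
from . import deconvolution as dc
from . import immunoactivity as ia
from . import linkage
from . import single_cell as sc
from . import survival as surv
from . import synthetic
from .config import RunConfig
from .io import ClinicalTable, GeneSetCollection
from .pipeline import run_pipeline


# ---------------------------------------------------------------------------
# Deconvolution recovery
# ---------------------------------------------------------------------------

def deconvolution_recovery(seed: int = 0, n_samples: int = 40,
                           n_celltypes: int = 6, noise_sd: float = 0.1,
                           n_perm: int = 100) -> dict:
    """Fraction recovery on a noisy synthetic cohort plus the noiseless
    exact-mixture check."""
    rng = np.random.default_rng(seed)
    expr, truth, _ = synthetic.generate_bulk_cohort(
        n_samples=n_samples, n_genes=720, n_celltypes=n_celltypes,
        noise_sd=noise_sd, seed=rng)
    sig = dc.SignatureMatrix.from_frame(truth.signature)
    fr = dc.estimate_fractions(expr, sig, n_perm=n_perm, seed=rng)
    rs = [np.corrcoef(fr.fractions.iloc[i], truth.fractions.iloc[i])[0, 1]
          for i in range(n_samples)]

    w = rng.dirichlet(np.ones(n_celltypes))
    mix = truth.signature.to_numpy() @ w
    from .io import ExpressionMatrix
    e1 = ExpressionMatrix(list(truth.signature.index), ["mix"], mix[:, None])
    f1 = dc.estimate_fractions(e1, sig, n_perm=10, seed=rng)
    exact_err = float(np.max(np.abs(f1.fractions.iloc[0].to_numpy() - w)))
    return {"mean_pearson_r": float(np.mean(rs)),
            "exact_mixture_max_abs_error": exact_err,
            "n": n_samples}


# ---------------------------------------------------------------------------
# Slope-change recovery
# ---------------------------------------------------------------------------

def delta_k_recovery(seed: int = 0, n_replicates: int = 500,
                     boot_reps: int = 200) -> dict:
    """Monte-Carlo recovery of a planted slope change of 0.6
    (k_control = 0.2, k_tumor = 0.8, sigma = 0.05, n = 30 per state),
    with bootstrap-interval coverage at nominal 95%."""
    rng = np.random.default_rng(seed)
    truth = synthetic.TwoStateTruth(k_control=0.2, k_tumor=0.8, sigma=0.05,
                                    n_control=30, n_tumor=30)
    target = truth.k_tumor - truth.k_control
    deltas, calls, covered = [], 0, 0
    for _ in range(n_replicates):
        tbl = synthetic.generate_two_state(truth, seed=rng)
        t = tbl[tbl.state == "tumor"]
        c = tbl[tbl.state == "control"]
        res = ia.delta_k((t.x.to_numpy(), t.y.to_numpy()),
                         (c.x.to_numpy(), c.y.to_numpy()),
                         boot_reps=boot_reps, seed=rng)
        deltas.append(res.delta_k)
        calls += res.call == "enhanced"
        covered += res.ci[0] <= target <= res.ci[1]
    return {"mean_delta_k": float(np.mean(deltas)),
            "target": target,
            "call_accuracy": calls / n_replicates,
            "ci_coverage": covered / n_replicates,
            "n": n_replicates}


# ---------------------------------------------------------------------------
# Exact 1-D partition optimality
# ---------------------------------------------------------------------------

def _brute_force_wss(x_sorted: np.ndarray, k: int = 3) -> float:
    best = np.inf
    n = len(x_sorted)
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = [0, *cuts, n]
        wss = 0.0
        for a, b in zip(bounds[:-1], bounds[1:]):
            seg = x_sorted[a:b]
            wss += float(((seg - seg.mean()) ** 2).sum())
        best = min(best, wss)
    return best


def partition_optimality(seed: int = 0, n_instances: int = 1000) -> dict:
    """Dynamic program vs exhaustive contiguous-partition search for
    random instances with n <= 12."""
    rng = np.random.default_rng(seed)
    matches = 0
    tried = 0
    while tried < n_instances:
        n = int(rng.integers(3, 13))
        x = np.sort(rng.normal(size=n))
        if len(np.unique(x)) < 3:
            continue
        tried += 1
        res = ia.partition_by_activity(pd.Series(x, index=range(n)))
        matches += abs(res.wss - _brute_force_wss(x)) < 1e-10
    return {"optimal_rate": matches / n_instances, "n": n_instances}


# ---------------------------------------------------------------------------
# Module recovery
# ---------------------------------------------------------------------------

def module_recovery(seed: int = 0, n_null_seeds: int = 20) -> dict:
    """Adjusted Rand index against three planted 50-gene blocks at
    within-block correlation 0.9 (200 samples), plus the null rate (no
    module detected when within_cor = 0)."""
    from sklearn.metrics import adjusted_rand_score
    expr, labels, _ = synthetic.generate_module_blocks(
        200, [50, 50, 50], within_cor=0.9, n_samples=200, seed=seed)
    mods = cx.build_modules(expr, min_size=10)
    ari = adjusted_rand_score(labels, pd.factorize(mods.labels.to_numpy())[0])
    clean = 0
    for s in range(n_null_seeds):
        e0, _, _ = synthetic.generate_module_blocks(
            200, [50, 50, 50], within_cor=0.0, n_samples=200,
            seed=seed + 1000 + s)
        m0 = cx.build_modules(e0, min_size=10)
        clean += len(m0.eigengenes.columns) == 0
    return {"ari": float(ari), "null_clean_rate": clean / n_null_seeds,
            "n": 200}


# ---------------------------------------------------------------------------
# Cox recovery
# ---------------------------------------------------------------------------

def cox_recovery(seed: int = 0, n: int = 500, n_null: int = 200) -> dict:
    """Planted hazard ratio 2 with ~20% censoring, plus null p-value
    uniformity over replicates."""
    rng = np.random.default_rng(seed)
    x = (rng.uniform(size=n) < 0.5).astype(float)
    tte = rng.exponential(scale=1.0 / np.exp(np.log(2.0) * x))
    cens = rng.exponential(scale=4.0, size=n)
    time = np.minimum(tte, cens)
    event = (tte <= cens).astype(float)
    clin = ClinicalTable(pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)], "state": "tumor",
        "time": np.maximum(time, 1e-9), "event": event}))
    cov = pd.DataFrame({"x": x}, index=clin.sample_ids)
    fit = surv.fit_cox(clin, cov)

    null_ps = []
    for _ in range(n_null):
        m = 100
        xn = rng.normal(size=m)
        tn = rng.exponential(size=m)
        cn = ClinicalTable(pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(m)], "state": "tumor",
            "time": tn, "event": np.ones(m)}))
        fn = surv.fit_cox(cn, pd.DataFrame({"x": xn}, index=cn.sample_ids))
        null_ps.append(fn.p["x"])
    ks = scipy.stats.kstest(null_ps, "uniform")
    return {"coef": float(fit.coef["x"]),
            "abs_error_vs_log2": float(abs(fit.coef["x"] - np.log(2.0))),
            "censoring_fraction": float(1.0 - event.mean()),
            "null_ks_p": float(ks.pvalue), "n": n}


# ---------------------------------------------------------------------------
# Time-dependent ROC
# ---------------------------------------------------------------------------

def roc_checks(seed: int = 0, n_null: int = 100) -> dict:
    """No-censoring reduction to the binary AUC, and the null AUC mean."""
    from sklearn.metrics import roc_auc_score
    rng = np.random.default_rng(seed)
    n = 200
    time = rng.exponential(size=n)
    m = -time + rng.normal(0, 0.5, size=n)
    clin = ClinicalTable(pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)], "state": "tumor",
        "time": time, "event": np.ones(n)}))
    horizon = float(np.median(time))
    roc = surv.time_dependent_roc(pd.Series(m, index=clin.sample_ids),
                                  clin, horizon)
    y = (time <= horizon).astype(int)
    reduction_diff = abs(roc["auc"] - roc_auc_score(y, m))

    aucs = []
    for _ in range(n_null):
        k = 100
        t = rng.exponential(size=k)
        risk = rng.normal(size=k)
        c = ClinicalTable(pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(k)], "state": "tumor",
            "time": t, "event": np.ones(k)}))
        r = surv.time_dependent_roc(pd.Series(risk, index=c.sample_ids),
                                    c, float(np.median(t)))
        aucs.append(r["auc"])
    return {"reduction_abs_diff": float(reduction_diff),
            "null_auc_mean": float(np.mean(aucs)), "n": n_null}


# ---------------------------------------------------------------------------
# QC exactness
# ---------------------------------------------------------------------------

def qc_exactness(seed: int = 0) -> dict:
    """Filter-report counts vs construction on an engineered fixture."""
    bulk, truth, _ = synthetic.generate_bulk_cohort(
        n_samples=20, n_genes=700, n_celltypes=6, noise_sd=0.1, seed=seed)
    types = [c for c in truth.signature.columns if c != truth.risk_celltype][:3]
    ms = GeneSetCollection({ct: truth.marker_genes[ct] for ct in types})
    counts, sct = synthetic.generate_single_cells(
        {ct: 120 for ct in types}, ms, bulk=bulk, bulk_risk=truth.risk_coef,
        planted_type=types[0], n_planted=30,
        shift_genes=truth.marker_genes[types[0]][:8], shift_size=1.0,
        seed=seed + 1)
    _, report = sc.qc_filter(counts)
    mismatches = sum(report.as_dict()[k] != v
                     for k, v in sct.expected_qc.items())
    return {"mismatch_count": int(mismatches),
            "n_cells_out": report.n_cells_out,
            "n": report.n_cells_in}


# ---------------------------------------------------------------------------
# Phenotype-linked cell recovery
# ---------------------------------------------------------------------------

def linkage_recovery_one(seed: int, n_samples: int = 60,
                         n_cells_per_type: int = 250,
                         n_planted: int = 80) -> dict:
    """One seed of the planted-subpopulation selection study."""
    cfg = RunConfig(seed=seed)
    rngs = cfg.spawn_rngs(4)
    bulk, truth, clin = synthetic.generate_bulk_cohort(
        n_samples=n_samples, n_genes=720, n_celltypes=6, noise_sd=0.1,
        seed=rngs[0])
    types = [c for c in truth.signature.columns if c != truth.risk_celltype][:3]
    ms = GeneSetCollection({ct: truth.marker_genes[ct] for ct in types})
    counts, sct = synthetic.generate_single_cells(
        {ct: n_cells_per_type for ct in types}, ms, bulk=bulk,
        bulk_risk=truth.risk_coef, planted_type=types[0],
        n_planted=n_planted, shift_genes=truth.marker_genes[types[0]][:10],
        shift_size=1.0, seed=rngs[1])
    filtered, _ = sc.qc_filter(counts)
    lognorm = sc.log_normalize(filtered)
    hvg = sc.select_hvg(lognorm, n=lognorm.n_genes)
    emb, _ = sc.embed_cells(lognorm, hvg, n_pcs=10, seed=rngs[2])
    corr = linkage.cell_bulk_correlation(lognorm, bulk)
    L = linkage.build_cell_graph(emb, k_neighbors=10)
    lam, _ = linkage.select_lambda_cv(corr.S, clin, L=L, seed=rngs[3],
                                      n_lambdas=8, n_folds=4, max_iter=300)
    fit = linkage.penalized_cox_select(corr.S, clin, lam, alpha_mix=0.05,
                                       L=L, max_iter=2000)
    classes = fit.classes()
    plus = set(classes.index[classes == "plus"])
    planted = set(sct.planted_subpop)
    precision = len(plus & planted) / len(plus) if plus else 0.0
    recall = len(plus & planted) / len(planted)
    monotone = bool(np.all(np.diff(fit.objective_path) <= 1e-9))
    return {"precision": precision, "recall": recall, "lambda": lam,
            "objective_monotone": monotone, "n_plus": len(plus),
            "S": corr.S, "clin": clin, "L": L}


def linkage_recovery(seed: int = 0, n_seeds: int = 20) -> dict:
    """Mean precision/recall over seeds, monotone-objective check, and the
    nonzero-count monotonicity along a 10-point lambda path."""
    precisions, recalls = [], []
    monotone_all = True
    keep = None
    for s in range(n_seeds):
        out = linkage_recovery_one(seed * 10_000 + s)
        precisions.append(out["precision"])
        recalls.append(out["recall"])
        monotone_all &= out["objective_monotone"]
        if keep is None:
            keep = out
    lams = np.sort(linkage.lambda_path(keep["S"], keep["clin"],
                                       alpha_mix=0.05, n_lambdas=10))
    counts = []
    for lam in lams:                                   # ascending lambda
        f = linkage.penalized_cox_select(keep["S"], keep["clin"], lam,
                                         alpha_mix=0.05, L=keep["L"],
                                         tol=1e-5, max_iter=500)
        counts.append(int((f.beta != 0).sum()))
    path_monotone = all(a >= b for a, b in zip(counts, counts[1:]))
    return {"mean_precision": float(np.mean(precisions)),
            "mean_recall": float(np.mean(recalls)),
            "objective_monotone": monotone_all,
            "lambda_path_monotone": path_monotone,
            "n": n_seeds}


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

def pipeline_reproducibility(seed: int = 0) -> dict:
    """Run the full pipeline twice from one seed: bit-identical outputs and
    planted shift-gene recovery through the module intersection."""
    a = run_pipeline(RunConfig(seed=seed))
    b = run_pipeline(RunConfig(seed=seed))
    identical = (
        np.array_equal(a.bulk.values, b.bulk.values)
        and a.scores.beta.equals(b.scores.beta)
        and a.modules.labels.equals(b.modules.labels)
        and a.delta_k.equals(b.delta_k)
        and a.intersection_table.equals(b.intersection_table)
    )
    return {"bit_identical": bool(identical),
            "shift_gene_recovery": a.shift_gene_recovery,
            "n": a.bulk.n_samples,
            "result": a}
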
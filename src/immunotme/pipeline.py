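"""End-to-end orchestration on a synthetic cohort with planted truth.

``run_pipeline`` chains every stage — simulate, deconvolve, score, group,
slope-change, differential expression, co-expression modules, survival,
single-cell processing, and phenotype linkage — from a single
:class:`~immunotme.config.RunConfig` seed, so a fixed seed yields
bit-identical results end to end. The planted single-cell shift genes are
drawn from the marker program of one immune cell type, which the bulk arm
recovers as a co-expression module; the final Table-style intersection of
subpopulation signature genes with module genes therefore has a known
expected content, making the whole pipeline testable without any external
download.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coexpression, deconvolution, immunoactivity, linkage, scoring, single_cell
from . import survival as surv
from .config import RunConfig
from .io import ClinicalTable, ExpressionMatrix, GeneSetCollection
from .synthetic import BulkTruth, SingleCellTruth, celltype_gene_sets, \
    generate_bulk_cohort, generate_single_cells


def bulk_counts_from_expression(expr: ExpressionMatrix, depth: float = 30.0,
                                rng: np.random.Generator | None = None) -> ExpressionMatrix:
    """Poisson read counts around the normalized expression surface
    (mean = expression * depth): the count-scale view of a simulated cohort."""
    rng = rng if rng is not None else np.random.default_rng(0)
    counts = rng.poisson(expr.values * depth).astype(float)
    return ExpressionMatrix(list(expr.gene_ids), list(expr.sample_ids),
                            counts, unit="counts")


@dataclass
class PipelineResult:
    """Everything the pipeline produced, plus planted-truth bookkeeping."""

    config: RunConfig
    bulk: ExpressionMatrix
    bulk_truth: BulkTruth
    clinical: ClinicalTable
    fractions: deconvolution.CellFractions
    activity: scoring.ActivityScore
    composite: pd.Series
    groups: immunoactivity.ImmunoGroups
    delta_k: pd.DataFrame
    de: pd.DataFrame
    modules: coexpression.CoexpressionModules
    cox: surv.CoxFit | None
    roc_auc: float
    qc_report: single_cell.QCReport
    sc_truth: SingleCellTruth
    annotation: single_cell.CellAnnotation
    scores: linkage.CellPhenotypeScores
    calls: list[linkage.SubpopulationCall]
    shift_gene_recovery: float
    intersection_table: pd.DataFrame
    summary: dict = field(default_factory=dict)


def run_pipeline(config: RunConfig | None = None,
                 n_samples: int = 60, n_genes: int = 720, n_celltypes: int = 6,
                 noise_sd: float = 0.1,
                 n_cells_per_type: int = 250, n_planted: int = 80,
                 n_shift_genes: int = 10, shift_size: float = 1.0,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Run every stage on one synthetic cohort. See module docstring."""
    config = config or RunConfig()
    rng_bulk, rng_counts, rng_deconv, rng_dk, rng_sc, rng_embed, rng_link = \
        config.spawn_rngs(7)

    # --- simulate bulk ---------------------------------------------------
    bulk, truth, clinical = generate_bulk_cohort(
        n_samples=n_samples, n_genes=n_genes, n_celltypes=n_celltypes,
        noise_sd=noise_sd, seed=rng_bulk)
    counts = bulk_counts_from_expression(bulk, rng=rng_counts)
    states = clinical.state_of()

    # --- deconvolve -------------------------------------------------------
    sig = deconvolution.SignatureMatrix.from_frame(truth.signature)
    fractions = deconvolution.estimate_fractions(
        bulk, sig, n_perm=config.n_perm, p_cutoff=config.deconv_p_cutoff,
        seed=rng_deconv)

    # --- score ------------------------------------------------------------
    immune_types = [ct for ct in truth.signature.columns if ct != truth.risk_celltype]
    gene_sets = celltype_gene_sets(truth)
    activity = scoring.ssgsea_score(bulk, gene_sets, alpha=config.ssgsea_alpha,
                                    normalize=config.ssgsea_normalize)
    composite = scoring.composite_immunoactivity(activity, immune_types)

    # --- group (tumor samples only, as in a primary-cancer stratification)
    tumor_ids = [s for s in bulk.sample_ids if states[s] == "tumor"]
    groups = immunoactivity.partition_by_activity(composite[tumor_ids],
                                                  k_groups=config.n_groups)

    # --- slope change per cell type --------------------------------------
    dk = immunoactivity.delta_k_table(fractions, activity, states,
                                      boot_reps=500, seed=rng_dk)

    # --- differential expression low vs high ------------------------------
    # the exact partition can leave an extreme group with < 3 samples; pad
    # such a group with its nearest-scored moderate samples so the
    # differential contrast is defined (deterministic)
    order = composite[tumor_ids].sort_values().index
    low_ids = [s for s in tumor_ids if groups.labels[s] == "low"]
    high_ids = [s for s in tumor_ids if groups.labels[s] == "high"]
    if len(low_ids) < 3:
        low_ids = list(order[:3])
    if len(high_ids) < 3:
        high_ids = list(order[-3:])
    de_groups = pd.Series("moderate", index=tumor_ids, dtype=object)
    de_groups[low_ids] = "low"
    de_groups[high_ids] = "high"
    de = coexpression.differential_expression(
        counts, de_groups, lfc_thresh=config.lfc_thresh,
        padj_thresh=config.padj_thresh)
    de_genes = de.loc[de["direction"] != "ns", "gene"].tolist()
    if len(de_genes) < 3 * config.min_module_size:
        # fall back to the strongest-ranked genes so the network stage runs
        de_genes = de.sort_values("p_adj")["gene"].head(
            3 * config.min_module_size).tolist()

    # --- co-expression modules on the low+high samples --------------------
    lh_ids = [s for s in tumor_ids if de_groups[s] in ("low", "high")]
    group_trait = pd.DataFrame(
        {"immunoactivity_group": [1.0 if de_groups[s] == "high" else 0.0
                                  for s in lh_ids]}, index=lh_ids)
    net_expr = ExpressionMatrix(
        de_genes, lh_ids,
        np.log2(bulk.subset_genes(de_genes).subset_samples(lh_ids).values + 1.0),
        unit="lognorm")
    modules = coexpression.build_modules(
        net_expr, candidate_powers=config.candidate_powers,
        min_size=config.min_module_size, kme_threshold=config.kme_threshold,
        cut_height_quantile=config.cut_height_quantile,
        traits=group_trait, strong_r=config.module_trait_r)
    module_genes = modules.module_genes()

    # --- survival on module eigengenes ------------------------------------
    cox = None
    roc_auc = float("nan")
    if len(modules.eigengenes.columns) and len(lh_ids) >= 8:
        clin_lh = clinical.subset(lh_ids)
        try:
            cox = surv.fit_cox(clin_lh, modules.eigengenes.loc[lh_ids])
            risk = pd.Series(
                modules.eigengenes.loc[lh_ids].to_numpy() @ cox.coef.to_numpy(),
                index=lh_ids)
            horizon = min(config.horizon,
                          float(clin_lh.table["time"].max()) * 0.9)
            roc = surv.time_dependent_roc(risk, clin_lh, horizon=horizon)
            roc_auc = roc["auc"]
        except (ValueError, np.linalg.LinAlgError):
            cox = None

    # --- single cells ------------------------------------------------------
    # the planted subpopulation carries a program drawn from the cohort's
    # own immunoactivity-linked module genes: its parent type is the immune
    # type whose markers the module analysis captured best
    module_set = set(module_genes)
    marker_in_module = {ct: [g for g in truth.marker_genes[ct]
                             if g in module_set] for ct in immune_types}
    planted_type = max(immune_types,
                       key=lambda ct: (len(marker_in_module[ct]), ct))
    sc_types = [planted_type] + [ct for ct in immune_types
                                 if ct != planted_type][:2]
    marker_sets = GeneSetCollection(
        {ct: truth.marker_genes[ct] for ct in sc_types})
    shift_genes = (marker_in_module[planted_type][:n_shift_genes]
                   or truth.marker_genes[planted_type][:n_shift_genes])
    n_per = {ct: n_cells_per_type for ct in sc_types}
    sc_counts, sc_truth = generate_single_cells(
        n_per, marker_sets, bulk=bulk, bulk_risk=truth.risk_coef,
        planted_type=planted_type, n_planted=n_planted,
        shift_genes=shift_genes, shift_size=shift_size, seed=rng_sc)

    filtered, qc_report = single_cell.qc_filter(
        sc_counts, mito_prefix=config.mito_prefix,
        min_cells_per_gene=config.min_cells_per_gene,
        min_features_create=config.min_features_create,
        min_features_filter=config.min_features_filter,
        max_mito_fraction=config.max_mito_fraction)
    lognorm = single_cell.log_normalize(filtered, config.scale_factor)
    hvg = single_cell.select_hvg(lognorm, n=min(config.n_hvg, lognorm.n_genes))
    embedding, _ = single_cell.embed_cells(lognorm, hvg, n_pcs=config.n_pcs,
                                           seed=rng_embed)
    clusters = single_cell.cluster_cells(embedding, k_neighbors=config.k_neighbors,
                                         resolution=config.resolution)
    annotation = single_cell.annotate_clusters(lognorm, clusters, marker_sets)

    # --- phenotype linkage on the pooled low+high groups ------------------
    context_ids = lh_ids
    context = "union"
    bulk_ctx = bulk.subset_samples(context_ids)
    corr = linkage.cell_bulk_correlation(lognorm, bulk_ctx)
    L = linkage.build_cell_graph(embedding, k_neighbors=config.graph_k)
    clin_ctx = clinical.subset(context_ids)
    if config.lam is None:
        lam, _path = linkage.select_lambda_cv(
            corr.S, clin_ctx, alpha_mix=config.alpha_mix, L=L,
            seed=rng_link)
    else:
        lam = config.lam
    scores = linkage.penalized_cox_select(
        corr.S, clin_ctx, lam, alpha_mix=config.alpha_mix, L=L,
        tol=config.prox_tol, max_iter=config.prox_max_iter)
    calls = linkage.classify_and_call(scores, annotation, context)
    for call in calls:
        linkage.subpopulation_signature(call, lognorm, annotation, module_genes)

    # --- planted shift-gene recovery through the full chain ----------------
    planted_set = set(sc_truth.planted_subpop)
    best_call = None
    best_overlap = -1
    for call in calls:
        ov = len(planted_set & set(call.members))
        if call.sign == "plus" and ov > best_overlap:
            best_call, best_overlap = call, ov
    if best_call is not None and sc_truth.shift_genes:
        recovered = set(best_call.module_intersection) & set(sc_truth.shift_genes)
        shift_gene_recovery = len(recovered) / len(sc_truth.shift_genes)
    else:
        shift_gene_recovery = 0.0

    inter_rows = [{"subpopulation": c.name, "parent_type": c.parent_type,
                   "n_cells": len(c.members),
                   "n_signature_genes": len(c.signature_genes),
                   "module_intersection": ";".join(c.module_intersection)}
                  for c in calls]
    intersection_table = pd.DataFrame(inter_rows)

    summary = {
        "seed": config.seed,
        "n_samples": n_samples,
        "group_sizes": {k: int(v) for k, v in groups.sizes().items()},
        "n_de_genes": int((de["direction"] != "ns").sum()),
        "n_modules": int(len(modules.eigengenes.columns)),
        "n_module_genes": len(module_genes),
        "qc": qc_report.as_dict(),
        "lambda": float(lam),
        "n_plus_cells": int((scores.classes() == "plus").sum()),
        "n_minus_cells": int((scores.classes() == "minus").sum()),
        "shift_gene_recovery": shift_gene_recovery,
        "roc_auc": roc_auc,
    }

    result = PipelineResult(
        config=config, bulk=bulk, bulk_truth=truth, clinical=clinical,
        fractions=fractions, activity=activity, composite=composite,
        groups=groups, delta_k=dk, de=de, modules=modules, cox=cox,
        roc_auc=roc_auc, qc_report=qc_report, sc_truth=sc_truth,
        annotation=annotation, scores=scores, calls=calls,
        shift_gene_recovery=shift_gene_recovery,
        intersection_table=intersection_table, summary=summary)

    if out_dir is not None:
        _write_outputs(result, Path(out_dir))
    return result


def _write_outputs(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.fractions.fractions.to_csv(out_dir / "fractions.tsv", sep="\t")
    result.activity.scores.to_csv(out_dir / "activity.tsv", sep="\t")
    result.composite.to_frame().to_csv(out_dir / "composite.tsv", sep="\t")
    result.groups.labels.to_frame().to_csv(out_dir / "groups.tsv", sep="\t")
    result.delta_k.to_csv(out_dir / "delta_k.tsv", sep="\t", index=False)
    result.de.to_csv(out_dir / "de.tsv", sep="\t", index=False)
    result.modules.labels.to_frame().to_csv(out_dir / "modules.tsv", sep="\t")
    result.scores.beta.to_frame().to_csv(out_dir / "cell_scores.tsv", sep="\t")
    result.intersection_table.to_csv(out_dir / "intersection.tsv", sep="\t",
                                     index=False)
    manifest = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in result.config.__dict__.items()},
                "summary": result.summary}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
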
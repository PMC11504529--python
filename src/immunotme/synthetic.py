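"""Synthetic cohorts with planted ground truth.

Every downstream stage of the pipeline is exercised on data produced here:

* :func:`generate_bulk_cohort` — bulk mixtures of a known nonnegative
  signature matrix with Dirichlet cell-type fractions, multiplicative
  log-normal noise, and exponential proportional-hazards survival tied to
  one planted fraction.
* :func:`generate_two_state` — abundance/activity pairs with planted
  per-state regression slopes, the test bed for the slope-change statistic.
* :func:`generate_module_blocks` — latent-factor co-expression blocks for
  network module recovery.
* :func:`generate_single_cells` — negative-binomial single-cell counts per
  annotated type, a phenotype-linked planted subpopulation whose profiles
  mix with high-risk bulk samples, and engineered QC-failure cells so every
  filter count is predictable by construction.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ClinicalTable, ExpressionMatrix, GeneSetCollection

# ---------------------------------------------------------------------------
# Bulk cohort
# ---------------------------------------------------------------------------


@dataclass
class BulkTruth:
    """Planted truth behind a synthetic bulk cohort."""

    signature: pd.DataFrame          # gene x cell-type nonnegative means
    fractions: pd.DataFrame          # sample x cell-type, rows sum to 1
    noise_sd: float
    risk_coef: pd.Series             # per-sample log-hazard
    risk_celltype: str               # the fraction the hazard is tied to
    marker_genes: dict[str, list[str]] = field(default_factory=dict)


def generate_bulk_cohort(
    n_samples: int = 40,
    n_genes: int = 720,
    n_celltypes: int = 6,
    dirichlet_conc: float = 5.0,
    noise_sd: float = 0.1,
    seed: int | np.random.Generator = 0,
    control_fraction: float = 0.2,
    purity_beta_control: tuple[float, float] = (2.0, 8.0),
    purity_beta_tumor: tuple[float, float] = (2.0, 2.0),
    risk_strength: float = 1.0,
    baseline_median_months: float = 24.0,
    censor_scale_months: float = 96.0,
    n_mito: int = 10,
    marker_fold: float = 15.0,
) -> tuple[ExpressionMatrix, BulkTruth, ClinicalTable]:
    """Simulate a bulk expression cohort as noisy signature mixtures.

    Expression is ``signature @ fractions.T`` perturbed elementwise by
    ``exp(N(0, noise_sd))``. Cell type 0 plays a tumor-like compartment:
    its fraction (tumor purity) is a Beta draw with a higher, wider
    distribution in tumor than in control samples (a planted group
    difference), while the relative composition of the remaining cell
    types is an independent Dirichlet draw — so tumor purity, and the
    survival hazard tied to it, carries no information about relative
    immune proportions. The per-sample log-hazard is ``risk_strength``
    times the z-score of the purity fraction. Survival times are
    exponential with that hazard; censoring is an independent exponential
    with scale ``censor_scale_months`` (about 20% censoring at baseline).

    The last ``n_mito`` genes are named with the ``MT-`` prefix so that
    single-cell QC on the same gene universe can exercise its mitochondrial
    rule.

    Returns ``(expression[normalized], truth, clinical)``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_samples < 8:
        raise ValueError("n_samples must be at least 8")
    if n_celltypes < 3:
        raise ValueError("n_celltypes must be at least 3")
    if n_genes < 20 * n_celltypes:
        raise ValueError("n_genes must be at least 20 * n_celltypes")

    celltypes = [f"CT{t}" for t in range(n_celltypes)]
    n_plain = n_genes - n_mito
    gene_ids = [f"G{i:05d}" for i in range(n_plain)] + [f"MT-{i}" for i in range(n_mito)]

    # signature: shared log-normal baseline, per-type jitter, and a marker
    # block per cell type elevated marker_fold-fold
    base = rng.lognormal(mean=math.log(2.0), sigma=0.4, size=n_genes)
    sig = base[:, None] * rng.lognormal(mean=0.0, sigma=0.1, size=(n_genes, n_celltypes))
    markers_per_type = n_plain // (2 * n_celltypes)
    marker_genes: dict[str, list[str]] = {}
    for t in range(n_celltypes):
        lo = t * markers_per_type
        hi = lo + markers_per_type
        sig[lo:hi, :] *= 0.2              # markers are cell-type specific:
        sig[lo:hi, t] *= 5.0 * marker_fold  # low elsewhere, high in their type
        marker_genes[celltypes[t]] = gene_ids[lo:hi]
    signature = pd.DataFrame(sig, index=gene_ids, columns=celltypes)
    if np.linalg.cond(sig) > 1e8:
        raise ValueError("degenerate signature (condition number too large)")

    n_control = max(3, int(round(control_fraction * n_samples)))
    states = ["control"] * n_control + ["tumor"] * (n_samples - n_control)
    # tumor purity (fraction of the tumor-like compartment, cell type 0) is
    # drawn independently of the relative immune composition, so that the
    # survival hazard — a function of purity alone — carries no information
    # about relative immune proportions
    conc = np.full(n_celltypes - 1, float(dirichlet_conc))
    fracs = np.empty((n_samples, n_celltypes))
    for i, st in enumerate(states):
        a, b = purity_beta_tumor if st == "tumor" else purity_beta_control
        purity = rng.beta(a, b)
        rel = rng.dirichlet(conc)
        fracs[i, 0] = purity
        fracs[i, 1:] = (1.0 - purity) * rel
    sample_ids = [f"S{i:03d}" for i in range(n_samples)]
    fractions = pd.DataFrame(fracs, index=sample_ids, columns=celltypes)

    mean_expr = sig @ fracs.T
    noise = rng.normal(0.0, noise_sd, size=mean_expr.shape) if noise_sd > 0 else 0.0
    values = mean_expr * np.exp(noise)
    expr = ExpressionMatrix(gene_ids, sample_ids, values, unit="normalized")

    f0 = fracs[:, 0]
    z = (f0 - f0.mean()) / f0.std(ddof=0)
    risk = risk_strength * z
    base_scale = baseline_median_months / np.log(2)  # median -> exponential scale
    t_event = rng.exponential(scale=base_scale / np.exp(risk))
    t_cens = rng.exponential(scale=censor_scale_months, size=n_samples)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-6)

    clinical = ClinicalTable(pd.DataFrame({
        "sample_id": sample_ids,
        "state": states,
        "time": time,
        "event": event,
    }), time_unit="months")

    truth = BulkTruth(
        signature=signature,
        fractions=fractions,
        noise_sd=noise_sd,
        risk_coef=pd.Series(risk, index=sample_ids, name="risk"),
        risk_celltype=celltypes[0],
        marker_genes=marker_genes,
    )
    return expr, truth, clinical


def celltype_gene_sets(truth: BulkTruth, exclude: tuple[str, ...] = ()) -> GeneSetCollection:
    """Marker gene sets per simulated cell type (for ssGSEA / annotation)."""
    sets = {ct: list(genes) for ct, genes in truth.marker_genes.items()
            if ct not in exclude}
    return GeneSetCollection(sets, {ct: "synthetic markers" for ct in sets})


# ---------------------------------------------------------------------------
# Two-state abundance/activity pairs
# ---------------------------------------------------------------------------


@dataclass
class TwoStateTruth:
    """Planted per-state regression lines for the slope-change comparison."""

    k_control: float
    k_tumor: float
    b_control: float = 0.0
    b_tumor: float = 0.0
    sigma: float = 0.05
    n_control: int = 30
    n_tumor: int = 30

    def __post_init__(self) -> None:
        if self.n_control < 3 or self.n_tumor < 3:
            raise ValueError("need at least 3 points per state")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")


def generate_two_state(truth: TwoStateTruth, seed: int | np.random.Generator = 0,
                       x_range: tuple[float, float] = (0.0, 1.0)) -> pd.DataFrame:
    """Draw (state, abundance x, activity y) with y = k*x + b + N(0, sigma).

    Abundance x is uniform on ``x_range`` within each state.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for state, k, b, n in (("control", truth.k_control, truth.b_control, truth.n_control),
                           ("tumor", truth.k_tumor, truth.b_tumor, truth.n_tumor)):
        x = rng.uniform(*x_range, size=n)
        y = k * x + b + (rng.normal(0.0, truth.sigma, size=n) if truth.sigma > 0 else 0.0)
        rows.append(pd.DataFrame({"state": state, "x": x, "y": y}))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Co-expression blocks
# ---------------------------------------------------------------------------


def generate_module_blocks(
    n_genes: int,
    block_sizes: list[int],
    within_cor: float,
    n_samples: int,
    seed: int | np.random.Generator = 0,
) -> tuple[ExpressionMatrix, np.ndarray, np.ndarray]:
    """Genes within a block share a latent sample factor.

    Each block gene is ``sqrt(w) * factor + sqrt(1-w) * noise`` with
    ``w = within_cor``, giving expected pairwise correlation ``within_cor``
    inside the block; background genes are independent standard normals.

    Returns ``(expression[lognorm-scale], labels, factors)`` where labels[g]
    is the 0-based block index or -1 for background, and factors is the
    (n_samples, n_blocks) latent matrix.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if sum(block_sizes) > n_genes:
        raise ValueError("block sizes exceed n_genes")
    if not 0 <= within_cor <= 1:
        raise ValueError("within_cor outside [0, 1]")
    factors = rng.standard_normal((n_samples, len(block_sizes)))
    values = rng.standard_normal((n_genes, n_samples))
    labels = np.full(n_genes, -1, dtype=int)
    pos = 0
    w = math.sqrt(within_cor)
    v = math.sqrt(1.0 - within_cor)
    for b, size in enumerate(block_sizes):
        values[pos:pos + size] = w * factors[:, b] + v * values[pos:pos + size]
        labels[pos:pos + size] = b
        pos += size
    gene_ids = [f"BG{i:05d}" for i in range(n_genes)]
    sample_ids = [f"S{i:03d}" for i in range(n_samples)]
    expr = ExpressionMatrix(gene_ids, sample_ids, values, unit="lognorm")
    return expr, labels, factors


# ---------------------------------------------------------------------------
# Single cells
# ---------------------------------------------------------------------------


@dataclass
class SingleCellTruth:
    """Planted truth for a synthetic single-cell experiment."""

    type_of_cell: dict[str, str]
    planted_subpop: list[str]
    shift_genes: list[str]
    shift_size: float
    expected_qc: dict[str, int] = field(default_factory=dict)
    dispersion: float = 0.5


HOUSEKEEPING_SIZE = 520  # genes guaranteed detected in every normal cell


def generate_single_cells(
    n_cells_per_type: dict[str, int],
    marker_sets: GeneSetCollection,
    bulk: ExpressionMatrix,
    bulk_risk: pd.Series,
    planted_type: str | None = None,
    n_planted: int = 0,
    shift_genes: list[str] | None = None,
    shift_size: float = 1.0,
    alpha_link: float = 0.6,
    dispersion: float = 0.5,
    base_mean: float = 1.0,
    marker_fold: float = 8.0,
    n_fail_create: int = 12,
    n_fail_filter: int = 5,
    n_fail_mito: int = 6,
    n_rare_genes: int = 8,
    mito_prefix: str = "MT-",
    seed: int | np.random.Generator = 0,
) -> tuple[ExpressionMatrix, SingleCellTruth]:
    """Simulate single-cell counts over the bulk gene universe.

    Per annotated type, counts are negative-binomial (gamma-Poisson with
    shape ``1/dispersion``) around a flat baseline with that type's marker
    genes elevated ``marker_fold``-fold. A housekeeping block of
    ``HOUSEKEEPING_SIZE`` genes (including the mitochondrial genes) receives
    one guaranteed count in every normal cell, pinning the detected-feature
    count of normal cells above the QC cutoffs.

    The planted subpopulation lives inside ``planted_type``: when
    ``shift_size != 0`` its mean profile is mixed with the mean profile of
    the top-quartile-risk bulk samples (weight ``alpha_link``) and its
    ``shift_genes`` are further scaled by ``2**shift_size``; when
    ``shift_size == 0`` no link is planted and the subpopulation equals its
    parent type in expectation.

    QC-failure cells are appended with deterministic feature counts:
    ``n_fail_create`` cells with exactly 200 detected features,
    ``n_fail_filter`` with exactly 400, and ``n_fail_mito`` normal-profile
    cells whose mitochondrial reads are inflated to 10% of the total.
    ``n_rare_genes`` genes are detected in exactly 5 cells. Expected filter
    counts (under the default QC thresholds, assuming at least 100 normal
    cells) are recorded in ``truth.expected_qc``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gene_ids = list(bulk.gene_ids)
    n_genes = len(gene_ids)
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    for name, genes in marker_sets.sets.items():
        unknown = [g for g in genes if g not in gene_index]
        if unknown:
            raise ValueError(f"marker set {name!r} references unknown genes: {unknown[:5]}")
    shift_genes = list(shift_genes or [])
    for g in shift_genes:
        if g not in gene_index:
            raise ValueError(f"shift gene {g!r} not in gene universe")
    if planted_type is not None and planted_type not in n_cells_per_type:
        raise ValueError(f"planted type {planted_type!r} has no cells")

    mito_idx = np.array([i for i, g in enumerate(gene_ids) if g.startswith(mito_prefix)],
                        dtype=int)
    # rare genes: last non-mito, non-marker genes
    marker_all = {g for genes in marker_sets.sets.values() for g in genes}
    candidates = [i for i, g in enumerate(gene_ids)
                  if not g.startswith(mito_prefix) and g not in marker_all
                  and g not in set(shift_genes)]
    rare_idx = np.array(candidates[-n_rare_genes:] if n_rare_genes else [], dtype=int)
    rare_set = set(rare_idx.tolist())
    nonrare_idx = np.array([i for i in range(n_genes) if i not in rare_set], dtype=int)
    if len(nonrare_idx) < HOUSEKEEPING_SIZE:
        raise ValueError("gene universe too small for the housekeeping block")
    # housekeeping: mito genes plus the first non-rare genes
    hk = list(mito_idx)
    for i in nonrare_idx:
        if len(hk) >= HOUSEKEEPING_SIZE:
            break
        if i not in mito_idx:
            hk.append(int(i))
    hk_idx = np.array(sorted(hk), dtype=int)

    # high-risk bulk mean profile (top risk quartile), scaled to baseline level
    risk = bulk_risk.reindex(bulk.sample_ids).to_numpy(dtype=float)
    n_top = max(2, len(risk) // 4)
    top = np.argsort(risk)[-n_top:]
    bulk_profile = bulk.values[:, top].mean(axis=1)
    bulk_profile = bulk_profile / bulk_profile.mean() * base_mean

    shape = 1.0 / dispersion

    def nb_draw(mu: np.ndarray, n: int) -> np.ndarray:
        lam = rng.gamma(shape, mu / shape, size=(n, len(mu)))
        return rng.poisson(lam).astype(float)

    cells: list[str] = []
    blocks: list[np.ndarray] = []
    type_of_cell: dict[str, str] = {}
    planted: list[str] = []

    for ct, n_cells in n_cells_per_type.items():
        mu = np.full(n_genes, base_mean)
        midx = np.array([gene_index[g] for g in marker_sets.sets.get(ct, [])], dtype=int)
        if midx.size:
            mu[midx] *= marker_fold
        mu[rare_idx] = 0.0
        if ct == planted_type and n_planted > n_cells:
            raise ValueError("n_planted exceeds cells of the planted type")
        ids = [f"{ct}_{i:04d}" for i in range(n_cells)]
        counts = np.zeros((n_cells, n_genes))
        # planted cells come first within their type; shift_size == 0 plants
        # nothing (null case: the subpopulation does not exist)
        n_sub = n_planted if (ct == planted_type and shift_size != 0) else 0
        if n_sub:
            mu_sub = (1 - alpha_link) * mu + alpha_link * bulk_profile
            sidx = np.array([gene_index[g] for g in shift_genes], dtype=int)
            if sidx.size:
                # shift genes sit at 2**shift_size times their level in
                # the parent type, regardless of the mixing dilution
                mu_sub[sidx] = mu[sidx] * 2.0 ** shift_size
            mu_sub[rare_idx] = 0.0
            counts[:n_sub] = nb_draw(mu_sub, n_sub)
            planted.extend(ids[:n_sub])
        if n_cells - n_sub:
            counts[n_sub:] = nb_draw(mu, n_cells - n_sub)
        counts[:, hk_idx] += 1.0  # guaranteed detection of the housekeeping block
        cells.extend(ids)
        blocks.append(counts)
        for cid in ids:
            type_of_cell[cid] = ct

    n_normal_total = len(cells)
    if n_normal_total < 100:
        raise ValueError("need at least 100 normal cells")

    # rare genes: detected in exactly 5 normal cells
    mat = np.vstack(blocks)
    for j in rare_idx:
        chosen = rng.choice(n_normal_total, size=5, replace=False)
        mat[chosen, j] = 1.0

    extra_blocks: list[np.ndarray] = []
    extra_ids: list[str] = []
    feat_pool = [i for i in nonrare_idx.tolist()]
    for tag, n_fail, n_feat in (("lowfeat", n_fail_create, 200),
                                ("midfeat", n_fail_filter, 400)):
        if n_fail:
            block = np.zeros((n_fail, n_genes))
            block[:, feat_pool[:n_feat]] = 1.0
            extra_blocks.append(block)
            ids = [f"QC_{tag}_{i:02d}" for i in range(n_fail)]
            extra_ids.extend(ids)
            for cid in ids:
                type_of_cell[cid] = "qc_fail"
    if n_fail_mito:
        any_type = next(iter(n_cells_per_type))
        mu = np.full(n_genes, base_mean)
        midx = np.array([gene_index[g] for g in marker_sets.sets.get(any_type, [])], dtype=int)
        if midx.size:
            mu[midx] *= marker_fold
        mu[rare_idx] = 0.0
        block = nb_draw(mu, n_fail_mito)
        block[:, hk_idx] += 1.0
        if mito_idx.size == 0:
            raise ValueError("no mitochondrial genes in the gene universe")
        nonmito_total = block.sum(axis=1) - block[:, mito_idx].sum(axis=1)
        per_mito = np.ceil(nonmito_total * 0.1 / (0.9 * len(mito_idx)))
        block[:, mito_idx] = per_mito[:, None]  # ~10% mito fraction, > 5% cutoff
        extra_blocks.append(block)
        ids = [f"QC_himito_{i:02d}" for i in range(n_fail_mito)]
        extra_ids.extend(ids)
        for cid in ids:
            type_of_cell[cid] = "qc_fail"

    all_ids = cells + extra_ids
    full = np.vstack([mat] + extra_blocks) if extra_blocks else mat
    counts = ExpressionMatrix(gene_ids, all_ids, full.T, unit="counts")

    expected_qc = {
        "n_cells_in": len(all_ids),
        "n_genes_in": n_genes,
        "n_removed_gene_filter": int(len(rare_idx)),
        "n_removed_feature_300": int(n_fail_create),
        "n_removed_feature_500": int(n_fail_filter),
        "n_removed_mito": int(n_fail_mito),
        "n_cells_out": len(all_ids) - n_fail_create - n_fail_filter - n_fail_mito,
        "n_genes_out": n_genes - int(len(rare_idx)),
    }
    truth = SingleCellTruth(
        type_of_cell=type_of_cell,
        planted_subpop=planted,
        shift_genes=shift_genes,
        shift_size=shift_size,
        expected_qc=expected_qc,
        dispersion=dispersion,
    )
    return counts, truth
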
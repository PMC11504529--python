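# immunotme

Immune-infiltrate profiling of tumor transcriptomes, for computational
biologists who want the full bulk + single-cell joint analysis as a single
reproducible, testable pipeline: estimate immune-cell fractions in bulk
samples, score per-sample immune activity, stratify samples into
low/moderate/high immunoactivity groups, compare activity between healthy
and cancerous states with a slope-change statistic, discover
survival-associated co-expression modules, and pick out the single cells
whose profiles track poor or good survival.

Every stage runs on synthetic cohorts with planted ground truth, so the
whole chain is verifiable without downloading any cohort data.

## The statistics at the core

* **Deconvolution.** Per sample, relative cell-type fractions solve the
  nonnegative least-squares problem `min ‖y − S f‖₂, f ≥ 0` over an
  LM22-style signature matrix S, renormalized so `Σ f = 1`, with a
  permutation p-value on the fit.
* **ssGSEA.** The activity of gene set G in a sample is the running-sum
  score `Σ_i [P_in(i) − P_out(i)]` over the expression-ranked gene list,
  where P_in weights in-set genes by `rank^α` (α = 0.25) and P_out is the
  uniform out-of-set CDF.
* **Immunoactivity grouping.** Exact 1-D k-means on the composite score:
  dynamic programming over the sorted scores minimizing the within-group
  sum of squared deviations — deterministic and provably optimal.
* **Slope change (Δk).** Within each state (control/tumor), OLS of
  activity y on abundance x gives a slope k; `Δk = k_tumor − k_control`
  with a percentile-bootstrap interval turns the sign into an
  enhanced / weakened / unchanged call.
* **Co-expression modules.** Signed adjacency `((1+cor)/2)^β`, topological
  overlap, average-linkage tree with a simplified dynamic-hybrid cut, module
  eigengenes (first PCs) and kME ≥ 0.75 membership.
* **Survival.** Newton–Raphson Cox regression (Breslow ties, step-halving),
  Kaplan–Meier / log-rank, and the cumulative/dynamic Kaplan–Meier
  time-dependent ROC at a five-year horizon.
* **Phenotype-guided cell selection.** With S the cell-by-sample Pearson
  correlation matrix, minimize
  `−loglik_Cox(S'β) + λ[α‖β‖₁ + (1−α) β'Lβ]` (L = cell-graph Laplacian) by
  proximal gradient; cells with β > 0 are poor-survival ("plus") cells,
  β < 0 good-survival, exact zeros background.

See `docs/methods.md` for assumptions, defaults, and limitations.

## Worked example

The whole pipeline on one synthetic cohort (60 bulk samples, 6 cell types,
~770 single cells, one planted poor-survival subpopulation of 80 cells
carrying 10 shifted genes):

```python
from immunotme.config import RunConfig
from immunotme.pipeline import run_pipeline

res = run_pipeline(RunConfig(seed=7))
print(res.summary)
print(res.delta_k[["celltype", "delta_k", "ci_low", "ci_high", "call"]])
```

prints (abridged):

```
group_sizes: {'moderate': 26, 'high': 12, 'low': 10}
n_de_genes: 307
n_modules: 5
qc: {'n_cells_in': 773, ..., 'n_removed_feature_300': 12,
     'n_removed_feature_500': 5, 'n_removed_mito': 6, 'n_cells_out': 750}
n_plus_cells: 96
shift_gene_recovery: 1.0
roc_auc: 0.818

celltype  delta_k  ci_low  ci_high      call
     CT0   -2.109  -3.035   -0.912  weakened
     CT1    1.066   0.321    1.970  enhanced
     CT2    0.396  -0.546    1.622 unchanged
     CT3    1.961   1.250    3.007  enhanced
     CT4    1.039   0.239    2.007  enhanced
     CT5    0.829  -0.500    1.663 unchanged
```

Reading it: the 48 tumor samples split 10/26/12 into low/moderate/high
immunoactivity; 307 genes are differential between the extremes and
organize into 5 co-expression modules whose eigengenes predict five-year
survival with AUC 0.82. The slope-change table says immune activity per
unit abundance rises in the tumor state for CT1/CT3/CT4 (interval above
zero) and falls for the tumor-like compartment CT0. On the single-cell
side, 750 of 773 cells pass QC with every removal count matching the
engineered fixture, and the selector's main plus-call (`CT1Lp`, 80 cells)
is exactly the planted subpopulation — its marker signature intersected
with the module genes recovers all 10 planted shift genes
(`shift_gene_recovery: 1.0`).

A command-line interface mirrors the stages
(`immunotme simulate|deconvolve|score|group|deltak|de|modules|survival|sc|link|enrich`),
e.g.:

```bash
immunotme simulate --scenario bulk --seed 3 --out sim/
immunotme deconvolve --expr sim/expression.tsv --sig sim/signature.tsv \
    --perm 100 --out fractions.tsv
```

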
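"""Run configuration: every tunable threshold of the pipeline in one place.

All randomness flows from ``RunConfig.seed``; stochastic stages derive
independent generators from it via :func:`numpy.random.SeedSequence.spawn`,
so a fixed seed yields bit-identical runs regardless of stage order.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class RunConfig:
    """Pipeline hyperparameters with documented defaults.

    The defaults mirror the published processing contract where one is
    stated (QC cutoffs, ssGSEA exponent, kME threshold, scale factor) and
    the field-standard value elsewhere.
    """

    seed: int = 0

    # deconvolution
    n_perm: int = 100                 # permutation count for the per-sample fit p-value
    deconv_p_cutoff: float = 0.05     # samples at/above are flagged

    # ssGSEA / immunoactivity
    ssgsea_alpha: float = 0.25        # rank-weight exponent
    ssgsea_normalize: bool = True
    n_groups: int = 3                 # low / moderate / high

    # differential expression
    lfc_thresh: float = 1.0           # |log2FC| cutoff
    padj_thresh: float = 0.05

    # co-expression network
    candidate_powers: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8, 10, 12, 14, 16)
    default_power: int = 6
    scale_free_r2: float = 0.8
    min_module_size: int = 10
    cut_height_quantile: float = 0.99  # static cut at this quantile of merge heights
    kme_threshold: float = 0.75
    module_trait_r: float = 0.85

    # single-cell QC (counts) and processing
    min_cells_per_gene: int = 100
    min_features_create: int = 300
    min_features_filter: int = 500
    max_mito_fraction: float = 0.05
    mito_prefix: str = "MT-"
    scale_factor: float = 10_000.0
    n_hvg: int = 2000
    n_pcs: int = 10
    k_neighbors: int = 20
    resolution: float = 1.0

    # survival
    horizon: float = 60.0             # 5 years in months
    time_unit: str = "months"

    # phenotype linkage
    lam: float | None = None          # None = path search
    alpha_mix: float = 0.05           # graph-dominated penalty mix
    graph_k: int = 10
    prox_tol: float = 1e-6
    prox_max_iter: int = 2000

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be nonnegative")
        if not 0 <= self.ssgsea_alpha <= 2:
            raise ValueError("ssgsea_alpha outside [0, 2]")
        if self.n_groups < 2:
            raise ValueError("n_groups must be at least 2")
        if not 0 < self.kme_threshold <= 1:
            raise ValueError("kme_threshold outside (0, 1]")
        if not 0 <= self.alpha_mix <= 1:
            raise ValueError("alpha_mix outside [0, 1]")
        if not 0 <= self.max_mito_fraction <= 1:
            raise ValueError("max_mito_fraction outside [0, 1]")

    def spawn_rngs(self, n: int) -> list[np.random.Generator]:
        """Derive ``n`` independent, reproducible generators from the seed."""
        return [np.random.default_rng(s) for s in np.random.SeedSequence(self.seed).spawn(n)]

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["candidate_powers"] = list(self.candidate_powers)
        Path(path).write_text(json.dumps(d, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        if "candidate_powers" in d:
            d["candidate_powers"] = tuple(d["candidate_powers"])
        return cls(**d)
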
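"""Over-representation analysis of gene lists against gene-set collections.

For a gene list of size n drawn from a universe of size N, the overlap k
with a set of size K is tested against the hypergeometric upper tail
``P(X >= k)``; q-values are Benjamini-Hochberg within the tested
collection. A set passes when both p < 0.05 and q < 0.05, the screening
rule used for pathway selection.
"""

from __future__ import annotations

import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection


def hypergeometric_enrichment(gene_list: list[str], universe: list[str],
                              collection: GeneSetCollection,
                              p_cutoff: float = 0.05,
                              q_cutoff: float = 0.05) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation per set.

    ``gene_list`` must be a subset of ``universe``; sets are intersected
    with the universe before testing.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    genes = set(gene_list)
    if not genes:
        raise ValueError("empty gene list")
    stray = genes - uni
    if stray:
        raise ValueError(f"gene list not contained in universe: {sorted(stray)[:3]}")
    N = len(uni)
    n = len(genes)
    rows = []
    for name, members in collection.sets.items():
        inset = set(members) & uni
        K = len(inset)
        k = len(genes & inset)
        # upper tail P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(scipy.stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"set": name, "overlap": k, "set_size": K,
                     "list_size": n, "universe_size": N, "p": min(p, 1.0)})
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
        out["passes"] = (out["p"] < p_cutoff) & (out["q"] < q_cutoff)
    return out
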
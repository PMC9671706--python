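"""Over-representation analysis of axis mRNAs against pathway gene sets.

One-sided hypergeometric test, the classical Fisher-exact-style ORA that
gene-set web tools run: for a query of n genes drawn from a universe of N,
the probability of seeing k or more hits in a set of size K is

    p = sum_{i=k}^{min(n,K)} C(K,i) C(N-K, n-i) / C(N,n).

The universe should be the set of genes that survived the expression
filters (not the whole genome), otherwise filter-induced composition bias
masquerades as enrichment.  BH adjustment runs across all tested sets.
"""

from __future__ import annotations

import warnings

import pandas as pd
from scipy import stats

from .io_formats import GeneSetCollection
from .diffexpr import benjamini_hochberg

__all__ = ["enrich"]


def enrich(
    query: set[str],
    sets: GeneSetCollection,
    universe: set[str],
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Query genes outside the universe are dropped with a warning; set
    members are likewise intersected with the universe before counting.
    Rows come back sorted by p ascending, ties broken by set name.
    """
    if len(sets) == 0:
        raise ValueError("empty gene-set collection")
    if not query:
        raise ValueError("empty query gene set")
    stray = query - universe
    if stray:
        warnings.warn(
            f"{len(stray)} query gene(s) outside the universe dropped "
            f"(e.g. {sorted(stray)[0]!r})",
            stacklevel=2,
        )
    query_in = query & universe
    if not query_in:
        raise ValueError("no query genes remain inside the universe")
    N = len(universe)
    n = len(query_in)
    rows = []
    for s in sets:
        members = set(s.genes) & universe
        K = len(members)
        overlap = sorted(query_in & members)
        k = len(overlap)
        # survival function at k-1 gives P(X >= k), the upper tail inclusive
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append(
            {
                "set_name": s.name,
                "overlap_k": k,
                "set_size_K": K,
                "query_n": n,
                "universe_N": N,
                "p_value": min(p, 1.0),
                "overlap_genes": "|".join(overlap),
            }
        )
    out = pd.DataFrame(rows)
    out["adj_p"] = benjamini_hochberg(out["p_value"])
    out = out.sort_values(["p_value", "set_name"], kind="stable").reset_index(drop=True)
    return out[
        [
            "set_name",
            "overlap_k",
            "set_size_K",
            "query_n",
            "universe_N",
            "p_value",
            "adj_p",
            "overlap_genes",
        ]
    ]
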
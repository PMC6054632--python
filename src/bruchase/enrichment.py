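"""Gene-set over-representation analysis (ORA).

For a query list of n genes drawn from a universe of N, a set with K
members in the universe, and an overlap of k, the enrichment p-value is
the hypergeometric upper tail P(X >= k); q-values come from BH adjustment
across all sets tested in the same call.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .synthesis import bh_adjust

__all__ = ["hypergeom_upper_tail", "ora_analysis"]


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), computed in log space."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: K={K}, n={n}, N={N}")
    if not 0 <= k <= min(n, K):
        raise ValueError(f"overlap k={k} outside [0, min(n={n}, K={K})]")
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k); scipy evaluates the tail stably in log space
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    return min(max(p, np.nextafter(0, 1)), 1.0)


def ora_analysis(
    query_genes,
    gene_sets: dict[str, list[str]],
    universe_genes,
    enrichment_fdr: float = 0.05,
) -> pd.DataFrame:
    """Over-representation of ``query_genes`` in each set, within the universe.

    Query genes outside the universe are dropped (their count is recorded
    in ``DataFrame.attrs['n_dropped']``); each set is intersected with the
    universe before testing.  Results are BH-adjusted across tested sets
    and sorted by (q, p).
    """
    universe = set(universe_genes)
    if not universe:
        raise ValueError("empty universe")
    query_all = set(query_genes)
    query = query_all & universe
    n_dropped = len(query_all) - len(query)
    N = len(universe)
    n = len(query)

    rows = []
    for name, members in gene_sets.items():
        in_universe = set(members) & universe
        K = len(in_universe)
        k = len(in_universe & query)
        p = hypergeom_upper_tail(k, K, n, N) if K else 1.0
        fold = (k / n) / (K / N) if (n and K) else 0.0
        rows.append(
            {"set_name": name, "k": k, "n": n, "K": K, "N": N, "p": p,
             "fold_enrichment": fold}
        )
    res = pd.DataFrame(rows)
    if len(res):
        res["q"] = bh_adjust(res["p"].to_numpy())
        res["significant"] = res["q"] < enrichment_fdr
        res = res.sort_values(["q", "p"], kind="mergesort").reset_index(drop=True)
    res.attrs["n_dropped"] = n_dropped
    return res
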
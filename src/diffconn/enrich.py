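"""Over-representation analysis of a feature list against gene sets.

One-sided hypergeometric test per set (upper tail: probability of seeing
at least the observed overlap), BH FDR across sets, and a −log10(p)
filter.  Sets are intersected with the universe before testing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .de import benjamini_hochberg
from .io import GeneSetCollection


def hypergeometric_enrichment(
    query: set[str], sets: GeneSetCollection, universe: set[str]
) -> pd.DataFrame:
    """Upper-tail hypergeometric p per gene set.

    ``query`` must be a subset of ``universe``.  Columns: set_name,
    overlap, set_size, query_size, universe_size, p_value, fdr,
    neg_log10_p.
    """
    if not query:
        raise ValueError("query is empty")
    if not universe:
        raise ValueError("universe is empty")
    stray = query - universe
    if stray:
        raise ValueError(f"query feature {sorted(stray)[0]!r} not in universe")
    M = len(universe)
    N = len(query)
    rows = []
    for name, members in sets.sets.items():
        in_universe = members & universe
        n = len(in_universe)
        overlap = len(in_universe & query)
        # P(X >= overlap), X ~ Hypergeom(M, n, N)
        p = float(stats.hypergeom.sf(overlap - 1, M, n, N)) if n else 1.0
        p = min(p, 1.0)
        rows.append(
            {
                "set_name": name,
                "overlap": overlap,
                "set_size": n,
                "query_size": N,
                "universe_size": M,
                "p_value": p,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["set_name", "overlap", "set_size", "query_size", "universe_size", "p_value"],
    )
    if len(df):
        df["fdr"] = benjamini_hochberg(df["p_value"].to_numpy())
        with np.errstate(divide="ignore"):
            df["neg_log10_p"] = -np.log10(df["p_value"].to_numpy())
    else:
        df["fdr"] = []
        df["neg_log10_p"] = []
    return df


def filter_enrichment(results: pd.DataFrame, min_neg_log10_p: float) -> pd.DataFrame:
    """Keep results with −log10(p) strictly greater than the cutoff."""
    return results.loc[results["neg_log10_p"] > min_neg_log10_p].reset_index(drop=True)
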
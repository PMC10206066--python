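"""Over-representation analysis by one-sided Fisher's exact test.

For a query gene set (FPS nodes, a TopNet, a DEG list) and a gene-set
collection, each set is intersected with the universe and the upper-tail
hypergeometric probability of an overlap at least as large as observed
is computed.  The universe should be the gene population the query was
drawn from — for network-derived queries, all genes of the scaffold
interaction network.  No multiple-testing correction gates significance
by default (a raw p < alpha call), but a Benjamini-Hochberg column is
emitted for modern use.
"""

from __future__ import annotations

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection

ENRICH_COLUMNS = [
    "set_name", "overlap_count", "set_size", "query_size", "universe_size",
    "p_value", "bh_q", "significant",
]


def enrich(
    query: set[str],
    universe: set[str],
    collection: GeneSetCollection,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    p = P[overlap >= observed] under sampling |query| genes from the
    universe without replacement.  Sets empty after universe intersection
    are dropped.  Rows are sorted by ascending p, ties by set name.
    """
    if not query or not universe:
        raise ValueError("query and universe must be non-empty")
    extra = query - universe
    if extra:
        raise ValueError(f"query genes outside the universe: {sorted(extra)[:5]}")
    m = len(universe)
    n_query = len(query)
    rows = []
    for name in sorted(collection.sets):
        members = collection.sets[name] & universe
        if not members:
            continue
        k = len(members)
        overlap = len(query & members)
        # upper tail: P[X >= overlap], X ~ Hypergeom(M=m, n=k, N=n_query)
        p = float(stats.hypergeom.sf(overlap - 1, m, k, n_query))
        rows.append((name, overlap, k, n_query, m, min(p, 1.0)))
    table = pd.DataFrame(
        rows,
        columns=["set_name", "overlap_count", "set_size",
                 "query_size", "universe_size", "p_value"],
    )
    if len(table):
        table["bh_q"] = multipletests(table["p_value"], method="fdr_bh")[1]
        table["significant"] = table["p_value"] < alpha
        table = table.sort_values(
            ["p_value", "set_name"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        table["bh_q"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
    return table[ENRICH_COLUMNS]
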
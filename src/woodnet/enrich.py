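"""Gene-set over-representation testing (hypergeometric upper tail).

Enrichment of a query gene list (a module or cluster) against a gene-set
collection is scored by the one-sided hypergeometric test: with N universe
genes, K of them in the term, and a query of n genes hitting k of the
term, ``p = P(X >= k)``.  Terms passing the reporting cutoff (raw
p < 0.05 by default) are returned sorted by p; an optional BH adjustment
is off by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

from .response import bh_adjust


@dataclass
class GeneSetCollection:
    """Term id → gene set mapping over a gene universe."""

    sets: dict[str, set]
    universe: set

    def __post_init__(self) -> None:
        if not self.universe:
            raise ValueError("empty gene universe")
        for term, members in self.sets.items():
            if not members <= self.universe:
                raise ValueError(f"term {term!r} has genes outside the universe")


def hypergeometric_enrichment(
    query,
    collection: GeneSetCollection,
    p_cutoff: float = 0.05,
    adjust: bool = False,
) -> pd.DataFrame:
    """Test each term for over-representation in the query.

    Query genes outside the universe are dropped with a warning.  Returns
    a DataFrame (term, k, K, n, N, p[, q]) with rows at p < ``p_cutoff``
    (or q < cutoff when ``adjust``), sorted by p ascending, ties by term id.
    """
    query = set(query)
    if not query:
        raise ValueError("empty query")
    outside = query - collection.universe
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) outside the universe were dropped",
            stacklevel=2,
        )
        query &= collection.universe
    if not query:
        raise ValueError("no query genes inside the universe")

    N = len(collection.universe)
    n = len(query)
    rows = []
    for term in sorted(collection.sets):
        members = collection.sets[term]
        K = len(members)
        k = len(query & members)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, K, n, N, min(p, 1.0)))
    table = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    if adjust:
        table["q"] = bh_adjust(table["p"].to_numpy())
        table = table[table["q"] < p_cutoff]
    else:
        table = table[table["p"] < p_cutoff]
    return table.sort_values(["p", "term"], kind="stable").reset_index(drop=True)
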
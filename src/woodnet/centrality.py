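"""Network centrality, gene ranking, hub calling and node categories.

Hubs are the top 20% of genes ranked by betweenness (rank 1 = highest
value), the operational definition of candidate master regulators in the
wood-formation network.  Node categories combine high/low betweenness,
closeness and degree: center (high in all three), connecting (high BTW and
Cl, low degree), monopole (high BTW only) and edge (low BTW and degree).
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

CATEGORIES = ("center", "connecting", "monopole", "edge")


def betweenness(net: nx.Graph) -> dict[str, float]:
    """Unweighted shortest-path betweenness, pair-normalized to [0, 1].

    Equal-length shortest paths share credit fractionally (Brandes
    accumulation); the raw count is divided by (N-1)(N-2)/2, the number of
    ordered pairs of other nodes counted once per unordered pair.
    """
    if net.number_of_nodes() < 3:
        raise ValueError("betweenness needs at least 3 nodes")
    return nx.betweenness_centrality(net, normalized=True, weight=None)


def closeness(net: nx.Graph) -> dict[str, float]:
    """Closeness with the reachable-set correction for disconnected graphs.

    For node v reaching r other nodes at total distance S:
    ``cl(v) = (r / (N-1)) * (r / S)``; an isolated node scores 0.  On a
    connected graph this is the reciprocal of the mean distance to the
    other nodes.
    """
    n = net.number_of_nodes()
    if n < 2:
        raise ValueError("closeness needs at least 2 nodes")
    out: dict[str, float] = {}
    for v in net.nodes:
        dist = nx.single_source_shortest_path_length(net, v)
        r = len(dist) - 1
        s = sum(dist.values())
        out[v] = (r / (n - 1)) * (r / s) if r > 0 else 0.0
    return out


def degree(net: nx.Graph) -> dict[str, int]:
    """Number of incident edges per node (edge signs ignored)."""
    return dict(net.degree())


def rank_descending(values) -> np.ndarray:
    """Rank values with 1 = largest; ties share the minimum rank."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot rank an empty sequence")
    return rankdata(-arr, method="min").astype(int)


def centrality_table(net: nx.Graph, hub_fraction: float = 0.20,
                     high_quantile: float = 0.80) -> pd.DataFrame:
    """Per-gene centrality table: btw, cl, degree, ranks, hub flag, category."""
    nodes = list(net.nodes)
    btw = betweenness(net)
    cl = closeness(net)
    deg = degree(net)
    table = pd.DataFrame(
        {
            "btw": [btw[v] for v in nodes],
            "cl": [cl[v] for v in nodes],
            "degree": [deg[v] for v in nodes],
        },
        index=pd.Index(nodes, name="gene"),
    )
    table["btw_rank"] = rank_descending(table["btw"])
    table["cl_rank"] = rank_descending(table["cl"])
    hubs = call_hubs(table, fraction=hub_fraction)
    table["hub"] = table.index.isin(sorted(hubs))
    table["category"] = pd.Series(categorize_nodes(table, high_quantile))
    return table


def call_hubs(table: pd.DataFrame, fraction: float = 0.20) -> set[str]:
    """Genes whose betweenness rank is within the top ``fraction``.

    The cutoff rank is ``ceil(fraction * N)``; genes tied with the cutoff
    value are all included (boundary ties are never silently dropped).
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    if len(table) == 0:
        raise ValueError("empty centrality table")
    cutoff_rank = math.ceil(fraction * len(table))
    ranks = table["btw_rank"]
    inside = table.index[ranks <= cutoff_rank]
    cutoff_value = table.loc[inside, "btw"].min()
    return set(table.index[(ranks <= cutoff_rank) | (table["btw"] == cutoff_value)])


def categorize_nodes(table: pd.DataFrame, high_quantile: float = 0.80) -> dict[str, str]:
    """Assign each node one of center/connecting/monopole/edge.

    A metric is "high" when its value is >= the ``high_quantile`` quantile
    across nodes.  Canonical patterns (BTW, Cl, degree): center = (H,H,H),
    connecting = (H,H,L), monopole = (H,L,L), edge = low BTW and low degree
    (any Cl).  Remaining combinations go to the nearest pattern by Hamming
    distance, with ties broken by BTW-first priority
    center > connecting > monopole > edge.
    """
    cuts = {m: np.quantile(table[m].to_numpy(dtype=float), high_quantile)
            for m in ("btw", "cl", "degree")}
    high = {m: table[m].to_numpy(dtype=float) >= cuts[m] for m in cuts}

    # patterns: True=high, False=low, None=either
    patterns = {
        "center": (True, True, True),
        "connecting": (True, True, False),
        "monopole": (True, False, False),
        "edge": (False, None, False),
    }
    out: dict[str, str] = {}
    for idx, gene in enumerate(table.index):
        obs = (high["btw"][idx], high["cl"][idx], high["degree"][idx])
        best, best_d = None, None
        for cat in CATEGORIES:  # priority order
            d = sum(
                1
                for want, got in zip(patterns[cat], obs)
                if want is not None and want != got
            )
            if best_d is None or d < best_d:
                best, best_d = cat, d
        out[gene] = best
    return out
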
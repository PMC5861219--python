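"""Seed-gene co-expression modules and their composition.

A module is the first-order neighborhood of a seed gene in the thresholded
network — the seed, its direct neighbors at or above the co-expression
threshold, and all induced edges among those members — the per-seed view
used to study individual transcription-factor neighborhoods.  Members can
be flagged as hubs, ethylene-responsive genes, or transcription factors by
joining the centrality, response and annotation tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd


@dataclass
class GeneModule:
    """Seed-centred co-expression module."""

    seed: str
    members: set[str]
    edges: list[tuple[str, str, float, str]]  # (a, b, clr weight, sign)
    flags: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.seed not in self.members:
            raise ValueError("seed must be a member of its own module")
        for a, b, _, _ in self.edges:
            if a not in self.members or b not in self.members:
                raise ValueError("edge endpoint outside module members")


def extract_module(
    net: nx.Graph,
    seed: str,
    threshold: float = 5.0,
    order: int = 1,
    centrality: pd.DataFrame | None = None,
    response: pd.DataFrame | None = None,
    tf_table: pd.DataFrame | None = None,
) -> GeneModule:
    """Extract the seed's neighborhood module at the given threshold.

    ``order=1`` (default) takes direct neighbors with edge weight >=
    ``threshold``; ``order=2`` additionally includes the neighbors'
    neighbors.  Edges are all induced edges among members that reach the
    threshold.  Flag columns (hub / ethylene_responsive / tf_family) are
    joined from the optional tables when supplied and do not affect
    membership.
    """
    if seed not in net:
        raise KeyError(f"unknown seed gene {seed!r}")
    if order < 1:
        raise ValueError("order must be >= 1")

    members = {seed}
    frontier = {seed}
    for _ in range(order):
        nxt = set()
        for v in frontier:
            for u in net.neighbors(v):
                if net.edges[v, u]["clr"] >= threshold:
                    nxt.add(u)
        frontier = nxt - members
        members |= nxt

    edges = []
    for a, b, data in net.subgraph(members).edges(data=True):
        if data["clr"] >= threshold:
            x, y = sorted((a, b))
            edges.append((x, y, float(data["clr"]), data["sign"]))
    edges.sort()

    flags = None
    if centrality is not None or response is not None or tf_table is not None:
        idx = pd.Index(sorted(members), name="gene")
        flags = pd.DataFrame(index=idx)
        flags["hub"] = (
            centrality["hub"].reindex(idx, fill_value=False).astype(bool)
            if centrality is not None
            else False
        )
        flags["ethylene_responsive"] = (
            response["responsive"].reindex(idx, fill_value=False).astype(bool)
            if response is not None
            else False
        )
        flags["tf_family"] = (
            tf_table["family"].reindex(idx, fill_value="")
            if tf_table is not None
            else ""
        )
    return GeneModule(seed=seed, members=members, edges=edges, flags=flags)


def module_overlap(a: GeneModule, b: GeneModule) -> set[str]:
    """Genes shared by two modules, excluding the seeds themselves."""
    return (a.members - {a.seed}) & (b.members - {b.seed})


def module_summary(module: GeneModule) -> dict[str, int]:
    """Composition counts: members, TFs, hubs, responsive, +/- edges."""
    pos = sum(1 for *_, sign in module.edges if sign == "+")
    out = {
        "n_members": len(module.members),
        "n_edges": len(module.edges),
        "n_positive_edges": pos,
        "n_negative_edges": len(module.edges) - pos,
        "n_tfs": 0,
        "n_hubs": 0,
        "n_responsive": 0,
    }
    if module.flags is not None:
        out["n_tfs"] = int((module.flags["tf_family"] != "").sum())
        out["n_hubs"] = int(module.flags["hub"].sum())
        out["n_responsive"] = int(module.flags["ethylene_responsive"].sum())
    return out
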
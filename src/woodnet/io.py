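"""File formats of the pipeline.

All tabular files are TSV with a single header row and gene ids in the
first column; missing values are forbidden and fail fast.  Gene sets use
the GMT dialect (term, description, member genes, tab-separated).
Networks are exchanged as edge-list TSV (gene_a, gene_b, clr, sign) or
GraphML with fixed attribute names "clr" and "sign".
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .containers import CountExperiment, SectionSeries
from .enrich import GeneSetCollection
from .modules import GeneModule


def _read_tsv(path, index_col: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.isna().any().any():
        raise ValueError(f"missing values in {path}")
    return df.set_index(index_col)


def write_section_series(series: SectionSeries, expr_path, meta_path) -> None:
    series.values.rename_axis("gene").to_csv(expr_path, sep="\t")
    series.section_meta.rename_axis("section").to_csv(meta_path, sep="\t")


def read_section_series(expr_path, meta_path) -> SectionSeries:
    values = _read_tsv(expr_path, "gene").astype(float)
    meta = _read_tsv(meta_path, "section")
    meta["position"] = meta["position"].astype(int)
    return SectionSeries(values, meta)


def write_count_experiment(exp: CountExperiment, counts_path, meta_path) -> None:
    exp.counts.rename_axis("gene").to_csv(counts_path, sep="\t")
    exp.library_meta.rename_axis("library").to_csv(meta_path, sep="\t")


def read_count_experiment(counts_path, meta_path) -> CountExperiment:
    counts = _read_tsv(counts_path, "gene").astype(np.int64)
    meta = _read_tsv(meta_path, "library")
    meta["replicate"] = meta["replicate"].astype(int)
    return CountExperiment(counts, meta)


def write_gmt(collection: GeneSetCollection, path, descriptions: dict | None = None) -> None:
    descriptions = descriptions or {}
    with open(path, "w") as fh:
        for term in sorted(collection.sets):
            desc = descriptions.get(term, "na")
            members = "\t".join(sorted(collection.sets[term]))
            fh.write(f"{term}\t{desc}\t{members}\n")


def read_gmt(path, universe=None) -> GeneSetCollection:
    sets: dict[str, set] = {}
    seen: set = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"malformed GMT line: {line!r}")
            term, _desc, *genes = fields
            sets[term] = set(genes)
            seen |= sets[term]
    return GeneSetCollection(sets, set(universe) if universe is not None else seen)


def write_edge_list(net: nx.Graph, path) -> None:
    rows = sorted(
        (min(a, b), max(a, b), data["clr"], data["sign"])
        for a, b, data in net.edges(data=True)
    )
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "clr", "sign"]).to_csv(
        path, sep="\t", index=False
    )


def read_edge_list(path, nodes=None) -> nx.Graph:
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str, "sign": str})
    if df.isna().any().any():
        raise ValueError(f"missing values in {path}")
    net = nx.Graph()
    if nodes is not None:
        net.add_nodes_from(nodes)
    for row in df.itertuples(index=False):
        net.add_edge(row.gene_a, row.gene_b, clr=float(row.clr), sign=row.sign)
    return net


def write_graphml(net: nx.Graph, path) -> None:
    nx.write_graphml(net, path)


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)


def write_module_json(module: GeneModule, path) -> None:
    record = {
        "seed": module.seed,
        "members": sorted(module.members),
        "edges": [list(e) for e in module.edges],
        "flags": (
            {
                gene: {
                    "hub": bool(row["hub"]),
                    "ethylene_responsive": bool(row["ethylene_responsive"]),
                    "tf_family": str(row["tf_family"]),
                }
                for gene, row in module.flags.iterrows()
            }
            if module.flags is not None
            else None
        ),
    }
    Path(path).write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")


def read_module_json(path) -> GeneModule:
    record = json.loads(Path(path).read_text())
    flags = None
    if record.get("flags") is not None:
        flags = pd.DataFrame.from_dict(record["flags"], orient="index")
        flags.index.name = "gene"
        flags = flags.sort_index()
    return GeneModule(
        seed=record["seed"],
        members=set(record["members"]),
        edges=[(a, b, float(w), s) for a, b, w, s in record["edges"]],
        flags=flags,
    )


def write_ground_truth(truth: dict, path) -> None:
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")


def read_ground_truth(path) -> dict:
    return json.loads(Path(path).read_text())


def write_linkage_json(assignment, path) -> None:
    record = {
        "items": list(assignment.items),
        "labels": [int(v) for v in assignment.labels],
        "linkage": [[float(v) for v in row] for row in assignment.linkage],
    }
    Path(path).write_text(json.dumps(record, indent=2) + "\n")
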
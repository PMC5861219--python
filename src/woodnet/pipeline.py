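"""End-to-end pipeline: simulate → prep → network → centrality → modules
→ differential expression → enrichment, with a JSON summary.

Every stage writes its output files into the run directory, and the
summary records the hub list, per-seed module membership, the
ethylene-responsive gene list and the enrichment tables.  With a fixed
seed the whole run is deterministic down to the bytes of the summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from . import __version__, centrality, enrich, io, modules, network, prep, response, simulate

log = logging.getLogger("woodnet")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass
class PipelineConfig:
    """All stage parameters plus input/output paths.

    Defaults are the analysis conditions used throughout: VST > 3
    expression filter, network threshold 5, top-20% hub rule, q < 0.01 and
    two-fold criteria for the responsive-gene caller, enrichment reporting
    at raw p < 0.05.
    """

    seed: int = 1
    out_dir: str = "woodnet_run"
    simulate: bool = True
    # external inputs (used when simulate is False)
    expression: str | None = None
    section_meta: str | None = None
    counts: str | None = None
    library_meta: str | None = None
    gene_sets: str | None = None
    seeds_file: str | None = None
    # stage parameters
    vst_threshold: float = 3.0
    min_samples: int = 2
    min_trees: int = 3
    bins: int | None = None
    network_threshold: float = 5.0
    hub_fraction: float = 0.20
    high_quantile: float = 0.80
    module_order: int = 1
    min_count: int = 10
    filter_mode: str = "all_libraries"
    fc_threshold: float = 1.0
    q_threshold: float = 0.01
    delta_threshold: float = 1.0
    enrichment_p: float = 0.05

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - reported with stage name
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and return the summary dict.

    Outputs land in ``config.out_dir``; the summary is also written there
    as ``summary.json`` (sorted keys, stable float formatting).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        log.info("woodnet %s seed=%d parameters=%s", __version__, config.seed, config.to_dict())
        summary = _run(config, out)
    finally:
        log.removeHandler(handler)
        handler.close()

    text = json.dumps(summary, indent=2, sort_keys=True)
    (out / "summary.json").write_text(text + "\n")
    return summary


@_stage("simulate")
def _simulate_inputs(config: PipelineConfig, out: Path):
    sim = simulate.default_config(seed=config.seed)
    series, truth = simulate.generate_section_series(sim)
    csim = simulate.default_count_config(seed=config.seed)
    exp, count_truth = simulate.generate_count_experiment(csim)
    planted = {
        f"MODULE{i + 1}_TERM": mod["members"] for i, mod in enumerate(truth["modules"])
    }
    collection, tf_table = simulate.generate_annotation(
        config.seed, series.genes, planted=planted
    )
    io.write_section_series(series, out / "expression.tsv", out / "sections.tsv")
    io.write_count_experiment(exp, out / "counts.tsv", out / "libraries.tsv")
    io.write_gmt(collection, out / "gene_sets.gmt")
    tf_table.to_csv(out / "tf_families.tsv", sep="\t")
    io.write_ground_truth(
        {"sections": truth, "counts": count_truth}, out / "ground_truth.json"
    )
    seeds = truth["hubs"]
    return series, exp, collection, tf_table, seeds


@_stage("load")
def _load_inputs(config: PipelineConfig, out: Path):
    for name in ("expression", "section_meta", "counts", "library_meta"):
        path = getattr(config, name)
        if path is None or not Path(path).exists():
            raise FileNotFoundError(f"required input {name!r} missing: {path}")
    series = io.read_section_series(config.expression, config.section_meta)
    exp = io.read_count_experiment(config.counts, config.library_meta)
    collection = io.read_gmt(config.gene_sets) if config.gene_sets else None
    seeds = (
        Path(config.seeds_file).read_text().split() if config.seeds_file else []
    )
    return series, exp, collection, None, seeds


def _run(config: PipelineConfig, out: Path) -> dict:
    if config.simulate:
        series, exp, collection, tf_table, seeds = _simulate_inputs(config, out)
    else:
        series, exp, collection, tf_table, seeds = _load_inputs(config, out)

    filtered = _prep(config, series, out)
    net = _network(config, filtered, out)
    cent = _centrality(config, net, out)
    resp = _de(config, exp, out)
    mods = _modules(config, net, seeds, cent, resp, tf_table, out)
    enrichment = _enrich(config, filtered, collection, mods, out)

    hubs = sorted(cent.index[cent["hub"]])
    responsive = sorted(resp.index[resp["responsive"]])
    # paths are excluded so identical analyses yield identical summaries
    params = {
        k: v
        for k, v in config.to_dict().items()
        if k not in {"out_dir", "expression", "section_meta", "counts",
                     "library_meta", "gene_sets", "seeds_file"}
    }
    summary = {
        "seed": config.seed,
        "parameters": params,
        "n_genes_input": len(series.genes),
        "n_genes_filtered": len(filtered.genes),
        "n_edges": net.number_of_edges(),
        "n_hubs": len(hubs),
        "hubs": hubs,
        "modules": {m.seed: sorted(m.members) for m in mods},
        "n_responsive": len(responsive),
        "responsive_genes": responsive,
        "enrichment": enrichment,
    }
    return summary


@_stage("prep")
def _prep(config, series, out: Path):
    filtered = prep.filter_expressed(
        series,
        vst_threshold=config.vst_threshold,
        min_samples=config.min_samples,
        min_trees=config.min_trees,
    )
    log.info("filter_expressed kept %d/%d genes", len(filtered.genes), len(series.genes))
    scaled = prep.scale_per_gene(filtered)
    io.write_section_series(scaled, out / "expression.scaled.tsv", out / "sections.meta.tsv")
    return filtered

@_stage("network")
def _network(config, filtered, out: Path):
    mi = network.mi_matrix(filtered, bins=config.bins)
    clr = network.clr_transform(mi)
    net = network.build_network(clr, filtered, threshold=config.network_threshold)
    io.write_edge_list(net, out / "edges.tsv")
    io.write_graphml(net, out / "network.graphml")
    log.info("network: %d nodes, %d edges", net.number_of_nodes(), net.number_of_edges())
    return net

@_stage("centrality")
def _centrality(config, net, out: Path):
    cent = centrality.centrality_table(
        net, hub_fraction=config.hub_fraction, high_quantile=config.high_quantile
    )
    cent.to_csv(out / "centrality.tsv", sep="\t")
    return cent

@_stage("de")
def _de(config, exp, out: Path):
    resp = response.response_table(
        exp, min_count=config.min_count, filter_mode=config.filter_mode
    )
    resp["responsive"] = response.call_ethylene_responsive(
        resp,
        fc_threshold=config.fc_threshold,
        q_threshold=config.q_threshold,
        delta_threshold=config.delta_threshold,
    )
    resp.to_csv(out / "response.tsv", sep="\t")
    return resp

@_stage("modules")
def _modules(config, net, seeds, cent, resp, tf_table, out: Path):
    mods = []
    for seed_gene in seeds:
        if seed_gene not in net:
            raise KeyError(f"module seed {seed_gene!r} not in network")
        m = modules.extract_module(
            net,
            seed_gene,
            threshold=config.network_threshold,
            order=config.module_order,
            centrality=cent,
            response=resp,
            tf_table=tf_table,
        )
        io.write_module_json(m, out / f"module_{seed_gene}.json")
        mods.append(m)
    return mods

@_stage("enrich")
def _enrich(config, filtered, collection, mods, out: Path):
    if collection is None:
        return {}
    universe = set(filtered.genes) & collection.universe
    trimmed = enrich.GeneSetCollection(
        {t: s & universe for t, s in collection.sets.items()}, universe
    )
    result = {}
    for m in mods:
        query = m.members & universe
        if not query:
            result[m.seed] = []
            continue
        table = enrich.hypergeometric_enrichment(query, trimmed, p_cutoff=config.enrichment_p)
        table.to_csv(out / f"enrichment_{m.seed}.tsv", sep="\t", index=False)
        result[m.seed] = [
            {
                "term": row.term,
                "k": int(row.k),
                "K": int(row.K),
                "n": int(row.n),
                "N": int(row.N),
                "p": round(float(row.p), 15),
            }
            for row in table.itertuples(index=False)
        ]
    return result
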
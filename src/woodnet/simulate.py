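"""Synthetic data generators with planted ground truth.

The generators emulate the two study designs the pipeline analyses:

* a high-spatial-resolution section series across the developmental zones
  of wood formation in several trees, with planted co-expression modules,
  designated hub genes and anticorrelated members
  (:func:`generate_section_series`);
* a 3-genotype × 2-treatment RNA-Seq count experiment with planted
  ethylene responders whose induction is confined to wild-type ACC
  libraries (:func:`generate_count_experiment`);
* gene-set annotations (GMT) with terms planted to over-represent chosen
  modules, plus a transcription-factor family table
  (:func:`generate_annotation`).

All randomness flows from one explicit seed per config through a single
``numpy.random.Generator``; the same config therefore yields byte-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GENOTYPES, TREATMENTS, ZONES, CountExperiment, SectionSeries

#: Sections per zone per tree, mirroring the relative widths of the
#: phloem/cambium, expansion, secondary-wall and cell-death zones in a
#: typical aspen cryosection series (~25 sections per tree).
DEFAULT_SECTIONS_PER_ZONE = {"P/C": 5, "Ex": 4, "SCW": 9, "CD": 7}


@dataclass
class PlantedModule:
    """Ground-truth co-expression module planted into a section series.

    Every member tracks the module signal — a zone-centred expression
    bump plus a module-level per-section covariation shared by all
    members — scaled by ``coupling``.  The hub carries the signal at
    ``hub_gain`` times the member amplitude with only the baseline noise
    level, so it is the least corrupted reporter of the module signal:
    its mutual information with every member systematically tops both
    genes' MI backgrounds, making the hub the best-connected, most
    central node of its module.  Ordinary members additionally carry
    gene-specific expression variability (see
    ``SimulationConfig.member_noise_scale``).  ``anticorrelated_members``
    follow the negated signal, shifted up so they stay expressed.
    """

    hub_gene: str
    member_genes: list[str]
    peak_zone: str
    anticorrelated_members: list[str] = field(default_factory=list)
    coupling: float = 0.9
    hub_gain: float = 2.0

    def __post_init__(self) -> None:
        if self.hub_gene not in self.member_genes:
            raise ValueError("hub_gene must be one of member_genes")
        if not set(self.anticorrelated_members) <= set(self.member_genes):
            raise ValueError("anticorrelated_members must be a subset of member_genes")
        if not 0 < self.coupling <= 1:
            raise ValueError("coupling must lie in (0, 1]")
        if self.peak_zone not in ZONES:
            raise ValueError(f"unknown zone label {self.peak_zone!r}")


@dataclass
class SimulationConfig:
    """Configuration of the section-series generator."""

    seed: int = 1
    n_genes: int = 300
    n_trees: int = 4
    sections_per_zone: dict = field(
        default_factory=lambda: dict(DEFAULT_SECTIONS_PER_ZONE)
    )
    modules: list[PlantedModule] = field(default_factory=list)
    noise_sd: float = 0.3
    baseline_mean: float = 4.0
    baseline_sd: float = 0.5
    archetype_amplitude: float = 4.0
    module_covariation_sd: float = 4.0
    member_noise_scale: float = 3.5

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        unknown = set(self.sections_per_zone) - set(ZONES)
        if unknown:
            raise ValueError(f"unknown zone label(s): {sorted(unknown)}")
        for zone in ZONES:
            if self.sections_per_zone.get(zone, 0) < 1:
                raise ValueError(f"every zone needs >= 1 section ({zone} has none)")
        total = sum(len(m.member_genes) for m in self.modules)
        if total > self.n_genes:
            raise ValueError("module sizes sum exceeds n_genes")


def config_from_dict(data: dict) -> SimulationConfig:
    """Build a SimulationConfig from a plain dict (YAML/JSON-friendly).

    ``modules`` entries are dicts with PlantedModule fields.  Unknown
    keys are rejected.
    """
    from dataclasses import fields as dc_fields

    data = dict(data)
    mods = [
        m if isinstance(m, PlantedModule) else PlantedModule(**m)
        for m in data.pop("modules", [])
    ]
    known = {f.name for f in dc_fields(SimulationConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return SimulationConfig(modules=mods, **data)


def count_config_from_dict(data: dict) -> CountSimConfig:
    """Build a CountSimConfig from a plain dict; unknown keys rejected."""
    from dataclasses import fields as dc_fields

    known = {f.name for f in dc_fields(CountSimConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return CountSimConfig(**data)


def default_config(seed: int = 1, anticorrelated: int = 0) -> SimulationConfig:
    """Default study conditions: 300 genes, 3 modules of 20 with designated
    hubs peaking in distinct zones, noise_sd 0.3, coupling 0.9.

    ``anticorrelated`` flips that many members per module to the negated
    module signal (0 by default; signed-edge analyses set it > 0).
    """
    modules = []
    for m, zone in enumerate(("P/C", "SCW", "CD")):
        members = [f"G{m * 20 + i + 1:04d}" for i in range(20)]
        modules.append(
            PlantedModule(
                hub_gene=members[0],
                member_genes=members,
                peak_zone=zone,
                anticorrelated_members=members[-anticorrelated:] if anticorrelated else [],
            )
        )
    return SimulationConfig(seed=seed, modules=modules)


def _gene_ids(n: int) -> list[str]:
    return [f"G{i + 1:04d}" for i in range(n)]


def _zone_layout(sections_per_zone: dict) -> tuple[list[str], dict[str, np.ndarray]]:
    """Zone label per within-tree position, plus position indices per zone."""
    labels: list[str] = []
    for zone in ZONES:
        labels.extend([zone] * sections_per_zone[zone])
    index = {zone: np.flatnonzero(np.array(labels) == zone) for zone in ZONES}
    return labels, index


def _archetype(peak_zone: str, sections_per_zone: dict, amplitude: float) -> np.ndarray:
    """Smooth Gaussian bump over within-tree section index, centred on the
    peak zone and as wide as the zone itself."""
    labels, index = _zone_layout(sections_per_zone)
    pos = np.arange(len(labels), dtype=float)
    zone_pos = index[peak_zone]
    centre = zone_pos.mean()
    width = max(len(zone_pos) / 2.0, 1.0)
    return amplitude * np.exp(-0.5 * ((pos - centre) / width) ** 2)


def generate_section_series(config: SimulationConfig):
    """Simulate a section series with planted modules.

    Returns
    -------
    (SectionSeries, dict)
        The expression container and a JSON-serializable ground-truth
        record listing module membership, hub ids, peak zones and
        anticorrelated members.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    gene_set = set(genes)
    for mod in config.modules:
        unknown = set(mod.member_genes) - gene_set
        if unknown:
            raise ValueError(f"module members outside gene universe: {sorted(unknown)}")

    zone_labels, _ = _zone_layout(config.sections_per_zone)
    per_tree = len(zone_labels)
    trees = [f"T{i + 1}" for i in range(config.n_trees)]
    section_ids = [f"{t}.{p + 1:02d}" for t in trees for p in range(per_tree)]
    meta = pd.DataFrame(
        {
            "tree": [t for t in trees for _ in range(per_tree)],
            "zone": zone_labels * config.n_trees,
            "position": list(range(1, per_tree + 1)) * config.n_trees,
        },
        index=pd.Index(section_ids, name="section"),
    )

    n_sections = per_tree * config.n_trees

    # module signal = zone-peaked bump (repeated per tree) + module-level
    # per-section covariation shared by all members.  The covariation
    # carries most of the within-module dependence; keeping it off the
    # positional axis prevents unrelated modules from becoming mutually
    # informative through the shared section coordinate.
    signals = {}
    for mod in config.modules:
        bump = _archetype(mod.peak_zone, config.sections_per_zone, config.archetype_amplitude)
        covariation = rng.normal(0.0, config.module_covariation_sd, size=n_sections)
        signals[id(mod)] = np.tile(bump, config.n_trees) + covariation

    values = np.empty((config.n_genes, n_sections))
    baselines = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)
    noise = rng.normal(0.0, 1.0, size=(config.n_genes, n_sections))

    gene_row = {g: i for i, g in enumerate(genes)}
    # members carry gene-specific variability on top of the baseline
    # technical noise; the hub reports the module signal at baseline noise
    member_noise_sd = config.noise_sd * np.sqrt(1.0 + config.member_noise_scale**2)
    in_module = set()
    for mod in config.modules:
        sig = signals[id(mod)]
        for g in mod.member_genes:
            in_module.add(g)
            row = gene_row[g]
            base_sig = sig
            if g in mod.anticorrelated_members:
                # negated signal, shifted up so the gene stays expressed
                base_sig = config.archetype_amplitude - sig
            if g == mod.hub_gene:
                profile = mod.hub_gain * mod.coupling * base_sig
                sd = config.noise_sd
            else:
                profile = mod.coupling * base_sig
                sd = member_noise_sd
            values[row] = baselines[row] + profile + sd * noise[row]

    for g in genes:
        if g not in in_module:
            row = gene_row[g]
            values[row] = baselines[row] + config.noise_sd * noise[row]

    series = SectionSeries(
        pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=section_ids),
        meta,
    )
    truth = {
        "modules": [
            {
                "hub": mod.hub_gene,
                "members": list(mod.member_genes),
                "peak_zone": mod.peak_zone,
                "anticorrelated": list(mod.anticorrelated_members),
            }
            for mod in config.modules
        ],
        "hubs": [mod.hub_gene for mod in config.modules],
    }
    return series, truth


@dataclass
class CountSimConfig:
    """Configuration of the factorial count-experiment generator.

    Counts are negative binomial with variance mu + dispersion * mu^2
    (gamma–Poisson mixture).  Planted responders get their mean multiplied
    by ``2**responder_log2fc`` in wild-type ACC libraries only; the
    ethylene-insensitive genotypes never respond.
    """

    seed: int = 1
    n_genes: int = 2000
    n_replicates: int = 3
    dispersion: float = 0.05
    responder_genes: list[str] = field(default_factory=list)
    responder_log2fc: float = 2.0
    baseline_mean: float = 200.0
    baseline_log_sd: float = 0.6
    library_size_cv: float = 0.2
    library_size_mean: float | None = None

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.dispersion < 0:
            raise ValueError("dispersion must be nonnegative")


def default_count_config(seed: int = 1, responder_fraction: float = 0.05) -> CountSimConfig:
    """Default study conditions: 2,000 genes, 3 replicates per cell,
    dispersion 0.05, 5% planted WT-only responders at |log2FC| = 2."""
    n_genes = 2000
    n_resp = int(round(responder_fraction * n_genes))
    rng = np.random.default_rng(seed + 10_000)
    responders = sorted(
        rng.choice(_gene_ids(n_genes), size=n_resp, replace=False).tolist()
    )
    return CountSimConfig(seed=seed, n_genes=n_genes, responder_genes=responders)


def generate_count_experiment(config: CountSimConfig):
    """Simulate the 3 genotypes × 2 treatments × n replicates design.

    Returns ``(CountExperiment, truth)`` where truth records the responder
    gene list and the planted log2 fold change.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    unknown = set(config.responder_genes) - set(genes)
    if unknown:
        raise ValueError(f"responder genes outside gene universe: {sorted(unknown)}")

    lib_rows = []
    for g in GENOTYPES:
        for t in TREATMENTS:
            for r in range(1, config.n_replicates + 1):
                lib_rows.append((f"{g}.{t}.r{r}", g, t, r))
    lib_ids = [r[0] for r in lib_rows]
    meta = pd.DataFrame(
        {
            "genotype": [r[1] for r in lib_rows],
            "treatment": [r[2] for r in lib_rows],
            "replicate": [r[3] for r in lib_rows],
        },
        index=pd.Index(lib_ids, name="library"),
    )

    # per-gene base abundance (log-normal around baseline_mean)
    log_mu = rng.normal(np.log(config.baseline_mean), config.baseline_log_sd, config.n_genes)
    base_mu = np.exp(log_mu)

    # per-library depth factors (log-normal, mean 1, given CV)
    cv = config.library_size_cv
    sigma2 = np.log1p(cv**2)
    depth = rng.lognormal(-sigma2 / 2.0, np.sqrt(sigma2), size=len(lib_ids))
    if config.library_size_mean is not None:
        depth *= config.library_size_mean / base_mu.sum()

    responder_mask = np.isin(genes, list(config.responder_genes))
    wt_acc = ((meta["genotype"] == "WT") & (meta["treatment"] == "ACC")).to_numpy()

    mu = base_mu[:, None] * depth[None, :]
    mu[np.ix_(responder_mask, wt_acc)] *= 2.0**config.responder_log2fc

    if config.dispersion > 0:
        shape = 1.0 / config.dispersion
        lam = rng.gamma(shape, mu / shape)
    else:
        lam = mu
    counts = rng.poisson(lam)

    exp = CountExperiment(
        pd.DataFrame(counts.astype(np.int64), index=pd.Index(genes, name="gene"), columns=lib_ids),
        meta,
    )
    truth = {
        "responders": sorted(config.responder_genes),
        "log2fc": config.responder_log2fc,
    }
    return exp, truth


#: Transcription-factor families seen among wood-formation regulators.
TF_FAMILIES = ("NAC", "MYB", "ERF", "EIN3", "WRKY", "bZIP", "C2H2", "GRAS")


def generate_annotation(
    seed: int,
    genes,
    n_terms: int = 20,
    planted: dict | None = None,
    base_rate: float = 0.05,
    odds_factor: float = 10.0,
    tf_fraction: float = 0.08,
):
    """Generate a gene-set collection plus a TF-family table.

    Parameters
    ----------
    planted
        Map term id → gene list; members of a planted term's gene list are
        annotated with that term with probability
        ``min(1, base_rate * odds_factor)`` while all other genes get it at
        ``base_rate``.  ``odds_factor=1`` is the null (no enrichment).

    Returns
    -------
    (GeneSetCollection, DataFrame)
        The collection (universe = ``genes``) and a table mapping each TF
        gene to its family.
    """
    from .enrich import GeneSetCollection

    genes = list(genes)
    if not genes:
        raise ValueError("empty gene universe")
    planted = dict(planted or {})
    rng = np.random.default_rng(seed)

    term_ids = [f"TERM{i + 1:03d}" for i in range(n_terms)]
    for t in planted:
        if t not in term_ids:
            term_ids.append(t)

    arr = np.array(genes)
    sets: dict[str, set] = {}
    p_in = min(1.0, base_rate * odds_factor)
    for term in term_ids:
        draw = rng.random(len(genes))
        keep = draw < base_rate
        if term in planted:
            target = np.isin(arr, list(planted[term]))
            keep = np.where(target, draw < p_in, keep)
        sets[term] = set(arr[keep])

    n_tf = int(round(tf_fraction * len(genes)))
    tf_genes = sorted(rng.choice(arr, size=n_tf, replace=False).tolist())
    families = rng.choice(TF_FAMILIES, size=n_tf)
    tf_table = pd.DataFrame(
        {"family": families}, index=pd.Index(tf_genes, name="gene")
    )
    return GeneSetCollection(sets, set(genes)), tf_table
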
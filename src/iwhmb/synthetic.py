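"""Synthetic cohorts with the statistical structure every pipeline stage assumes.

A cohort consists of: a scale-free gene interaction network (plus a handful
of directed TF -> target edges); gene sets sampled from the universe;
per-sample somatic mutations with a lognormal global-rate confound and
subtype-specific enrichment inside designated gene sets; an expression
matrix in which planted score-related genes respond linearly to the
pipeline's own pathway scores; a planted co-expressed progression module
driven by a shared latent factor; designated immune genes; and planted
bridge genes wired to both the progression module and the immune genes.
Gene-level copy-number calls are drawn independently.

Everything is reproducible from the seed, and the ground truth (subtype
labels, planted coefficients, module/immune/bridge gene lists) is carried
alongside the data so recovery can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import io_formats, network, scoring
from .io_formats import (
    GeneSetCollection,
    InteractionNetwork,
    MutationProfile,
)

__all__ = ["SyntheticCohortConfig", "SyntheticCohort", "generate", "toy_fixture"]


@dataclass
class SyntheticCohortConfig:
    """Knobs of the generator; defaults define the standard study conditions."""

    n_samples: int = 300
    n_genes: int = 2000
    n_sets: int = 24
    set_size_min: int = 30
    set_size_max: int = 60
    set_overlap_fraction: float = 0.1  # per-set budget of genes shared with earlier sets
    attachment: int = 3  # scale-free preferential-attachment edges per node
    n_tf_edges: int = 200
    n_subtypes: int = 4
    sets_per_subtype: int = 6
    enrichment_multiplier: float = 8.0
    background_rate: float = 0.02  # per-gene mutation probability baseline
    tmb_log_sd: float = 0.6  # lognormal sd of the per-sample global rate
    n_planted_irgs: int = 200
    coef_min: float = 0.3
    coef_max: float = 0.9
    expression_noise_sd: float = 0.5
    n_module_genes: int = 50
    module_noise_sd: float = 0.3
    n_immune_genes: int = 40
    n_planted_bridges: int = 30
    bridge_edges_per_side: int = 3
    seed: int = 0

    def validate(self) -> None:
        counts = (
            self.n_samples, self.n_genes, self.n_sets, self.set_size_min,
            self.set_size_max, self.n_subtypes, self.sets_per_subtype,
            self.n_planted_irgs, self.n_module_genes, self.n_immune_genes,
            self.n_planted_bridges,
        )
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        if not 0 < self.background_rate < 1:
            raise ValueError("background_rate must be in (0, 1)")
        if self.set_size_max > self.n_genes:
            raise ValueError("set sizes exceed the gene universe")
        if self.sets_per_subtype * self.n_subtypes > self.n_sets:
            raise ValueError("not enough gene sets for the requested subtypes")
        needed = self.n_planted_irgs + self.n_module_genes + self.n_immune_genes + self.n_planted_bridges
        if needed > self.n_genes:
            raise ValueError("planted gene groups exceed the gene universe")


@dataclass
class SyntheticCohort:
    """A generated cohort plus its ground truth."""

    config: SyntheticCohortConfig
    profiles: list[MutationProfile]
    sets: GeneSetCollection
    net: InteractionNetwork
    expression: pd.DataFrame
    cnv: pd.DataFrame
    subtype_labels: pd.Series  # sample -> 1..n_subtypes
    enriched_sets: dict[int, list[str]]  # subtype -> enriched set names
    irg_coefficients: dict[str, dict[str, float]]  # gene -> {set: beta}
    module_genes: list[str] = field(default_factory=list)
    immune_genes: list[str] = field(default_factory=list)
    bridge_genes: list[str] = field(default_factory=list)
    latent_factor: pd.Series | None = None
    sample_rates: pd.Series | None = None
    iwhmb: pd.DataFrame | None = None
    whmb: pd.DataFrame | None = None

    @property
    def samples(self) -> list[str]:
        return list(self.expression.columns)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write the cohort as plain-text files plus a ground-truth JSON."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "maf": out / "cohort.maf",
            "gmt": out / "sets.gmt",
            "edges": out / "ppi_edges.tsv",
            "tf_edges": out / "tf_edges.tsv",
            "expression": out / "expression.tsv",
            "cnv": out / "cnv.tsv",
            "truth": out / "truth.json",
        }
        io_formats.write_maf(self.profiles, paths["maf"])
        io_formats.write_gmt(self.sets, paths["gmt"])
        io_formats.write_edge_list(
            InteractionNetwork(self.net.graph, provenance=self.net.provenance),
            paths["edges"],
        )
        io_formats.write_edge_list(
            InteractionNetwork(nx.Graph(), directed=self.net.directed or nx.DiGraph()),
            paths["tf_edges"],
        )
        io_formats.write_matrix(self.expression, paths["expression"])
        io_formats.write_matrix(self.cnv, paths["cnv"])
        truth = {
            "config": asdict(self.config),
            "subtype_labels": {s: int(v) for s, v in self.subtype_labels.items()},
            "enriched_sets": {str(k): v for k, v in self.enriched_sets.items()},
            "irg_coefficients": self.irg_coefficients,
            "module_genes": self.module_genes,
            "immune_genes": self.immune_genes,
            "bridge_genes": self.bridge_genes,
        }
        paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True))
        return paths


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"G{i:0{width}d}" for i in range(n)]


def _snowball_sample(
    graph: nx.Graph,
    genes: list[str],
    size: int,
    rng: np.random.Generator,
    used: set[str],
    overlap_fraction: float,
) -> list[str]:
    """Grow a gene set as a random connected neighborhood of the network.

    Genes already claimed by earlier sets are admitted only up to an
    overlap budget of ``overlap_fraction * size``, so sets are connected
    modules with controlled pairwise overlap.
    """
    fresh_genes = [g for g in genes if g not in used]
    start = str(rng.choice(fresh_genes)) if fresh_genes else str(rng.choice(genes))
    members = [start]
    member_set = {start}
    budget = int(round(overlap_fraction * size)) - (start in used)
    frontier = set(graph.neighbors(start)) - member_set
    while len(members) < size:
        fresh = sorted(g for g in frontier if g not in used)
        reused = sorted(g for g in frontier if g in used)
        if fresh:
            nxt = str(rng.choice(fresh))
        elif reused and budget > 0:
            nxt = str(rng.choice(reused))
            budget -= 1
        else:  # surrounded by claimed genes: jump to a fresh random node
            candidates = [g for g in genes if g not in member_set and g not in used]
            if not candidates:
                candidates = [g for g in genes if g not in member_set]
            nxt = str(rng.choice(candidates))
        members.append(nxt)
        member_set.add(nxt)
        frontier |= set(graph.neighbors(nxt))
        frontier -= member_set
    return members


def generate(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Generate a full cohort (see module docstring for the data model)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config.n_genes)
    samples = [f"S{i:04d}" for i in range(config.n_samples)]

    # (i) scale-free interaction network over the universe
    ba_seed = int(rng.integers(0, 2**31 - 1))
    skeleton = nx.barabasi_albert_graph(config.n_genes, config.attachment, seed=ba_seed)
    graph = nx.relabel_nodes(skeleton, dict(enumerate(genes)))
    directed = nx.DiGraph()
    while directed.number_of_edges() < config.n_tf_edges:
        a, b = rng.choice(config.n_genes, size=2, replace=False)
        directed.add_edge(genes[int(a)], genes[int(b)])

    # designated gene groups (disjoint) for downstream planting
    shuffled = list(rng.permutation(genes))
    irg_genes = shuffled[: config.n_planted_irgs]
    offset = config.n_planted_irgs
    module_genes = shuffled[offset : offset + config.n_module_genes]
    offset += config.n_module_genes
    immune_genes = shuffled[offset : offset + config.n_immune_genes]
    offset += config.n_immune_genes
    bridge_genes = shuffled[offset : offset + config.n_planted_bridges]

    # (v) wire bridges to both the progression module and the immune genes
    for bridge in bridge_genes:
        for target in rng.choice(module_genes, size=min(config.bridge_edges_per_side, len(module_genes)), replace=False):
            graph.add_edge(bridge, str(target))
        for target in rng.choice(immune_genes, size=min(config.bridge_edges_per_side, len(immune_genes)), replace=False):
            graph.add_edge(bridge, str(target))
    net = InteractionNetwork(graph, directed=directed, provenance=("synthetic-ppi", "synthetic-tf"))

    # (ii) network-coherent gene sets: grown as random neighborhoods so the
    # induced subnetworks are connected modules (as curated pathways are on
    # real interaction networks); overlap arises naturally via shared hubs
    set_names = [f"SET_{i:02d}" for i in range(config.n_sets)]
    sets = {}
    used: set[str] = set()
    for name in set_names:
        size = int(rng.integers(config.set_size_min, config.set_size_max + 1))
        sets[name] = _snowball_sample(
            graph, genes, size, rng, used, config.set_overlap_fraction
        )
        used.update(sets[name])
    collection = GeneSetCollection(sets, source="synthetic")

    # subtype assignment and the sets each subtype enriches
    subtype = pd.Series(
        rng.integers(1, config.n_subtypes + 1, size=config.n_samples),
        index=samples, name="subtype",
    )
    enriched: dict[int, list[str]] = {}
    cursor = 0
    for s in range(1, config.n_subtypes + 1):
        enriched[s] = set_names[cursor : cursor + config.sets_per_subtype]
        cursor += config.sets_per_subtype

    # (iii) mutations: lognormal global-rate confound x subtype enrichment
    log_rates = rng.normal(0.0, config.tmb_log_sd, size=config.n_samples)
    rates = config.background_rate * np.exp(log_rates)
    gene_index = {g: i for i, g in enumerate(genes)}
    enriched_mask = {}
    for s, names in enriched.items():
        mask = np.zeros(config.n_genes, dtype=bool)
        for name in names:
            mask[[gene_index[g] for g in sets[name]]] = True
        enriched_mask[s] = mask
    profiles = []
    for j, sample in enumerate(samples):
        prob = np.full(config.n_genes, rates[j])
        prob[enriched_mask[int(subtype[sample])]] *= config.enrichment_multiplier
        np.clip(prob, 0.0, 0.95, out=prob)
        mutated = rng.random(config.n_genes) < prob
        counts = {genes[i]: 1 for i in np.nonzero(mutated)[0]}
        profiles.append(MutationProfile(sample, counts))

    # (iv) pathway scores by the pipeline itself, on the global network
    table = network.centrality_table(net, collection)
    whmb = scoring.compute_whmb(profiles, collection, table, net, samples=samples)
    iwhmb = scoring.compute_iwhmb(whmb)

    # expression: planted responders track the scores, the rest is noise
    expression = pd.DataFrame(
        rng.normal(0.0, 1.0, size=(config.n_genes, config.n_samples)),
        index=genes, columns=samples,
    )
    irg_coefficients: dict[str, dict[str, float]] = {}
    for gene in irg_genes:
        n_targets = int(rng.integers(1, 4))
        targets = [str(t) for t in rng.choice(set_names, size=n_targets, replace=False)]
        betas = {}
        signal = np.zeros(config.n_samples)
        for target in targets:
            beta = float(rng.uniform(config.coef_min, config.coef_max)) * (
                1.0 if rng.random() < 0.5 else -1.0
            )
            betas[target] = beta
            signal += beta * iwhmb.loc[target].to_numpy()
        expression.loc[gene] = signal + rng.normal(
            0.0, config.expression_noise_sd, size=config.n_samples
        )
        irg_coefficients[gene] = betas
    latent = pd.Series(rng.normal(0.0, 1.0, size=config.n_samples), index=samples, name="latent")
    for gene in module_genes:
        loading = float(rng.uniform(0.7, 1.3))
        expression.loc[gene] = loading * latent.to_numpy() + rng.normal(
            0.0, config.module_noise_sd, size=config.n_samples
        )

    cnv = pd.DataFrame(
        rng.choice([-1, 0, 1], p=[0.1, 0.8, 0.1], size=(config.n_genes, config.n_samples)),
        index=genes, columns=samples,
    )

    return SyntheticCohort(
        config=config,
        profiles=profiles,
        sets=collection,
        net=net,
        expression=expression,
        cnv=cnv,
        subtype_labels=subtype,
        enriched_sets=enriched,
        irg_coefficients=irg_coefficients,
        module_genes=[str(g) for g in module_genes],
        immune_genes=[str(g) for g in immune_genes],
        bridge_genes=[str(g) for g in bridge_genes],
        latent_factor=latent,
        sample_rates=pd.Series(rates, index=samples, name="rate"),
        iwhmb=iwhmb,
        whmb=whmb,
    )


def toy_fixture() -> SyntheticCohort:
    """A fixed 6-gene, 2-set, 3-sample cohort small enough to hand-check.

    The interaction network is the path TP53-KRAS-EGFR plus the single edge
    MYC-BRCA1; PTEN stays off-network.  Expression rows for the path genes
    are collinear so the edges survive the cohort correlation filter.
    """
    graph = nx.Graph([("TP53", "KRAS"), ("KRAS", "EGFR"), ("MYC", "BRCA1")])
    net = InteractionNetwork(graph, provenance=("toy",))
    sets = GeneSetCollection(
        {
            "SET_PATH": ["TP53", "KRAS", "EGFR", "PTEN"],
            "SET_PAIR": ["MYC", "BRCA1", "PTEN", "EGFR"],
        },
        source="toy",
    )
    profiles = [
        MutationProfile("S1", {"TP53": 1, "PTEN": 2, "BRCA1": 1}),
        MutationProfile("S2", {"KRAS": 1, "EGFR": 1}),
        MutationProfile("S3", {"BRCA1": 1}),
    ]
    samples = ["S1", "S2", "S3"]
    expression = pd.DataFrame(
        {
            "TP53": [1.0, 2.0, 3.0],
            "KRAS": [2.0, 4.0, 6.0],
            "EGFR": [1.5, 2.5, 3.5],
            "MYC": [3.0, 1.0, 2.0],
            "BRCA1": [6.0, 2.0, 4.0],
            "PTEN": [1.0, 1.0, 2.0],
        },
        index=samples,
    ).T
    cnv = pd.DataFrame(
        {"S1": [1, 0, 0, -1, 0, 0], "S2": [0, 0, 1, 0, 0, -1], "S3": [0, 0, 0, 0, 1, 0]},
        index=["TP53", "KRAS", "EGFR", "MYC", "BRCA1", "PTEN"],
    )
    table = network.centrality_table(net, sets)
    whmb = scoring.compute_whmb(profiles, sets, table, net, samples=samples)
    iwhmb = scoring.compute_iwhmb(whmb)
    return SyntheticCohort(
        config=SyntheticCohortConfig(
            n_samples=3, n_genes=6, n_sets=2, set_size_min=4, set_size_max=4,
            n_subtypes=1, sets_per_subtype=1, n_planted_irgs=1,
            n_module_genes=1, n_immune_genes=1, n_planted_bridges=1, seed=0,
        ),
        profiles=profiles,
        sets=sets,
        net=net,
        expression=expression,
        cnv=cnv,
        subtype_labels=pd.Series([1, 1, 1], index=samples, name="subtype"),
        enriched_sets={1: ["SET_PATH"]},
        irg_coefficients={},
        iwhmb=iwhmb,
        whmb=whmb,
    )
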
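"""Synthetic two-group omics data with planted, recorded ground truth.

The generator emulates the statistical structure the analysis assumes:

* a directed scale-free interaction network (preferential attachment,
  randomly oriented — regulator detection presumes hub-like drivers)
  into which planted regulators are wired with directed edges to their
  target genes;
* a two-group log2 expression matrix in which regulator targets are
  shifted by ±``effect_log2fc`` in the disease group on top of per-gene
  baselines ~ Normal(8, 1) and i.i.d. Normal(0, ``noise_sd``) noise;
* a gene-set collection with background pathways sampled uniformly,
  planted enriched pathways seeded with planted DEGs, and one causal
  pathway per planted regulator carrying a ligand → receptor →
  transducer → transcription-factor topology whose TF is the regulator,
  wired to its targets.

Design of the planted causal structure: each planted regulator is the
transcription factor of its cascade; the upstream chain genes (ligand,
receptor, transducers) are themselves planted as up-regulated DEGs, so
the full cascade is affected and recoverable, while the TF changes only
its targets (regulators need not be DEGs — they are drivers). All
planted TFs are members of every causal pathway so that the
regulator-list enrichment of those pathways is informative even when
few regulators are detected.

One global seed derives fixed per-stage sub-seeds, so stages can be
re-run independently, and any artifact regenerated from the same
(config, seed) is byte-identical.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .causal import PathwayMap
from .io import (EdgeRecord, ExpressionMatrix, GeneSetCollection,
                 NodeRoleRecord)
from .regulators import InteractionNetwork

# per-stage sub-seed channels
_NET, _EXPR, _ONTO = 1, 2, 3


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults are the study conditions used
    throughout the test suite (see docs/methods.md)."""

    n_genes: int = 1000
    n_per_group: int = 10
    effect_log2fc: float = 1.0
    noise_sd: float = 0.5
    n_regulators: int = 3
    targets_per_regulator: int = 20
    network_edges: int = 3000
    pathway_count: int = 20
    pathway_size: int = 30
    n_enriched_pathways: int = 2
    enriched_fraction: float = 0.6
    cascade_length: int = 4  # ligand, receptor, transducer(s), TF
    blood_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_per_group", "network_edges",
                     "pathway_count", "pathway_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("n_regulators", "n_enriched_pathways"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.effect_log2fc < 0 or self.noise_sd <= 0:
            raise ValueError("effect_log2fc must be >= 0 and noise_sd > 0")
        if self.targets_per_regulator > self.n_genes:
            raise ValueError("targets_per_regulator exceeds n_genes")
        if self.pathway_size > self.n_genes:
            raise ValueError("pathway_size exceeds n_genes")
        if not 0 < self.enriched_fraction <= 1:
            raise ValueError("enriched_fraction must be in (0, 1]")
        if self.cascade_length < 3:
            raise ValueError("cascade_length must be >= 3 "
                             "(ligand, receptor, ..., TF)")

    def gene_names(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]


@dataclass
class SimTruth:
    """Planted ground truth recorded by the generator."""

    planted_deg_up: frozenset[str] = frozenset()
    planted_deg_down: frozenset[str] = frozenset()
    planted_regulators: frozenset[str] = frozenset()
    regulator_targets: dict[str, tuple[str, ...]] = field(default_factory=dict)
    cascade_genes: dict[str, tuple[str, ...]] = field(default_factory=dict)
    planted_enriched_pathways: frozenset[str] = frozenset()
    causal_pathway_names: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.planted_deg_up & self.planted_deg_down:
            raise ValueError("planted up and down DEG sets overlap")

    @property
    def planted_degs(self) -> frozenset[str]:
        return self.planted_deg_up | self.planted_deg_down


def _rng(channel: int, seed: int) -> np.random.Generator:
    return np.random.default_rng([channel, seed])


def simulate_network(config: SimConfig) -> tuple[InteractionNetwork, SimTruth]:
    """Scale-free directed background plus planted regulator wiring."""
    n = config.n_genes
    if config.network_edges < n - 1:
        raise ValueError(f"network_edges={config.network_edges} infeasible "
                         f"for {n} nodes (need >= n-1)")
    chain_len = config.cascade_length - 1  # genes upstream of the TF
    reserved = config.n_regulators * (config.cascade_length
                                      + config.targets_per_regulator)
    if reserved > n:
        raise ValueError("planted structure needs more genes than n_genes")

    rng = _rng(_NET, config.seed)
    genes = config.gene_names()
    m = max(1, round(config.network_edges / n))
    base = nx.barabasi_albert_graph(n, m, seed=int(rng.integers(2**31)))

    edges: dict[tuple[str, str, str], EdgeRecord] = {}

    def put(rec: EdgeRecord) -> None:
        edges[rec.key] = rec

    for u, v in base.edges():
        if rng.random() < 0.5:
            u, v = v, u
        effect = "activation" if rng.random() < 0.5 else "inhibition"
        put(EdgeRecord(genes[u], genes[v], effect, "binding"))

    picks = rng.choice(n, size=reserved, replace=False) if reserved else []
    picks = [genes[i] for i in picks]
    truth = SimTruth(seed=config.seed)
    up: set[str] = set()
    down: set[str] = set()
    regulators: set[str] = set()
    roles: dict[str, NodeRoleRecord] = {}
    pos = 0
    for _ in range(config.n_regulators):
        chain = picks[pos:pos + chain_len]
        tf = picks[pos + chain_len]
        targets = picks[pos + config.cascade_length:
                        pos + config.cascade_length + config.targets_per_regulator]
        pos += config.cascade_length + config.targets_per_regulator

        for a, b in zip(chain, chain[1:] + [tf]):
            put(EdgeRecord(a, b, "activation", "binding"))
        n_up = math.ceil(len(targets) / 2)
        for i, t in enumerate(targets):
            effect = "activation" if i < n_up else "inhibition"
            put(EdgeRecord(tf, t, effect, "transcription-regulation"))
        up.update(chain)
        up.update(targets[:n_up])
        down.update(targets[n_up:])
        regulators.add(tf)
        truth.regulator_targets[tf] = tuple(targets)
        truth.cascade_genes[tf] = tuple(chain)
        chain_roles = (["ligand", "receptor"]
                       + ["transducer"] * (chain_len - 2))
        for g, role in zip(chain, chain_roles):
            roles[g] = NodeRoleRecord(g, role)
        roles[tf] = NodeRoleRecord(tf, "transcription-factor")

    blood = rng.random(n) < config.blood_fraction
    for g, b in zip(genes, blood):
        prev = roles.get(g)
        roles[g] = NodeRoleRecord(g, prev.role if prev else "other", bool(b))

    truth.planted_deg_up = frozenset(up)
    truth.planted_deg_down = frozenset(down)
    truth.planted_regulators = frozenset(regulators)
    network = InteractionNetwork(edges.values(), roles)
    for g in genes:  # isolated genes stay part of the universe
        network.graph.add_node(g)
    return network, truth


def simulate_expression(config: SimConfig, truth: SimTruth) -> ExpressionMatrix:
    """Two-group log2 matrix with planted group shifts on DEG targets."""
    rng = _rng(_EXPR, config.seed)
    genes = config.gene_names()
    baseline = rng.normal(8.0, 1.0, config.n_genes)
    delta = np.zeros(config.n_genes)
    idx = {g: i for i, g in enumerate(genes)}
    for g in truth.planted_deg_up:
        delta[idx[g]] = config.effect_log2fc
    for g in truth.planted_deg_down:
        delta[idx[g]] = -config.effect_log2fc
    k = config.n_per_group
    means = np.concatenate([np.tile(baseline[:, None], (1, k)),
                            np.tile((baseline + delta)[:, None], (1, k))],
                           axis=1)
    values = means + rng.normal(0.0, config.noise_sd, means.shape)
    samples = ([f"control_{i+1:02d}" for i in range(k)]
               + [f"disease_{i+1:02d}" for i in range(k)])
    design = {s: ("control" if s.startswith("control") else "disease")
              for s in samples}
    df = pd.DataFrame(values, index=genes, columns=samples)
    return ExpressionMatrix(df, design)


def simulate_ontology(config: SimConfig, truth: SimTruth
                      ) -> tuple[GeneSetCollection, list[PathwayMap]]:
    """Background, planted-enriched and causal pathway gene sets.

    Updates ``truth.planted_enriched_pathways`` and
    ``truth.causal_pathway_names`` in place.
    """
    rng = _rng(_ONTO, config.seed)
    genes = config.gene_names()
    coll = GeneSetCollection()

    n_bg = config.pathway_count - config.n_enriched_pathways
    if n_bg < 0:
        raise ValueError("n_enriched_pathways exceeds pathway_count")
    for i in range(n_bg):
        members = rng.choice(genes, size=config.pathway_size, replace=False)
        coll.add(f"BG_{i+1:02d}", "background pathway", members)

    planted_names = []
    planted_pool = sorted(truth.planted_degs)
    for i in range(config.n_enriched_pathways):
        k_deg = min(math.ceil(config.enriched_fraction * config.pathway_size),
                    len(planted_pool))
        seeded = list(rng.choice(planted_pool, size=k_deg, replace=False)) \
            if k_deg else []
        rest_pool = [g for g in genes if g not in seeded]
        rest = rng.choice(rest_pool, size=config.pathway_size - len(seeded),
                          replace=False)
        name = f"EP_{i+1:02d}"
        coll.add(name, "planted enriched pathway", list(seeded) + list(rest))
        planted_names.append(name)

    maps: list[PathwayMap] = []
    causal_names = []
    tfs = sorted(truth.planted_regulators)
    for tf in tfs:
        chain = list(truth.cascade_genes[tf])
        targets = list(truth.regulator_targets[tf])
        core = chain + tfs + targets
        core = list(dict.fromkeys(core))
        if len(core) < config.pathway_size:
            pool = [g for g in genes if g not in core]
            pad = rng.choice(pool, size=config.pathway_size - len(core),
                             replace=False)
            members = core + list(pad)
        else:
            members = core
        name = f"CP_{tf}"
        coll.add(name, "planted causal pathway", members)
        causal_names.append(name)

        topo = nx.DiGraph()
        chain_roles = (["ligand", "receptor"]
                       + ["transducer"] * (len(chain) - 2))
        for g, role in zip(chain, chain_roles):
            topo.add_node(g, role=role)
        topo.add_node(tf, role="transcription-factor")
        for a, b in zip(chain, chain[1:] + [tf]):
            topo.add_edge(a, b, effect="activation", mechanism="binding")
        for t in targets:
            effect = ("activation" if t in truth.planted_deg_up
                      else "inhibition")
            topo.add_node(t, role="other")
            topo.add_edge(tf, t, effect=effect,
                          mechanism="transcription-regulation")
        maps.append(PathwayMap(name, frozenset(members), topo,
                               {f"{tf}-targets": frozenset(targets)}))

    truth.planted_enriched_pathways = frozenset(planted_names)
    truth.causal_pathway_names = tuple(causal_names)
    return coll, maps


@dataclass
class SimData:
    """Bundle of all artifacts produced by one (config, seed)."""

    config: SimConfig
    truth: SimTruth
    network: InteractionNetwork
    expression: ExpressionMatrix
    collection: GeneSetCollection
    pathway_maps: list[PathwayMap]

    @property
    def blood_genes(self) -> frozenset[str]:
        return frozenset(g for g, r in self.network.roles.items()
                         if r.blood_expressed)


def simulate_all(config: SimConfig) -> SimData:
    network, truth = simulate_network(config)
    expression = simulate_expression(config, truth)
    collection, maps = simulate_ontology(config, truth)
    return SimData(config, truth, network, expression, collection, maps)


def write_truth(truth: SimTruth, path: str | Path) -> None:
    payload = {
        "planted_deg_up": sorted(truth.planted_deg_up),
        "planted_deg_down": sorted(truth.planted_deg_down),
        "planted_regulators": sorted(truth.planted_regulators),
        "regulator_targets": {k: list(v)
                              for k, v in sorted(truth.regulator_targets.items())},
        "cascade_genes": {k: list(v)
                          for k, v in sorted(truth.cascade_genes.items())},
        "planted_enriched_pathways": sorted(truth.planted_enriched_pathways),
        "causal_pathway_names": list(truth.causal_pathway_names),
        "seed": truth.seed,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


def config_from_dict(d: dict) -> SimConfig:
    known = {f for f in SimConfig.__dataclass_fields__}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown simulation parameter(s): {sorted(unknown)}")
    return SimConfig(**d)
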
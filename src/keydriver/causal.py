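"""Key-pathway identification and causal-network reconstruction.

A *key pathway* is one that is synergistically enriched: its
hypergeometric enrichment p-value for the combined list of DEGs and
expression regulators (their union) is lower than its p-value for
either list alone, with all three passing a significance gate
(raw p <= alpha, default 0.05).

A *causal network* is assembled over the annotated topologies of the key
pathways. DEGs and regulators are both considered affected. Affected
ligands or receptors act as triggers; simple directed paths from a
trigger to an affected transcription factor are retained when they carry
a consecutive stretch of at least ``min_stretch`` affected molecules and
at most ``max_gap`` unaffected interior nodes. Retained cascade edges
are unioned across pathways with per-edge and per-node provenance;
affected members of annotated functional-module groups (e.g. protein
complexes) are attached as module-group nodes. No edge is invented: the
causal network is a subgraph of the union of key-pathway topologies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .enrichment import EnrichmentResult

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05
DEFAULT_MIN_STRETCH = 2
DEFAULT_MAX_GAP = 0


@dataclass
class PathwayMap:
    """A named gene set with an optional directed, role-annotated topology.

    ``topology`` is a DiGraph whose nodes carry a ``role`` attribute
    (ligand / receptor / transducer / transcription-factor / other) and
    whose edges carry ``effect`` and ``mechanism``. ``modules`` maps a
    functional-module name (e.g. a protein complex) to its members.
    """

    name: str
    members: frozenset[str]
    topology: nx.DiGraph | None = None
    modules: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.topology is not None:
            extra = set(self.topology.nodes) - set(self.members)
            if extra:
                logger.warning("pathway %s: %d topology node(s) outside the "
                               "member set (small-molecule placeholders?)",
                               self.name, len(extra))


@dataclass(frozen=True)
class KeyPathway:
    name: str
    p_deg: float
    p_reg: float
    p_combo: float
    is_key: bool


@dataclass
class CausalNetwork:
    """Reconstructed condition-specific signaling subgraph.

    Node attributes: ``annotations`` (subset of {trigger, cascade,
    transcription-factor, module-group}) and ``provenance`` (source
    pathway names). Edge attribute ``provenance`` likewise.
    ``cascades`` lists (pathway name, node path) for every retained
    cascade.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)
    cascades: list[tuple[str, tuple[str, ...]]] = field(default_factory=list)

    @property
    def triggers(self) -> set[str]:
        return {v for v, d in self.graph.nodes(data=True)
                if "trigger" in d["annotations"]}

    @property
    def transcription_factors(self) -> set[str]:
        return {v for v, d in self.graph.nodes(data=True)
                if "transcription-factor" in d["annotations"]}

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    def node_provenance(self, gene: str) -> set[str]:
        return set(self.graph.nodes[gene]["provenance"])


def identify_key_pathways(deg_enrich: Sequence[EnrichmentResult],
                          reg_enrich: Sequence[EnrichmentResult],
                          combo_enrich: Sequence[EnrichmentResult],
                          alpha: float = DEFAULT_ALPHA) -> list[KeyPathway]:
    """Apply the synergy rule to three enrichment runs over one collection.

    The combination run must be computed on the union of the DEG and
    regulator lists. A pathway is key iff p_combo < p_deg and
    p_combo < p_reg and all three are <= alpha. Sorted by p_combo.
    """
    p_deg = {e.set_name: e.p_value for e in deg_enrich}
    p_reg = {e.set_name: e.p_value for e in reg_enrich}
    p_combo = {e.set_name: e.p_value for e in combo_enrich}
    keys = set(p_deg)
    if set(p_reg) != keys or set(p_combo) != keys:
        diff = (set(p_reg) ^ keys) | (set(p_combo) ^ keys)
        raise ValueError("enrichment runs cover different collections; "
                         f"symmetric difference: {sorted(diff)}")
    out = []
    for name in keys:
        pd_, pr, pc = p_deg[name], p_reg[name], p_combo[name]
        is_key = (pc < pd_ and pc < pr
                  and pd_ <= alpha and pr <= alpha and pc <= alpha)
        out.append(KeyPathway(name, pd_, pr, pc, is_key))
    out.sort(key=lambda k: (k.p_combo, k.name))
    return out


def _longest_affected_run(path: Sequence[str], affected: frozenset[str]) -> int:
    best = run = 0
    for v in path:
        run = run + 1 if v in affected else 0
        best = max(best, run)
    return best


def find_affected_cascades(topology: nx.DiGraph,
                           affected: Iterable[str],
                           min_stretch: int = DEFAULT_MIN_STRETCH,
                           max_gap: int = DEFAULT_MAX_GAP
                           ) -> list[tuple[str, ...]]:
    """Simple directed paths from affected triggers to affected TFs.

    A path qualifies when it starts at an affected ligand or receptor,
    ends at an affected transcription factor, contains a consecutive
    stretch of >= ``min_stretch`` affected nodes, and has at most
    ``max_gap`` unaffected interior nodes. Cycles are never revisited
    (simple paths only). Deterministic output order: (length, path).
    """
    aff = frozenset(affected)
    roles = nx.get_node_attributes(topology, "role")
    triggers = sorted(v for v in topology.nodes
                      if v in aff and roles.get(v) in ("ligand", "receptor"))
    tfs = sorted(v for v in topology.nodes
                 if v in aff and roles.get(v) == "transcription-factor")
    cascades: list[tuple[str, ...]] = []
    for trig in triggers:
        for tf in tfs:
            if trig == tf:
                continue
            for path in nx.all_simple_paths(topology, trig, tf):
                interior = path[1:-1]
                gaps = sum(1 for v in interior if v not in aff)
                if gaps > max_gap:
                    continue
                if _longest_affected_run(path, aff) < min_stretch:
                    continue
                cascades.append(tuple(path))
    cascades.sort(key=lambda p: (len(p), p))
    return cascades


def reconstruct_causal_network(key: Sequence[KeyPathway],
                               pathways: Sequence[PathwayMap] | Mapping[str, PathwayMap],
                               degs: Iterable[str],
                               regulators: Iterable[str],
                               min_stretch: int = DEFAULT_MIN_STRETCH,
                               max_gap: int = DEFAULT_MAX_GAP) -> CausalNetwork:
    """Overlay affected genes (DEGs ∪ regulators) on key-pathway
    topologies and union the retained cascades into one network."""
    if not isinstance(pathways, Mapping):
        pathways = {p.name: p for p in pathways}
    affected = frozenset(degs) | frozenset(regulators)
    net = CausalNetwork()

    def _touch_node(v: str, annotation: str, provenance: str) -> None:
        if v not in net.graph:
            net.graph.add_node(v, annotations=set(), provenance=set())
        net.graph.nodes[v]["annotations"].add(annotation)
        net.graph.nodes[v]["provenance"].add(provenance)

    for kp in key:
        if not kp.is_key:
            continue
        pmap = pathways.get(kp.name)
        if pmap is None or pmap.topology is None:
            logger.warning("key pathway %s has no topology; skipped", kp.name)
            continue
        topo = pmap.topology
        cascades = find_affected_cascades(topo, affected, min_stretch, max_gap)
        for path in cascades:
            net.cascades.append((kp.name, path))
            _touch_node(path[0], "trigger", kp.name)
            _touch_node(path[-1], "transcription-factor", kp.name)
            for v in path[1:-1]:
                _touch_node(v, "cascade", kp.name)
            for u, v in zip(path, path[1:]):
                data = topo.edges[u, v]
                if not net.graph.has_edge(u, v):
                    net.graph.add_edge(u, v, effect=data.get("effect", "unspecified"),
                                       mechanism=data.get("mechanism", "other"),
                                       provenance=set())
                net.graph.edges[u, v]["provenance"].add(kp.name)
        for mod_name, members in pmap.modules.items():
            hit = sorted(set(members) & affected)
            if not hit:
                continue
            for v in hit:
                _touch_node(v, "module-group", kp.name)
                net.graph.nodes[v]["module"] = mod_name
            # keep any topology edges among affected module members
            for u in hit:
                for v in hit:
                    if u != v and topo.has_edge(u, v):
                        data = topo.edges[u, v]
                        if not net.graph.has_edge(u, v):
                            net.graph.add_edge(u, v,
                                               effect=data.get("effect", "unspecified"),
                                               mechanism=data.get("mechanism", "other"),
                                               provenance=set())
                        net.graph.edges[u, v]["provenance"].add(kp.name)

    if not net.triggers:
        logger.warning("no affected ligand/receptor trigger anywhere; "
                       "causal network is empty")
    return net
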
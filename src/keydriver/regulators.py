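"""Topologically significant genes on a molecular interaction network.

Two complementary statistics identify candidate expression regulators —
proteins responsible for an observed set of expression changes without
necessarily changing expression themselves:

* **Direct regulators** (over-connectivity): a node whose immediate
  interaction partners contain more DEGs than expected by chance. The
  null is hypergeometric: the node's n neighbours are a draw from the
  N = |nodes| - 1 other genes, of which R are DEGs; the observed DEG
  neighbours r are tested with the upper tail. By default only outgoing
  edges count (a regulator acts on its targets); an undirected mode
  covers binding-only networks.

* **Remote regulators** ("hidden nodes"): a node traversed by an
  unexpectedly high share of the shortest directed paths connecting DEG
  pairs, relative to its share of all shortest paths in the network. All
  shortest paths per ordered pair are enumerated (not one arbitrary
  path), each counting once per interior node. With K the total number
  of DEG-pair shortest paths, M the total over all ordered pairs, and
  k_v / m_v the numbers passing through v as an interior node, the
  significance is the hypergeometric upper tail of k_v successes in m_v
  draws from M paths of which K connect DEG pairs. A seeded permutation
  null (resampling DEG-sized node sets) is available as a sensitivity
  alternative.

Shortest-path traversal counts use a per-source BFS over the
shortest-path DAG with a descendant-count accumulation, so the total
cost is O(V (V + E)) without materialising any path.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .enrichment import hypergeom_tail
from .io import EdgeRecord, NodeRoleRecord

logger = logging.getLogger(__name__)


class InteractionNetwork:
    """A directed gene-interaction graph with optional node roles.

    Parallel duplicate edges (same source, target, mechanism) are
    collapsed at construction; self-loops are kept but flagged.
    """

    def __init__(self, edges: Iterable[EdgeRecord],
                 roles: Mapping[str, NodeRoleRecord] | None = None):
        self.graph = nx.DiGraph()
        self.roles: dict[str, NodeRoleRecord] = dict(roles or {})
        seen: set[tuple[str, str, str]] = set()
        self.self_loops: set[str] = set()
        for e in edges:
            if e.key in seen:
                continue
            seen.add(e.key)
            if e.is_self_loop:
                self.self_loops.add(e.source)
            self.graph.add_edge(e.source, e.target,
                                effect=e.effect, mechanism=e.mechanism)
        for gene in self.roles:
            self.graph.add_node(gene)

    @property
    def nodes(self) -> list[str]:
        return sorted(self.graph.nodes)

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def neighbors(self, gene: str, direction: str = "out") -> set[str]:
        """Interaction partners of ``gene`` (itself excluded)."""
        if direction == "out":
            nb = set(self.graph.successors(gene))
        elif direction == "in":
            nb = set(self.graph.predecessors(gene))
        elif direction == "undirected":
            nb = set(self.graph.successors(gene)) | set(self.graph.predecessors(gene))
        else:
            raise ValueError("direction must be 'out', 'in' or 'undirected'")
        nb.discard(gene)
        return nb

    def edge_records(self) -> list[EdgeRecord]:
        return [EdgeRecord(u, v, d["effect"], d["mechanism"])
                for u, v, d in self.graph.edges(data=True)]


@dataclass(frozen=True)
class RegulatorResult:
    """One candidate regulator with its counting statistic.

    ``statistic`` is (r, n, R, N) for direct candidates and
    (k_v, m_v, K, M) for remote ones.
    """

    gene: str
    kind: str  # "direct" | "remote"
    statistic: tuple[int, int, int, int]
    p_value: float
    fdr: float
    rank: int


def _ranked(genes: Sequence[str], kind: str,
            statistics: Sequence[tuple[int, int, int, int]],
            pvals: Sequence[float]) -> list[RegulatorResult]:
    """BH-correct, order by (p asc, overlap desc, gene asc), 1-based ranks."""
    fdrs = multipletests(pvals, method="fdr_bh")[1] if len(pvals) else []
    order = sorted(range(len(genes)),
                   key=lambda i: (pvals[i], -statistics[i][0], genes[i]))
    return [RegulatorResult(genes[i], kind, statistics[i],
                            float(pvals[i]), float(fdrs[i]), rank)
            for rank, i in enumerate(order, start=1)]


def direct_regulators(network: InteractionNetwork,
                      degs: Iterable[str],
                      direction: str = "out") -> list[RegulatorResult]:
    """Over-connectivity test of every node against a DEG list.

    DEGs outside the network are dropped (logged). For candidate v:
    n = |neighbours(v)|, r = |neighbours(v) ∩ DEGs|, R = |DEGs \\ {v}|,
    N = |nodes| - 1 (the candidate is excluded from its own universe).
    """
    nodes = network.nodes
    deg_all = set(degs)
    deg_in = deg_all & set(nodes)
    if len(deg_in) < len(deg_all):
        logger.info("dropped %d DEG(s) not in the network",
                    len(deg_all) - len(deg_in))
    if not deg_in:
        raise ValueError("no DEGs present in the network")
    N = len(nodes) - 1
    genes, statistics, rr, nn, RR = [], [], [], [], []
    for v in nodes:
        nb = network.neighbors(v, direction)
        n = len(nb)
        r = len(nb & deg_in)
        R = len(deg_in - {v})
        genes.append(v)
        statistics.append((r, n, R, N))
        rr.append(r)
        nn.append(n)
        RR.append(R)
    # vectorized upper tail: sf(r-1) with r=0 giving exactly 1
    rr = np.asarray(rr)
    pvals = np.where(rr == 0, 1.0,
                     stats.hypergeom.sf(rr - 1, N, np.asarray(RR),
                                        np.asarray(nn)))
    return _ranked(genes, "direct", statistics, [float(p) for p in pvals])


def _bfs_dag(graph: nx.DiGraph, source) -> tuple[dict, dict, list]:
    """BFS from source: distances, shortest-path counts sigma, and nodes
    in non-decreasing distance order (source first)."""
    dist = {source: 0}
    sigma = {source: 1}
    order = [source]
    queue = deque([source])
    while queue:
        v = queue.popleft()
        dv = dist[v]
        for w in graph.successors(v):
            if w not in dist:
                dist[w] = dv + 1
                sigma[w] = 0
                order.append(w)
                queue.append(w)
            if dist[w] == dv + 1:
                sigma[w] += sigma[v]
    return dist, sigma, order


def shortest_path_counts(network: InteractionNetwork,
                         pairs: Iterable[tuple[str, str]]
                         ) -> tuple[dict[str, int], int]:
    """Interior-node traversal counts over all shortest directed paths.

    For each ordered (source, target) pair with at least one directed
    path, every shortest path increments the counter of each of its
    interior nodes once; endpoints are never counted and unreachable or
    degenerate (s, s) pairs contribute nothing.

    Returns
    -------
    counts
        node -> number of selected shortest paths on which it is interior.
    n_paths
        total number of shortest paths over all the pairs.
    """
    graph = network.graph
    by_source: dict[str, set[str]] = {}
    for s, t in pairs:
        if s == t:
            continue
        by_source.setdefault(s, set()).add(t)
    counts: dict[str, int] = {v: 0 for v in graph.nodes}
    n_paths = 0
    for s, targets in by_source.items():
        if s not in graph:
            continue
        dist, sigma, order = _bfs_dag(graph, s)
        tset = {t for t in targets if t in dist}
        if not tset:
            continue
        # g[v] = number of DAG paths from v to any target below it; the
        # number of shortest s->t paths with v interior is sigma[v]*g[v]
        g = {v: 0 for v in order}
        for v in reversed(order):
            dv = dist[v]
            for w in graph.successors(v):
                if dist.get(w) == dv + 1:
                    g[v] += (1 if w in tset else 0) + g[w]
        for v in order:
            if v != s and g[v]:
                counts[v] += sigma[v] * g[v]
        n_paths += sum(sigma[t] for t in tset)
    return counts, n_paths


def _all_ordered_pairs(nodes: Sequence[str]):
    for s in nodes:
        for t in nodes:
            if s != t:
                yield (s, t)


def hidden_nodes(network: InteractionNetwork,
                 degs: Iterable[str],
                 null: str = "hypergeom",
                 n_permutations: int = 1000,
                 seed: int | None = None) -> list[RegulatorResult]:
    """Remote-regulator statistic from shortest-path traversal shares.

    Nodes never traversed by any all-pairs shortest path (m_v = 0) are
    excluded. If no DEG pair is connected the result is empty (warning).
    """
    nodes = network.nodes
    deg_in = sorted(set(degs) & set(nodes))
    if len(deg_in) < 2:
        raise ValueError("need >=2 DEGs present in the network")
    if null not in ("hypergeom", "permutation"):
        raise ValueError("null must be 'hypergeom' or 'permutation'")

    m, M = shortest_path_counts(network, _all_ordered_pairs(nodes))
    k, K = shortest_path_counts(network, _all_ordered_pairs(deg_in))
    if K == 0:
        logger.warning("no DEG pair is connected; no remote regulators")
        return []

    candidates = [v for v in nodes if m[v] > 0]
    statistics = [(k[v], m[v], K, M) for v in candidates]
    if null == "hypergeom":
        pvals = [hypergeom_tail(k[v], m[v], K, M) for v in candidates]
    else:
        rng = np.random.default_rng(seed)
        exceed = {v: 0 for v in candidates}
        node_arr = np.asarray(nodes, dtype=object)
        for _ in range(n_permutations):
            draw = rng.choice(node_arr, size=len(deg_in), replace=False)
            k_perm, _ = shortest_path_counts(network,
                                             _all_ordered_pairs(list(draw)))
            for v in candidates:
                if k_perm[v] >= k[v]:
                    exceed[v] += 1
        pvals = [(1 + exceed[v]) / (1 + n_permutations) for v in candidates]
    return _ranked(candidates, "remote", statistics, pvals)


def significant_regulators(results: Iterable[RegulatorResult],
                           alpha: float = 0.05,
                           on: str = "fdr") -> list[str]:
    """Genes called regulators at an FDR (default) or raw-p threshold,
    in rank order."""
    if on not in ("p", "fdr"):
        raise ValueError("on must be 'p' or 'fdr'")
    key = (lambda r: r.fdr) if on == "fdr" else (lambda r: r.p_value)
    return [r.gene for r in sorted(results, key=lambda r: r.rank)
            if key(r) <= alpha]
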
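import itertools
import math

import networkx as nx
import numpy as np
import pytest

from keydriver.io import EdgeRecord, NodeRoleRecord
from keydriver.regulators import (InteractionNetwork, direct_regulators,
                                  hidden_nodes, shortest_path_counts)

from oracles import brute_force_traversals, exact_hypergeom_tail


def _network(edges, extra_nodes=()):
    net = InteractionNetwork([EdgeRecord(u, v) for u, v in edges],
                             {g: NodeRoleRecord(g) for g in extra_nodes})
    return net


def _all_pairs(nodes):
    return [(s, t) for s in nodes for t in nodes if s != t]


# --- traversal counts ------------------------------------------------------

def test_chain_counts_interior_nodes_once():
    net = _network([("A", "B"), ("B", "C"), ("C", "D")])
    counts, n_paths = shortest_path_counts(net, [("A", "D")])
    assert counts == {"A": 0, "B": 1, "C": 1, "D": 0}
    assert n_paths == 1


def test_diamond_counts_both_shortest_paths():
    net = _network([("A", "B"), ("B", "D"), ("A", "C"), ("C", "D")])
    counts, n_paths = shortest_path_counts(net, [("A", "D")])
    assert counts == {"A": 0, "B": 1, "C": 1, "D": 0}
    assert n_paths == 2


def test_degenerate_and_unreachable_pairs_contribute_nothing():
    net = _network([("A", "B")], extra_nodes=["Z"])
    counts, n_paths = shortest_path_counts(net, [("A", "A"), ("B", "A"),
                                                 ("A", "Z")])
    assert n_paths == 0
    assert all(c == 0 for c in counts.values())


def test_traversal_counts_match_brute_force_on_random_digraphs(rng):
    """Exact equality against explicit all-shortest-path enumeration,
    plus the traversal-mass conservation identity."""
    for _ in range(100):
        n = int(rng.integers(4, 16))
        p = rng.uniform(0.1, 0.35)
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)),
                                directed=True)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        net = _network(list(g.edges), extra_nodes=list(g.nodes))
        pairs = _all_pairs(sorted(g.nodes))
        counts, n_paths = shortest_path_counts(net, pairs)
        ref_counts, ref_paths = brute_force_traversals(net.graph, pairs)
        assert counts == ref_counts
        assert n_paths == ref_paths
        # sum of interior counts == sum over paths of (length - 1)
        total = 0
        for s, t in pairs:
            try:
                for path in nx.all_shortest_paths(net.graph, s, t):
                    total += len(path) - 2
            except nx.NetworkXNoPath:
                continue
        assert sum(counts.values()) == total


# --- direct regulators -----------------------------------------------------

def test_node_without_deg_neighbours_has_p_one():
    net = _network([("A", "B"), ("C", "D")])
    degs = {"B"}
    res = {r.gene: r for r in direct_regulators(net, degs)}
    assert res["C"].p_value == 1.0
    assert res["A"].p_value < 1.0


def test_hub_with_all_deg_neighbours_matches_enumeration():
    # H -> 4 DEGs among 9 nodes: p = C(4,4)C(4,0)/C(8,4) = 1/70
    degs = [f"D{i}" for i in range(4)]
    others = [f"O{i}" for i in range(4)]
    net = _network([("H", d) for d in degs], extra_nodes=others)
    res = {r.gene: r for r in direct_regulators(net, set(degs))}
    assert res["H"].statistic == (4, 4, 4, 8)
    assert math.isclose(res["H"].p_value, 1 / 70, rel_tol=1e-12)
    assert math.isclose(res["H"].p_value,
                        float(exact_hypergeom_tail(4, 4, 4, 8)), rel_tol=1e-12)
    assert res["H"].rank == 1


def test_empty_deg_set_rejected():
    net = _network([("A", "B")])
    with pytest.raises(ValueError):
        direct_regulators(net, {"ZZZ"})


def test_direction_modes_count_different_neighbourhoods():
    net = _network([("A", "B"), ("C", "A")])
    res_out = {r.gene: r for r in direct_regulators(net, {"B"}, "out")}
    res_und = {r.gene: r for r in direct_regulators(net, {"B", "C"},
                                                    "undirected")}
    assert res_out["A"].statistic[:2] == (1, 1)   # successors only
    assert res_und["A"].statistic[:2] == (2, 2)   # both directions


def test_pvalues_invariant_under_gene_relabeling(rng):
    g = nx.gnp_random_graph(12, 0.25, seed=7, directed=True)
    edges = [(f"n{u}", f"n{v}") for u, v in g.edges]
    nodes = [f"n{i}" for i in g.nodes]
    degs = set(rng.choice(nodes, size=4, replace=False))
    net = _network(edges, extra_nodes=nodes)
    mapping = {v: f"x{ord(v[1]) * 7 % 97}_{v}" for v in nodes}
    net2 = _network([(mapping[u], mapping[v]) for u, v in edges],
                    extra_nodes=[mapping[v] for v in nodes])
    res1 = {r.gene: r.p_value for r in direct_regulators(net, degs)}
    res2 = {r.gene: r.p_value
            for r in direct_regulators(net2, {mapping[d] for d in degs})}
    for v in nodes:
        assert math.isclose(res1[v], res2[mapping[v]], rel_tol=1e-12)


# --- hidden nodes ----------------------------------------------------------

def test_chain_hidden_node_statistic_frozen():
    """Chain A->B->C->D with DEGs {A, D}: B is interior to 2 of the 6
    all-pairs shortest paths and to the single DEG-pair path, giving
    p = tail(1, 2, 1, 6) = 1/3 (exact enumeration)."""
    net = _network([("A", "B"), ("B", "C"), ("C", "D")])
    res = {r.gene: r for r in hidden_nodes(net, {"A", "D"})}
    assert res["B"].statistic == (1, 2, 1, 6)
    assert math.isclose(res["B"].p_value, 1 / 3, rel_tol=1e-12)
    assert math.isclose(res["B"].p_value,
                        float(exact_hypergeom_tail(1, 2, 1, 6)), rel_tol=1e-12)
    assert res["C"].statistic == (1, 2, 1, 6)
    # endpoints are never interior
    assert "A" not in res and "D" not in res


def test_all_nodes_as_degs_gives_p_one_everywhere(rng):
    g = nx.gnp_random_graph(10, 0.3, seed=3, directed=True)
    nodes = [f"n{i}" for i in g.nodes]
    net = _network([(f"n{u}", f"n{v}") for u, v in g.edges],
                   extra_nodes=nodes)
    results = hidden_nodes(net, set(nodes))
    assert results  # some node is traversed
    for r in results:
        assert r.p_value == 1.0
        k, m, K, M = r.statistic
        assert (k, K) == (m, M)


def test_unconnected_deg_pairs_give_empty_result(caplog):
    net = _network([("A", "B")], extra_nodes=["X", "Y"])
    with caplog.at_level("WARNING"):
        assert hidden_nodes(net, {"X", "Y"}) == []
    assert any("no DEG pair" in r.message for r in caplog.records)


def test_fewer_than_two_degs_rejected():
    net = _network([("A", "B")])
    with pytest.raises(ValueError):
        hidden_nodes(net, {"A"})


def test_permutation_null_is_seeded_and_bounded():
    net = _network([("A", "B"), ("B", "C"), ("C", "D"), ("A", "C")])
    res1 = hidden_nodes(net, {"A", "D"}, null="permutation",
                        n_permutations=200, seed=5)
    res2 = hidden_nodes(net, {"A", "D"}, null="permutation",
                        n_permutations=200, seed=5)
    assert [(r.gene, r.p_value) for r in res1] == \
           [(r.gene, r.p_value) for r in res2]
    assert all(0 < r.p_value <= 1 for r in res1)


def test_upstream_regulator_recovered_via_two_step_cascades(rng):
    """A node relaying upstream DEGs to downstream DEG targets through
    two-step cascades should score in the top 10 in >=80% of runs."""
    hits, n_runs = 0, 50
    for run in range(n_runs):
        run_rng = np.random.default_rng(1000 + run)
        n_bg = 100
        g = nx.gnp_random_graph(n_bg, 0.02,
                                seed=int(run_rng.integers(2**31)),
                                directed=True)
        edges = [(f"n{u}", f"n{v}") for u, v in g.edges]
        upstream = [f"u{i}" for i in range(5)]
        mids = [f"m{i}" for i in range(3)]
        targets = [f"t{i}" for i in range(10)]
        edges += [(u, "REG") for u in upstream]
        edges += [("REG", m) for m in mids]
        for i, t in enumerate(targets):
            edges.append((mids[i % 3], t))
        nodes = [f"n{i}" for i in range(n_bg)] + upstream + mids \
            + targets + ["REG"]
        net = _network(edges, extra_nodes=nodes)
        results = hidden_nodes(net, set(upstream) | set(targets))
        top10 = [r.gene for r in results[:10]]
        if "REG" in top10:
            hits += 1
    assert hits >= 0.8 * n_runs
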
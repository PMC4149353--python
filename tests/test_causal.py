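import math

import networkx as nx
import pytest
from hypothesis import given, strategies as st

from keydriver.causal import (KeyPathway, PathwayMap, find_affected_cascades,
                              identify_key_pathways,
                              reconstruct_causal_network)
from keydriver.enrichment import EnrichmentResult, enrich
from keydriver.io import GeneSetCollection

from oracles import exact_hypergeom_tail


def _res(name, p):
    return EnrichmentResult(name, 1, 1, 1, 10, p, p)


# --- key pathways ----------------------------------------------------------

def test_combo_below_both_is_key():
    (kp,) = identify_key_pathways([_res("P", 0.01)], [_res("P", 0.02)],
                                  [_res("P", 0.001)])
    assert kp.is_key


def test_combo_not_below_both_is_not_key():
    (kp,) = identify_key_pathways([_res("P", 0.01)], [_res("P", 0.02)],
                                  [_res("P", 0.015)])
    assert not kp.is_key


def test_significance_gate_applies_to_all_three():
    (kp,) = identify_key_pathways([_res("P", 0.2)], [_res("P", 0.02)],
                                  [_res("P", 0.001)])
    assert not kp.is_key


def test_mismatched_collections_rejected():
    with pytest.raises(ValueError, match="Q"):
        identify_key_pathways([_res("P", 0.1)], [_res("Q", 0.1)],
                              [_res("P", 0.1)])


def test_toy_universe_synergy_decided_by_exact_tail_values():
    """30-gene universe, one 10-gene set; DEGs 6 (overlap 4), regulators
    5 (overlap 3), combined 11 (overlap 7). The three enrichment p's are
    fixed by exact enumeration: 86/1131, 1514/7917, 1511/130065. The
    combination is the smallest, but the DEG and regulator p's miss the
    0.05 gate, so the pathway is key only under a relaxed gate."""
    universe = [f"u{i}" for i in range(30)]
    pathway = universe[:10]
    degs = universe[:4] + universe[10:12]          # overlap 4 of 6
    regs = universe[4:7] + universe[12:14]          # overlap 3 of 5
    combo = degs + regs                             # overlap 7 of 11
    coll = GeneSetCollection()
    coll.add("S", "", pathway)
    coll.explicit_universe = frozenset(universe)
    e_deg = enrich(degs, coll)
    e_reg = enrich(regs, coll)
    e_combo = enrich(combo, coll)
    expect = [float(exact_hypergeom_tail(4, 10, 6, 30)),
              float(exact_hypergeom_tail(3, 10, 5, 30)),
              float(exact_hypergeom_tail(7, 10, 11, 30))]
    got = [e_deg[0].p_value, e_reg[0].p_value, e_combo[0].p_value]
    for g, e in zip(got, expect):
        assert math.isclose(g, e, rel_tol=1e-12)
    (strict,) = identify_key_pathways(e_deg, e_reg, e_combo, alpha=0.05)
    assert not strict.is_key  # p_deg = 86/1131 > 0.05
    (relaxed,) = identify_key_pathways(e_deg, e_reg, e_combo, alpha=0.2)
    assert relaxed.is_key


# --- cascades --------------------------------------------------------------

def _chain_topology():
    g = nx.DiGraph()
    for v, role in [("L", "ligand"), ("R", "receptor"), ("K", "transducer"),
                    ("T", "transcription-factor")]:
        g.add_node(v, role=role)
    g.add_edge("L", "R", effect="activation", mechanism="binding")
    g.add_edge("R", "K", effect="activation", mechanism="binding")
    g.add_edge("K", "T", effect="activation", mechanism="binding")
    return g


def test_fully_affected_chain_yields_one_full_cascade():
    cascades = find_affected_cascades(_chain_topology(), {"L", "R", "K", "T"})
    assert ("L", "R", "K", "T") in cascades
    # the receptor is also an affected trigger, so its suffix qualifies too
    assert set(cascades) == {("L", "R", "K", "T"), ("R", "K", "T")}


def test_gap_semantics():
    affected = {"L", "R", "T"}  # K unaffected
    assert find_affected_cascades(_chain_topology(), affected,
                                  max_gap=0) == []
    with_gap = find_affected_cascades(_chain_topology(), affected, max_gap=1)
    assert ("L", "R", "K", "T") in with_gap


def test_min_stretch_filters_sparse_paths():
    g = _chain_topology()
    affected = {"L", "K", "T"}  # R unaffected: longest run is K,T = 2
    assert find_affected_cascades(g, affected, min_stretch=3,
                                  max_gap=1) == []
    assert find_affected_cascades(g, affected, min_stretch=2,
                                  max_gap=1) == [("L", "R", "K", "T")]


def test_branched_topology_returns_only_affected_tf_branch():
    g = nx.DiGraph()
    for v, role in [("L", "ligand"), ("A", "transducer"), ("B", "transducer"),
                    ("T1", "transcription-factor"),
                    ("T2", "transcription-factor")]:
        g.add_node(v, role=role)
    for u, v in [("L", "A"), ("A", "T1"), ("L", "B"), ("B", "T2")]:
        g.add_edge(u, v, effect="activation", mechanism="binding")
    affected = {"L", "A", "B", "T1"}  # T2 unaffected
    cascades = find_affected_cascades(g, affected)
    assert cascades == [("L", "A", "T1")]


def test_cycles_are_traversed_at_most_once():
    g = _chain_topology()
    g.add_edge("K", "R", effect="activation", mechanism="binding")  # cycle
    cascades = find_affected_cascades(g, {"L", "R", "K", "T"})
    for path in cascades:
        assert len(path) == len(set(path))


@given(st.sets(st.sampled_from(["L", "R", "K", "T"])),
       st.sets(st.sampled_from(["L", "R", "K", "T"])))
def test_enlarging_affected_set_never_removes_cascades(a, b):
    topo = _chain_topology()
    small = find_affected_cascades(topo, a, max_gap=1)
    large = find_affected_cascades(topo, a | b, max_gap=1)
    assert set(small) <= set(large)


# --- reconstruction --------------------------------------------------------

def _pathway(name, topology):
    return PathwayMap(name, frozenset(topology.nodes), topology)


def test_single_key_pathway_fully_affected_chain():
    kp = KeyPathway("P", 0.01, 0.01, 0.001, True)
    net = reconstruct_causal_network([kp], [_pathway("P", _chain_topology())],
                                     degs={"L", "R", "K"}, regulators={"T"})
    assert net.triggers >= {"L"}
    assert net.transcription_factors == {"T"}
    assert set(net.graph.nodes) == {"L", "R", "K", "T"}
    assert set(net.graph.edges) == {("L", "R"), ("R", "K"), ("K", "T")}


def test_no_affected_triggers_gives_empty_network(caplog):
    kp = KeyPathway("P", 0.01, 0.01, 0.001, True)
    with caplog.at_level("WARNING"):
        net = reconstruct_causal_network([kp],
                                         [_pathway("P", _chain_topology())],
                                         degs={"K"}, regulators={"T"})
    assert net.graph.number_of_nodes() == 0
    assert any("trigger" in r.message for r in caplog.records)


def test_non_key_pathways_are_ignored():
    kp = KeyPathway("P", 0.01, 0.01, 0.5, False)
    net = reconstruct_causal_network([kp], [_pathway("P", _chain_topology())],
                                     degs={"L", "R", "K"}, regulators={"T"})
    assert net.graph.number_of_nodes() == 0


def test_key_pathway_without_topology_skipped_with_warning(caplog):
    kp = KeyPathway("P", 0.01, 0.01, 0.001, True)
    bare = PathwayMap("P", frozenset({"L", "R"}), None)
    with caplog.at_level("WARNING"):
        net = reconstruct_causal_network([kp], [bare], {"L", "R"}, set())
    assert net.graph.number_of_nodes() == 0
    assert any("topology" in r.message for r in caplog.records)


def test_shared_tf_merges_with_both_provenances():
    g1 = _chain_topology()
    g2 = nx.DiGraph()
    for v, role in [("L2", "ligand"), ("K2", "transducer"),
                    ("T", "transcription-factor")]:
        g2.add_node(v, role=role)
    g2.add_edge("L2", "K2", effect="activation", mechanism="binding")
    g2.add_edge("K2", "T", effect="inhibition", mechanism="binding")
    keys = [KeyPathway("P1", 0.01, 0.01, 0.001, True),
            KeyPathway("P2", 0.01, 0.01, 0.002, True)]
    net = reconstruct_causal_network(keys, [_pathway("P1", g1),
                                            _pathway("P2", g2)],
                                     degs={"L", "R", "K", "L2", "K2"},
                                     regulators={"T"})
    assert net.node_provenance("T") == {"P1", "P2"}
    # every edge exists in exactly one source topology
    union = set(g1.edges) | set(g2.edges)
    assert set(net.graph.edges) <= union


def test_module_groups_attach_affected_members():
    topo = _chain_topology()
    pmap = PathwayMap("P", frozenset(list(topo.nodes) + ["M1", "M2"]),
                      topo, {"complex": frozenset({"M1", "M2"})})
    kp = KeyPathway("P", 0.01, 0.01, 0.001, True)
    net = reconstruct_causal_network([kp], [pmap],
                                     degs={"L", "R", "K", "M1"},
                                     regulators={"T"})
    assert "module-group" in net.graph.nodes["M1"]["annotations"]
    assert "M2" not in net.graph.nodes  # unaffected member not attached
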
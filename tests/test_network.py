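"""Network inference, modules, Zi-Pi roles, baselines and facilitators."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mycohub.io import AsvCountTable, SampleMetadata, TaxonomyTable, TAXONOMY_RANKS
from mycohub.network import (
    CategoryDef,
    CoocNetwork,
    ModulePartition,
    classify_roles,
    clr_transform,
    degree_powerlaw_fit,
    export_graph,
    facilitator_ranking,
    fast_greedy_modules,
    filter_category_asvs,
    infer_network,
    random_graph_baseline,
    register_backend,
    zi_pi,
)


def test_clr_rows_sum_to_zero():
    df = pd.DataFrame([[1, 5, 10], [0, 3, 7]], index=["s1", "s2"],
                      columns=["a", "b", "c"])
    clr = clr_transform(df)
    assert np.allclose(clr.sum(axis=1), 0.0)


def test_infer_network_finds_planted_pair():
    rng = np.random.default_rng(3)
    n = 24
    base = rng.poisson(100, size=(n, 6))
    shared = rng.lognormal(0, 1.0, size=n)
    pair = rng.poisson(np.outer(shared, [200.0, 200.0]))
    counts = np.hstack([pair, base])
    tab = AsvCountTable(pd.DataFrame(
        counts, index=[f"s{i}" for i in range(n)],
        columns=[f"A{j}" for j in range(8)]))
    net = infer_network(tab, n_perm=1000, q_max=0.05, seed=1)
    assert net.graph.has_edge("A0", "A1")
    assert net.graph.edges["A0", "A1"]["weight"] > 0
    # determinism
    net2 = infer_network(tab, n_perm=1000, q_max=0.05, seed=1)
    assert set(net.graph.edges) == set(net2.graph.edges)


def test_infer_network_errors():
    small = AsvCountTable(pd.DataFrame(
        np.ones((4, 3), dtype=int), index=list("abcd"), columns=list("xyz")))
    with pytest.raises(ValueError, match="8 samples"):
        infer_network(small)
    ok = AsvCountTable(pd.DataFrame(
        np.arange(1, 9).reshape(8, 1), index=[f"s{i}" for i in range(8)],
        columns=["x"]))
    with pytest.raises(ValueError, match="2 ASVs"):
        infer_network(ok)
    with pytest.raises(ValueError, match="registered backends"):
        infer_network(small, method="nope")


def test_register_backend():
    def trivial(table, **kwargs):
        g = nx.Graph()
        g.add_nodes_from(table.counts.columns)
        return g

    register_backend("trivial", trivial)
    tab = AsvCountTable(pd.DataFrame([[1, 2]], index=["s"], columns=["a", "b"]))
    net = infer_network(tab, method="trivial")
    assert net.n_edges == 0


def test_two_cliques_modularity_half():
    g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
    g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
    part = fast_greedy_modules(CoocNetwork(g))
    assert part.modularity_Q == pytest.approx(0.5)
    members = part.members()
    assert sorted(len(v) for v in members.values()) == [5, 5]


def test_edgeless_graph_gets_singletons():
    g = nx.Graph()
    g.add_nodes_from(["a", "b", "c"])
    part = fast_greedy_modules(CoocNetwork(g))
    assert part.modularity_Q == 0.0
    assert len(set(part.assignment.values())) == 3


def test_self_edge_rejected():
    g = nx.Graph()
    g.add_edge("a", "a")
    with pytest.raises(ValueError, match="self-edge"):
        CoocNetwork(g)


def test_zi_pi_bridge_example():
    # hub with 4 edges: 3 inside its module, 1 outside -> pi = 1 - (9+1)/16
    g = nx.Graph()
    g.add_edges_from([("h", "a"), ("h", "b"), ("h", "c"), ("h", "x")])
    part = ModulePartition({"h": 0, "a": 0, "b": 0, "c": 0, "x": 1}, 0.0)
    roles = {r.node: r for r in zi_pi(CoocNetwork(g), part)}
    assert roles["h"].pi == pytest.approx(0.375)
    assert roles["x"].pi == pytest.approx(0.0)


def test_zi_pi_isolated_node_zero():
    g = nx.Graph()
    g.add_nodes_from(["a", "b"])
    g.add_edge("a", "b")
    g.add_node("lone")
    part = ModulePartition({"a": 0, "b": 0, "lone": 1}, 0.0)
    roles = {r.node: r for r in zi_pi(CoocNetwork(g), part)}
    assert (roles["lone"].zi, roles["lone"].pi) == (0.0, 0.0)


def test_classify_roles_thresholds():
    from mycohub.network import NodeRole

    labeled = {r.node: r.role for r in classify_roles([
        NodeRole("boundary", 2.5, 0.62),
        NodeRole("nhub", 2.6, 0.63),
        NodeRole("mhub", 2.6, 0.1),
        NodeRole("conn", 0.0, 0.63),
        NodeRole("peri", 0.0, 0.1),
    ])}
    assert labeled == {
        "boundary": "peripheral",   # boundary falls on the peripheral side
        "nhub": "network_hub",
        "mhub": "module_hub",
        "conn": "connector",
        "peri": "peripheral",
    }


def test_degree_powerlaw_exact_fit():
    # degree histogram freq = 36 / k^2 for k = 1, 2, 3 -> gamma = 2, R^2 = 1
    seq = [1] * 36 + [2] * 9 + [3] * 4
    g = nx.havel_hakimi_graph(seq)
    g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
    fit = degree_powerlaw_fit(CoocNetwork(g))
    assert fit["gamma"] == pytest.approx(2.0, abs=1e-9)
    assert fit["R2"] == pytest.approx(1.0, abs=1e-12)


def test_degree_powerlaw_needs_three_degrees():
    g = nx.complete_graph(4)
    fit = degree_powerlaw_fit(CoocNetwork(nx.relabel_nodes(
        g, {i: str(i) for i in g.nodes})))
    assert fit == {"gamma": None, "R2": None}


def test_random_graph_baseline_summary():
    g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
    g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
    s = random_graph_baseline(CoocNetwork(g), R=20, seed=5)
    assert s.n_nodes == 10 and s.n_edges == 20 and s.n_random == 20
    assert s.modularity_Q == pytest.approx(0.5)
    assert s.null_Q_sd >= 0.0
    assert s.z_modularity > 0  # two cliques are far more modular than G(n, m)
    with pytest.raises(ValueError):
        random_graph_baseline(CoocNetwork(g), R=0)


def test_filter_category_strict_threshold(tiny_table, tiny_meta):
    cat = CategoryDef("leafy", ("X",), ("leaf",))
    # leaf totals: A1 = 10, A2 = 8, A3 = 7
    sub = filter_category_asvs(tiny_table, tiny_meta, cat, min_reads=7)
    assert sub.asv_ids == ["A1", "A2"]
    sub2 = filter_category_asvs(tiny_table, tiny_meta, cat, min_reads=10)
    assert sub2.asv_ids == []  # strict: exactly 10 does not pass
    with pytest.raises(ValueError, match="no samples"):
        filter_category_asvs(tiny_table, tiny_meta,
                             CategoryDef("none", ("Y",), ("leaf",)))


def _taxonomy(genus_map):
    df = pd.DataFrame({r: ["" for _ in genus_map] for r in TAXONOMY_RANKS},
                      index=pd.Index(list(genus_map), name="asv_id"))
    df["genus"] = list(genus_map.values())
    return TaxonomyTable(df)


def test_facilitator_ranking_flags_and_cautions():
    # producer network with 4 modules, each holding one PHP ASV plus a member
    # of genus G; one genus U-unclassified member; non-producer network with
    # genus H next to a PHP ASV
    g1 = nx.Graph()
    assignment = {}
    genus_map = {}
    php = set()
    for m in range(4):
        p, f, u = f"php{m}", f"fac{m}", f"unk{m}"
        g1.add_edges_from([(p, f), (f, u)])
        assignment.update({p: m, f: m, u: m})
        php.add(p)
        genus_map[p] = "Producerella"
        genus_map[f] = "Goodfriendia"
        genus_map[u] = ""
    part1 = ModulePartition(assignment, 0.4)
    g2 = nx.Graph()
    g2.add_edge("php0", "other")
    part2 = ModulePartition({"php0": 0, "other": 0}, 0.0)
    genus_map["other"] = "Shyfriendia"
    tax = _taxonomy(genus_map)
    fac = facilitator_ranking(
        {"A": (CoocNetwork(g1), part1), "C": (CoocNetwork(g2), part2)},
        php, tax, producer_networks={"A"}, flag_min=4,
    ).set_index("genus")
    assert bool(fac.loc["Goodfriendia", "flagged"])
    assert not bool(fac.loc["Goodfriendia", "cautioned"])
    assert not bool(fac.loc["unclassified", "flagged"])  # never flagged
    assert bool(fac.loc["Shyfriendia", "cautioned"])     # non-producer only
    assert not bool(fac.loc["Shyfriendia", "flagged"])


def test_export_graph_round_trip(tmp_path):
    g = nx.Graph()
    g.add_edge("a", "b", weight=0.9, q=0.01)
    net = CoocNetwork(g)
    part = ModulePartition({"a": 0, "b": 0}, 0.0)
    roles = classify_roles(zi_pi(net, part))
    path = tmp_path / "net.graphml"
    export_graph(net, path, partition=part, roles=roles, fmt="graphml")
    back = nx.read_graphml(path)
    assert back.nodes["a"]["module"] == 0
    assert back.nodes["a"]["role"] == "peripheral"
    assert back.nodes["a"]["degree"] == 1
    tsv = tmp_path / "net.tsv"
    export_graph(net, tsv, fmt="tsv")
    frame = pd.read_csv(tsv, sep="\t")
    assert list(frame.columns) == ["source", "target", "weight", "q"]
    with pytest.raises(ValueError, match="unknown export format"):
        export_graph(net, tmp_path / "x", fmt="dot")
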
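import random

import networkx as nx
import pytest

from seednet.geneset_io import SeedList
from seednet.interactome import Interactome
from seednet.steiner import (approximate_steiner_tree, brute_force_steiner,
                             export_subnetwork, extract_connectors,
                             key_node_neighborhood)


def seed(*genes):
    return SeedList(label="t", genes=frozenset(genes))


def random_instance(rnd):
    n = rnd.randint(8, 14)
    g = nx.gnp_random_graph(n, rnd.uniform(0.25, 0.45),
                            seed=rnd.randint(0, 10 ** 6))
    g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
    terms = rnd.sample(sorted(g.nodes), rnd.randint(3, 5))
    return Interactome(graph=g), seed(*terms)


def test_unique_path_instance(path_net):
    res = approximate_steiner_tree(path_net, seed("A", "E"))
    assert res.n_nodes == 5 and res.n_edges == 4
    assert res.connectors == {"B", "C", "D"}
    assert res.terminals_included == {"A", "E"}
    exact = brute_force_steiner(path_net, seed("A", "E"))
    assert exact.subnetwork.edges == res.subnetwork.edges


def test_forced_hub(star_net):
    res = approximate_steiner_tree(star_net, seed("T1", "T2", "T3"))
    assert res.n_nodes == 4 and res.n_edges == 3
    assert res.connectors == {"H"}


def test_triangle_with_pendants():
    g = nx.Graph([("A", "B"), ("B", "C"), ("C", "A"), ("T1", "A"), ("T2", "B")])
    net = Interactome(graph=g)
    exact = brute_force_steiner(net, seed("T1", "T2"))
    assert exact.n_edges == 3
    assert exact.connectors == {"A", "B"}


def test_adjacent_terminals_need_no_connector():
    net = Interactome.from_edges([("A", "B"), ("B", "C")])
    exact = brute_force_steiner(net, seed("A", "B"))
    assert exact.n_edges == 1 and exact.connectors == set()


def test_brute_force_rejects_large_instance():
    g = nx.path_graph(20)
    g = nx.relabel_nodes(g, {i: f"N{i:02d}" for i in g.nodes})
    with pytest.raises(ValueError, match="too large"):
        brute_force_steiner(Interactome(graph=g), seed("N00", "N19"))


def test_missing_and_disconnected_terminals():
    g = nx.Graph([("A", "B"), ("X", "Y")])
    net = Interactome(graph=g)
    res = approximate_steiner_tree(net, seed("A", "B", "X", "GHOST"))
    assert res.terminals_included == {"A", "B"}
    assert res.unreachable_terminals == {"X", "GHOST"}
    with pytest.raises(ValueError, match="nothing to connect"):
        approximate_steiner_tree(net, seed("A", "GHOST"))


def test_forest_mode_spans_both_components():
    g = nx.Graph([("A", "M", {}), ("M", "B", {}), ("X", "Y", {})])
    net = Interactome(graph=g)
    res = approximate_steiner_tree(net, seed("A", "B", "X", "Y"), forest=True)
    assert res.terminals_included == {"A", "B", "X", "Y"}
    assert res.connectors == {"M"}
    assert not res.is_tree  # a forest, flagged as such


def test_induced_edges_mode():
    g = nx.Graph([("T1", "A"), ("A", "T2"), ("T1", "T2")])
    net = Interactome(graph=g)
    tree = approximate_steiner_tree(net, seed("T1", "T2"))
    assert tree.n_edges == 1  # direct edge wins
    dense = approximate_steiner_tree(net, seed("T1", "T2", "A"),
                                     induce_edges=True)
    assert dense.n_edges == 3 and not dense.is_tree


def test_tree_identity_and_approximation_bound():
    rnd = random.Random(1234)
    checked = 0
    while checked < 30:
        net, terms = random_instance(rnd)
        try:
            exact = brute_force_steiner(net, terms)
        except ValueError:
            continue
        approx = approximate_steiner_tree(net, terms)
        approx.validate()
        assert approx.n_edges == approx.n_nodes - 1
        assert approx.terminals_included == exact.terminals_included
        assert approx.n_edges <= 2 * exact.n_edges
        checked += 1


def test_determinism_identical_runs():
    rnd = random.Random(7)
    net, terms = random_instance(rnd)
    a = approximate_steiner_tree(net, terms)
    b = approximate_steiner_tree(net, terms)
    assert a.subnetwork.edges == b.subnetwork.edges
    assert a.connectors == b.connectors


def test_shortcut_edge_never_hurts():
    # adding an edge between two existing tree nodes must not grow the tree
    rnd = random.Random(99)
    for _ in range(20):
        net, terms = random_instance(rnd)
        try:
            before = approximate_steiner_tree(net, terms)
        except ValueError:
            continue
        nodes = sorted(before.subnetwork.nodes)
        if len(nodes) < 2:
            continue
        u, v = nodes[0], nodes[-1]
        g2 = nx.Graph(net.graph)
        g2.add_edge(u, v)
        after = approximate_steiner_tree(Interactome(graph=g2), terms)
        assert after.n_edges <= before.n_edges


def test_extract_connectors(path_net):
    res = approximate_steiner_tree(path_net, seed("A", "E"))
    assert extract_connectors(res, seed("A", "E")) == {"B", "C", "D"}
    star = approximate_steiner_tree(
        Interactome.from_edges([("A", "B"), ("B", "C")]), seed("A", "B", "C"))
    assert extract_connectors(star, seed("A", "B", "C")) == set()


def test_neighborhood_report(star_net):
    rep = key_node_neighborhood(star_net, {"H"}, seed("T1", "T2", "T3"))
    assert rep.seed_fraction == 1.0
    assert rep.neighborhood.n_nodes == 4

    lonely = Interactome.from_edges([("A", "B")], nodes=["Z"])
    rep0 = key_node_neighborhood(lonely, {"Z"}, seed("A"))
    assert rep0.seed_fraction == 0.0

    with pytest.raises(ValueError, match="focus"):
        key_node_neighborhood(star_net, set(), seed("T1"))
    with pytest.raises(ValueError, match="absent"):
        key_node_neighborhood(star_net, {"NOPE"}, seed("T1"))


def test_neighborhood_planted_fraction():
    # 69 neighbors of a hub, 54 of them seeds: fraction 54/69
    g = nx.Graph()
    neighbors = [f"N{i:02d}" for i in range(69)]
    for n in neighbors:
        g.add_edge("HUB", n)
    seeds = seed(*neighbors[:54])
    rep = key_node_neighborhood(Interactome(graph=g), {"HUB"}, seeds)
    assert rep.seed_fraction == pytest.approx(54 / 69)


def test_export_subnetwork_files(tmp_path, path_net):
    res = approximate_steiner_tree(path_net, seed("A", "E"))
    paths = export_subnetwork(res, seed("A", "E"), tmp_path / "sub")
    names = {p.name for p in paths}
    assert names == {"sub.sif", "sub.tsv", "sub.graphml", "sub_connectors.tsv"}
    connectors = (tmp_path / "sub_connectors.tsv").read_text().split()
    assert connectors == ["B", "C", "D"]
    back = nx.read_graphml(tmp_path / "sub.graphml")
    assert back.nodes["A"]["role"] == "seed"
    assert back.nodes["B"]["role"] == "connector"
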
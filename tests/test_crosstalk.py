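import itertools
from fractions import Fraction

import networkx as nx
import pytest
from hypothesis import given, settings, strategies as st

from seednet.crosstalk import (build_crosstalk_network, crosstalk_score,
                               export_network, jaccard, overlap_coefficient)
from seednet.geneset_io import GeneSet, GeneSetCollection

genes = st.sets(st.sampled_from([f"G{i}" for i in range(20)]), min_size=1,
                max_size=12)


def make(a):
    return GeneSet("A", "a", frozenset(a))


def make_b(b):
    return GeneSet("B", "b", frozenset(b))


def oracle_pair(a: set, b: set):
    """Independent set-arithmetic oracle, exact rationals."""
    inter = len(a & b)
    j = Fraction(inter, len(a | b))
    o = Fraction(inter, min(len(a), len(b)))
    return j, o, (j + o) / 2


def test_identical_and_disjoint_sets():
    a = make({"X", "Y"})
    assert jaccard(a, a) == overlap_coefficient(a, a) == crosstalk_score(a, a) == 1.0
    b = make_b({"P", "Q"})
    assert jaccard(a, b) == crosstalk_score(a, b) == 0.0


def test_subset_gives_full_overlap_coefficient():
    a = make({"X", "Y"})
    b = make_b({"X", "Y", "Z", "W"})
    assert overlap_coefficient(a, b) == 1.0
    assert jaccard(a, b) == pytest.approx(0.5)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(genes, genes)
def test_coefficient_ordering_property(a, b):
    A, B = make(a), make_b(b)
    j, o, s = jaccard(A, B), overlap_coefficient(A, B), crosstalk_score(A, B)
    oj, oo, os = oracle_pair(set(a), set(b))
    assert j == pytest.approx(float(oj))
    assert o == pytest.approx(float(oo))
    assert s == pytest.approx(float(os))
    assert 0.0 <= j <= o <= 1.0
    assert j <= s <= o


def test_fixture_pair_circadian_glutamatergic(mdd):
    _, pathways, _ = mdd
    a = pathways["Circadian entrainment"]
    b = pathways["Glutamatergic synapse"]
    assert len(a) == 15 and len(b) == 22
    assert len(a.members & b.members) == 14
    assert jaccard(a, b) == pytest.approx(14 / 23)
    assert overlap_coefficient(a, b) == pytest.approx(14 / 15)
    assert crosstalk_score(a, b) == pytest.approx((14 / 23 + 14 / 15) / 2)
    # the excluded genes named by the independent transcription check
    assert b.members - a.members >= {"CACNA1A", "GRIK1", "GRIK4", "GRM7",
                                     "GRM8", "SLC1A2", "PLD1", "HOMER1"}


def test_fixture_pair_without_shared_genes(mdd):
    _, pathways, _ = mdd
    a = pathways["Circadian rhythm"]
    b = pathways["Tryptophan metabolism"]
    assert not a.members & b.members
    net = build_crosstalk_network(pathways, min_shared=3)
    assert not any({e.set_a, e.set_b} == {a.set_id, b.set_id} for e in net.edges)


def test_network_matches_double_loop_oracle(mdd):
    _, pathways, _ = mdd
    net = build_crosstalk_network(pathways, min_shared=3)
    expected = set()
    for a, b in itertools.combinations(pathways, 2):
        if len(a.members & b.members) >= 3:
            expected.add(frozenset((a.set_id, b.set_id)))
    got = {frozenset((e.set_a, e.set_b)) for e in net.edges}
    assert got == expected
    assert len(got) == len(net.edges)  # pair uniqueness
    assert all(e.set_a < e.set_b for e in net.edges)
    scores = [e.score for e in net.edges]
    assert scores == sorted(scores, reverse=True)


def test_min_shared_filtering_is_monotone(mdd):
    _, pathways, _ = mdd
    prev_nodes = prev_edges = None
    for ms in (2, 3, 4, 5, 6):
        net = build_crosstalk_network(pathways, min_shared=ms)
        if prev_nodes is not None:
            assert net.n_nodes <= prev_nodes
            assert net.n_edges <= prev_edges
        prev_nodes, prev_edges = net.n_nodes, net.n_edges


def test_disjoint_only_collection_gives_empty_network():
    coll = GeneSetCollection("d", [
        GeneSet("P1", "a", frozenset({"A", "B", "C"})),
        GeneSet("P2", "b", frozenset({"X", "Y", "Z"})),
    ])
    net = build_crosstalk_network(coll, min_shared=3)
    assert net.n_nodes == 0 and net.n_edges == 0


def test_build_validations(toy_collection):
    with pytest.raises(ValueError):
        build_crosstalk_network(toy_collection, min_shared=0)
    one = GeneSetCollection("one", [GeneSet("P1", "a", frozenset({"A"}))])
    with pytest.raises(ValueError):
        build_crosstalk_network(one)


def test_score_cutoff_flag(toy_collection):
    full = build_crosstalk_network(toy_collection, min_shared=3)
    assert full.n_edges == 1
    none = build_crosstalk_network(toy_collection, min_shared=3, score_cutoff=0.99)
    assert none.n_edges == 0


def test_export_formats(tmp_path, toy_collection):
    net = build_crosstalk_network(toy_collection, min_shared=3)
    sif = export_network(net, tmp_path / "n.sif", "sif")
    assert sif.read_text() == "P1\tcrosstalk\tP2\n"
    tsv = export_network(net, tmp_path / "n.tsv", "tsv")
    lines = tsv.read_text().splitlines()
    assert lines[0].split("\t") == ["set_a", "set_b", "n_shared", "jaccard",
                                    "overlap", "score", "shared_genes"]
    assert len(lines) == 2
    gml = export_network(net, tmp_path / "n.graphml", "graphml")
    back = nx.read_graphml(gml)
    assert back.number_of_edges() == 1
    attrs = back.edges["P1", "P2"]
    assert attrs["n_shared"] == 3
    with pytest.raises(ValueError, match="unknown format"):
        export_network(net, tmp_path / "n.x", "xml")


def test_export_empty_graphml_is_valid(tmp_path):
    coll = GeneSetCollection("d", [
        GeneSet("P1", "a", frozenset({"A"})),
        GeneSet("P2", "b", frozenset({"X"})),
    ])
    net = build_crosstalk_network(coll)
    gml = export_network(net, tmp_path / "empty.graphml", "graphml")
    assert nx.read_graphml(gml).number_of_nodes() == 0
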
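import networkx as nx
import pytest

from seednet.geneset_io import GeneSet, GeneSetCollection, SeedList, load_mdd_fixtures
from seednet.interactome import Interactome


@pytest.fixture(scope="session")
def mdd():
    """(seeds, pathways, connectors) bundled study fixtures."""
    return load_mdd_fixtures()


@pytest.fixture()
def path_net():
    """Path A-B-C-D-E as an interactome."""
    g = nx.relabel_nodes(nx.path_graph(5), dict(enumerate("ABCDE")))
    return Interactome(graph=g)


@pytest.fixture()
def star_net():
    """Hub H with terminal leaves T1..T3."""
    g = nx.Graph()
    g.add_edges_from([("H", "T1"), ("H", "T2"), ("H", "T3")])
    return Interactome(graph=g)


@pytest.fixture()
def toy_collection():
    return GeneSetCollection(
        source_label="toy",
        sets=[
            GeneSet("P1", "first", frozenset({"A", "B", "C", "D"})),
            GeneSet("P2", "second", frozenset({"B", "C", "D", "E"})),
            GeneSet("P3", "third", frozenset({"X", "Y", "Z"})),
        ],
    )


@pytest.fixture()
def seed_ab():
    return SeedList(label="toy-seeds", genes=frozenset({"A", "B"}))
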
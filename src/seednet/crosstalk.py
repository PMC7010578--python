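"""Pathway cross-talk network construction.

Two pathways "cross-talk" when they share enough of the disease seed genes.
Overlap strength for a pair of seed-restricted memberships A, B is scored by

* Jaccard coefficient  ``|A ∩ B| / |A ∪ B|``
* Overlap coefficient  ``|A ∩ B| / min(|A|, |B|)``
* cross-talk score: the arithmetic mean of the two.

An edge is created when the pair shares at least ``min_shared`` genes
(default 3); the coefficients rank edges but do not gate them unless an
explicit ``score_cutoff`` is requested.  Pathways left without any edge are
dropped from the network.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

from .geneset_io import GeneSet, GeneSetCollection

__all__ = [
    "CrosstalkEdge",
    "CrosstalkNetwork",
    "jaccard",
    "overlap_coefficient",
    "crosstalk_score",
    "build_crosstalk_network",
    "export_network",
]


def jaccard(a: GeneSet, b: GeneSet) -> float:
    """``|A ∩ B| / |A ∪ B|`` for two non-empty gene sets."""
    if not a.members or not b.members:
        raise ValueError("jaccard undefined for empty sets")
    return len(a.members & b.members) / len(a.members | b.members)


def overlap_coefficient(a: GeneSet, b: GeneSet) -> float:
    """``|A ∩ B| / min(|A|, |B|)`` for two non-empty gene sets."""
    if not a.members or not b.members:
        raise ValueError("overlap coefficient undefined for empty sets")
    return len(a.members & b.members) / min(len(a.members), len(b.members))


def crosstalk_score(a: GeneSet, b: GeneSet) -> float:
    """Arithmetic mean of the Jaccard and Overlap coefficients."""
    return (jaccard(a, b) + overlap_coefficient(a, b)) / 2.0


@dataclass(frozen=True)
class CrosstalkEdge:
    set_a: str
    set_b: str
    shared: frozenset[str]
    jaccard: float
    overlap: float
    score: float

    def __post_init__(self) -> None:
        if self.set_a >= self.set_b:
            raise ValueError("edges must be canonically oriented (set_a < set_b)")


@dataclass
class CrosstalkNetwork:
    """Nodes are pathway ids with >= 1 edge; edges sorted by descending score."""

    nodes: list[str]
    edges: list[CrosstalkEdge]

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.set_a, e.set_b, jaccard=e.jaccard, overlap=e.overlap,
                       score=e.score, n_shared=len(e.shared),
                       shared_genes=",".join(sorted(e.shared)))
        return g


def build_crosstalk_network(
    collection: GeneSetCollection,
    min_shared: int = 3,
    score_cutoff: float | None = None,
) -> CrosstalkNetwork:
    """Evaluate all unordered pathway pairs and keep those sharing
    ``min_shared`` or more genes (optionally also ``score >= score_cutoff``).

    Edges are sorted by descending score, ties by ``(set_a, set_b)``;
    pathways that end up isolated are excluded from the node list.
    """
    if min_shared < 1:
        raise ValueError("min_shared must be >= 1")
    if len(collection) < 2:
        raise ValueError("need at least two gene sets")
    edges: list[CrosstalkEdge] = []
    for a, b in itertools.combinations(collection, 2):
        first, second = sorted((a, b), key=lambda s: s.set_id)
        shared = first.members & second.members
        if len(shared) < min_shared:
            continue
        j = jaccard(first, second)
        o = overlap_coefficient(first, second)
        s = (j + o) / 2.0
        if score_cutoff is not None and s < score_cutoff:
            continue
        edges.append(CrosstalkEdge(set_a=first.set_id, set_b=second.set_id,
                                   shared=frozenset(shared), jaccard=j,
                                   overlap=o, score=s))
    edges.sort(key=lambda e: (-e.score, e.set_a, e.set_b))
    connected = sorted({n for e in edges for n in (e.set_a, e.set_b)})
    return CrosstalkNetwork(nodes=connected, edges=edges)


def export_network(net: CrosstalkNetwork, path: str | Path, format: str = "tsv") -> Path:
    """Write the network as SIF, GraphML or TSV (Cytoscape-ready)."""
    path = Path(path)
    fmt = format.lower()
    if fmt == "sif":
        with open(path, "w") as fh:
            for e in net.edges:
                fh.write(f"{e.set_a}\tcrosstalk\t{e.set_b}\n")
    elif fmt == "graphml":
        nx.write_graphml(net.to_graph(), path)
    elif fmt == "tsv":
        with open(path, "w") as fh:
            fh.write("set_a\tset_b\tn_shared\tjaccard\toverlap\tscore\tshared_genes\n")
            for e in net.edges:
                fh.write(
                    f"{e.set_a}\t{e.set_b}\t{len(e.shared)}\t{e.jaccard:.6f}\t"
                    f"{e.overlap:.6f}\t{e.score:.6f}\t{','.join(sorted(e.shared))}\n"
                )
    else:
        raise ValueError(f"unknown format {format!r} (expected sif, graphml or tsv)")
    return path
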
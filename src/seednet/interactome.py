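"""Protein–protein interactome ingestion, cleaning and merging.

An interactome here is a simple undirected graph over gene symbols: no
self-loops, no duplicate unordered pairs, unweighted edges.  Cleaning is
idempotent and merging is a plain union with the invariants re-asserted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .geneset_io import normalize_symbols

__all__ = ["Interactome", "read_interactions", "merge_networks", "degree_table",
           "write_interactions"]

log = logging.getLogger(__name__)


@dataclass
class Interactome:
    """Simple undirected graph over uppercase gene symbols."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str]],
                   nodes: Iterable[str] = ()) -> "Interactome":
        """Build from raw symbol pairs; self-loops and duplicates are dropped."""
        g = nx.Graph()
        n_self = n_dup = 0
        for u, v in edges:
            (u,) = normalize_symbols([u]) or {""}
            (v,) = normalize_symbols([v]) or {""}
            if not u or not v:
                continue
            if u == v:
                n_self += 1
                continue
            if g.has_edge(u, v):
                n_dup += 1
                continue
            g.add_edge(u, v)
        for n in normalize_symbols(nodes):
            g.add_node(n)
        if n_self or n_dup:
            log.info("dropped %d self-loops and %d duplicate pairs", n_self, n_dup)
        return cls(graph=g)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset((u, v)) for u, v in self.graph.edges}

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def subgraph(self, nodes: Iterable[str]) -> "Interactome":
        return Interactome(graph=nx.Graph(self.graph.subgraph(nodes)))


def read_interactions(path: str | Path, format: str | None = None) -> Interactome:
    """Read a TSV edge list (>=2 columns, extras ignored) or a SIF file.

    Format is inferred from the suffix when not given.  Symbols are
    uppercased; self-loops and duplicate pairs (either orientation) are
    dropped and counted in the log.  An empty file yields an empty graph
    with a warning, not an error.
    """
    path = Path(path)
    fmt = (format or ("sif" if path.suffix.lower() == ".sif" else "tsv")).lower()
    if fmt not in {"tsv", "sif"}:
        raise ValueError(f"unknown interactome format {fmt!r}")
    pairs: list[tuple[str, str]] = []
    lone_nodes: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if fmt == "sif":
                # "A relation B [C ...]"; a single-field line is an isolated node
                if len(fields) == 1:
                    lone_nodes.append(fields[0])
                    continue
                if len(fields) < 3:
                    raise ValueError(f"{path}:{lineno}: malformed SIF line: {line!r}")
                src, targets = fields[0], fields[2:]
                pairs.extend((src, t) for t in targets)
            else:
                if len(fields) < 2:
                    raise ValueError(f"{path}:{lineno}: expected >=2 columns: {line!r}")
                if lineno == 1 and _looks_like_header(fields):
                    continue
                pairs.append((fields[0], fields[1]))
    if not pairs and not lone_nodes:
        log.warning("%s: no interactions found, returning empty graph", path)
    return Interactome.from_edges(pairs, nodes=lone_nodes)


def _looks_like_header(fields: Sequence[str]) -> bool:
    lowered = {f.strip().lower() for f in fields[:2]}
    return bool(lowered & {"source", "target", "gene_a", "gene_b", "protein1",
                           "protein2", "node_a", "node_b", "symbol_a", "symbol_b"})


def write_interactions(net: Interactome, path: str | Path, format: str = "tsv") -> Path:
    path = Path(path)
    fmt = format.lower()
    ordered = sorted(tuple(sorted(e)) for e in net.edges)
    isolated = sorted(n for n in net.nodes if net.graph.degree[n] == 0)
    with open(path, "w") as fh:
        if fmt == "tsv":
            for u, v in ordered:
                fh.write(f"{u}\t{v}\n")
        elif fmt == "sif":
            for u, v in ordered:
                fh.write(f"{u}\tpp\t{v}\n")
            for n in isolated:
                fh.write(f"{n}\n")
        else:
            raise ValueError(f"unknown format {format!r}")
    return path


def merge_networks(nets: Sequence[Interactome]) -> Interactome:
    """Union of node and edge sets; cleaning invariants re-asserted."""
    if not nets:
        raise ValueError("nothing to merge: empty network list")
    edges: list[tuple[str, str]] = []
    nodes: set[str] = set()
    for net in nets:
        edges.extend(tuple(sorted(e)) for e in net.edges)
        nodes |= net.nodes
    return Interactome.from_edges(edges, nodes=nodes)


def degree_table(net: Interactome) -> dict[str, int]:
    """Degree of every node (handshake identity: values sum to 2|E|)."""
    return {n: int(d) for n, d in net.graph.degree}
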
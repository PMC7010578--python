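"""Steiner-tree extraction of a seed-gene subnetwork from an interactome.

The problem: connect as many seed genes (terminals) as possible through as
few non-seed "connector" genes as possible.  Finding the minimum Steiner
tree is NP-hard, so the package uses the classic shortest-path
2-approximation: build the metric closure over terminals, take its minimum
spanning tree, expand each closure edge back into a concrete shortest path,
re-extract a spanning tree of the expanded subgraph and prune non-terminal
leaves.  On a graph with unit edge weights the result has at most twice the
optimal number of edges.  All tie-breaks are lexicographic on node names,
so identical inputs always give identical trees.

Terminals missing from the graph, or stranded in other components, are
reported as unreachable rather than raised; the tree is built on the
connected component holding the most terminals (optionally one tree per
eligible component in forest mode).
"""

from __future__ import annotations

import heapq
import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx

from .geneset_io import SeedList
from .interactome import Interactome

__all__ = [
    "SteinerResult",
    "NeighborhoodReport",
    "approximate_steiner_tree",
    "brute_force_steiner",
    "extract_connectors",
    "key_node_neighborhood",
    "export_subnetwork",
]

log = logging.getLogger(__name__)


@dataclass
class SteinerResult:
    subnetwork: Interactome
    terminals_included: frozenset[str]
    connectors: frozenset[str]
    unreachable_terminals: frozenset[str]
    is_tree: bool = True

    @property
    def n_nodes(self) -> int:
        return self.subnetwork.n_nodes

    @property
    def n_edges(self) -> int:
        return self.subnetwork.n_edges

    def validate(self) -> None:
        g = self.subnetwork.graph
        if set(g.nodes) != set(self.terminals_included) | set(self.connectors):
            raise AssertionError("tree nodes != terminals ∪ connectors")
        if self.terminals_included & self.connectors:
            raise AssertionError("terminals and connectors overlap")
        if self.is_tree and g.number_of_nodes() > 0:
            if not nx.is_tree(g):
                raise AssertionError("subnetwork is not a tree")


@dataclass
class NeighborhoodReport:
    focus_genes: frozenset[str]
    neighborhood: Interactome
    seed_fraction: float


def _canonical_path(g: nx.Graph, dist: dict[str, int], target: str) -> list[str]:
    """Walk back from target to the BFS source along lexicographically
    smallest predecessors; returns the path source->target."""
    path = [target]
    cur = target
    while dist[cur] > 0:
        cur = min(n for n in g.neighbors(cur) if dist.get(n, -1) == dist[cur] - 1)
        path.append(cur)
    return path[::-1]


def _node_weighted_dist(g: nx.Graph, source: str, terminals: set[str]
                        ) -> dict[str, int]:
    """Dijkstra where entering a non-terminal costs 1 and a terminal costs 0
    (minimises interlinking nodes rather than hops)."""
    dist = {source: 0}
    heap = [(0, source)]
    while heap:
        d, u = heapq.heappop(heap)
        if d > dist.get(u, 1 << 30):
            continue
        for v in sorted(g.neighbors(u)):
            nd = d + (0 if v in terminals else 1)
            if nd < dist.get(v, 1 << 30):
                dist[v] = nd
                heapq.heappush(heap, (nd, v))
    return dist


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        if rb < ra:  # deterministic root choice
            ra, rb = rb, ra
        self.parent[rb] = ra
        return True


def _kruskal(nodes, weighted_edges):
    """MST edges from (weight, u, v) tuples with lexicographic tie-break."""
    uf = _UnionFind(nodes)
    mst = []
    for w, u, v in sorted(weighted_edges):
        if uf.union(u, v):
            mst.append((w, u, v))
    return mst


def _pick_component(g: nx.Graph, terminals: set[str]) -> list[set[str]]:
    """Components ranked by (terminal count desc, smallest member asc)."""
    comps = [set(c) for c in nx.connected_components(g)]
    comps = [c for c in comps if len(c & terminals) >= 2]
    comps.sort(key=lambda c: (-len(c & terminals), min(c)))
    return comps


def _tree_for_component(g: nx.Graph, comp: set[str], terminals: set[str],
                        node_weighted: bool) -> nx.Graph:
    sub = g.subgraph(comp)
    terms = sorted(comp & terminals)
    dists: dict[str, dict[str, int]] = {}
    for t in terms:
        if node_weighted:
            dists[t] = _node_weighted_dist(sub, t, set(terms))
        else:
            dists[t] = nx.single_source_shortest_path_length(sub, t)
    closure = [(dists[a][b], a, b) for a, b in itertools.combinations(terms, 2)]
    expanded = nx.Graph()
    expanded.add_nodes_from(terms)
    termset = set(terms)
    for _, a, b in _kruskal(terms, closure):
        if node_weighted:
            # walk back from b along the node-weighted distance field; the
            # relaxation was dist[v] = dist[u] + cost(v), so a predecessor u
            # of cur satisfies dist[u] + cost(cur) == dist[cur]
            path = [b]
            cur = b
            while cur != a:
                step = 0 if cur in termset else 1
                cur = min(v for v in sub.neighbors(cur)
                          if dists[a].get(v, 1 << 30) + step == dists[a][cur])
                path.append(cur)
            nx.add_path(expanded, path[::-1])
        else:
            nx.add_path(expanded, _canonical_path(sub, dists[a], b))
    # spanning tree of the expanded subgraph, then prune non-terminal leaves
    mst_edges = _kruskal(sorted(expanded.nodes),
                         [(1, *sorted((u, v))) for u, v in expanded.edges])
    tree = nx.Graph()
    tree.add_nodes_from(expanded.nodes)
    tree.add_edges_from((u, v) for _, u, v in mst_edges)
    while True:
        leaves = [n for n in tree.nodes
                  if tree.degree[n] <= 1 and n not in termset]
        if not leaves:
            break
        tree.remove_nodes_from(leaves)
    return tree


def approximate_steiner_tree(
    net: Interactome,
    terminals: SeedList,
    node_weighted: bool = False,
    forest: bool = False,
    induce_edges: bool = False,
) -> SteinerResult:
    """Shortest-path 2-approximate Steiner tree over the seed genes.

    ``forest=True`` builds one tree per connected component holding >= 2
    terminals instead of only the richest component.  ``induce_edges=True``
    re-adds every interactome edge between tree nodes afterwards (the result
    is then a subnetwork, not a tree, and is flagged as such).
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("interactome is empty")
    term_all = set(terminals.genes)
    present = term_all & set(g.nodes)
    missing = term_all - present
    if missing:
        log.warning("%d terminals absent from the interactome", len(missing))
    comps = _pick_component(g, present)
    if not comps:
        raise ValueError("nothing to connect: fewer than 2 reachable terminals")
    chosen = comps if forest else comps[:1]
    tree = nx.Graph()
    for comp in chosen:
        tree.update(_tree_for_component(g, comp, present, node_weighted))
    included = present & set(tree.nodes)
    unreachable = term_all - included
    if induce_edges:
        tree = nx.Graph(g.subgraph(tree.nodes))
    result = SteinerResult(
        subnetwork=Interactome(graph=tree),
        terminals_included=frozenset(included),
        connectors=frozenset(set(tree.nodes) - included),
        unreachable_terminals=frozenset(unreachable),
        is_tree=not induce_edges and not forest,
    )
    if result.is_tree:
        result.validate()
    return result


def brute_force_steiner(net: Interactome, terminals: SeedList) -> SteinerResult:
    """Exact minimum-edge Steiner tree by exhaustive connector enumeration.

    Only feasible on tiny graphs (<= 16 nodes); used as a test oracle.  With
    unit edge weights the minimum tree spanning the terminals has
    ``|terminals| + c* - 1`` edges where ``c*`` is the minimum number of
    connectors, so we search connector subsets in increasing size and
    lexicographic order.
    """
    g = net.graph
    if g.number_of_nodes() > 16:
        raise ValueError("instance too large for brute force; "
                         "use approximate_steiner_tree")
    term_all = set(terminals.genes)
    present = term_all & set(g.nodes)
    comps = _pick_component(g, present)
    if not comps:
        raise ValueError("nothing to connect: fewer than 2 reachable terminals")
    comp = comps[0]
    terms = sorted(comp & present)
    others = sorted(comp - set(terms))
    for size in range(len(others) + 1):
        for extra in itertools.combinations(others, size):
            nodes = set(terms) | set(extra)
            sub = g.subgraph(nodes)
            comp0 = nx.node_connected_component(sub, terms[0])
            if not set(terms) <= comp0:
                continue
            if not set(extra) <= comp0:
                # an unused connector: the same connection exists at a
                # smaller size, so it was (or will be) found without it
                continue
            mst = _kruskal(sorted(comp0),
                           [(1, *sorted((u, v)))
                            for u, v in sub.subgraph(comp0).edges])
            tree = nx.Graph()
            tree.add_nodes_from(comp0)
            tree.add_edges_from((u, v) for _, u, v in mst)
            result = SteinerResult(
                subnetwork=Interactome(graph=tree),
                terminals_included=frozenset(terms),
                connectors=frozenset(extra),
                unreachable_terminals=frozenset(term_all - set(terms)),
            )
            result.validate()
            return result
    raise RuntimeError("unreachable: terminals share a component")


def extract_connectors(result: SteinerResult, seeds: SeedList) -> set[str]:
    """Tree nodes that are not seeds — the newly introduced candidate genes."""
    return set(result.subnetwork.nodes) - set(seeds.genes)


def key_node_neighborhood(
    net: Interactome, focus: set[str], seeds: SeedList
) -> NeighborhoodReport:
    """Direct-interactor neighborhood of a focus gene set.

    ``seed_fraction`` is the fraction of non-focus neighbors that are seed
    genes; a focus with no neighbors yields 0.0 with a warning.
    """
    if not focus:
        raise ValueError("focus set is empty")
    missing = set(focus) - net.nodes
    if missing:
        raise ValueError(f"focus genes absent from network: {sorted(missing)}")
    neighbors: set[str] = set()
    for f in focus:
        neighbors |= set(net.graph.neighbors(f))
    hood_nodes = set(focus) | neighbors
    non_focus = neighbors - set(focus)
    if not non_focus:
        log.warning("focus genes have no non-focus neighbors; fraction set to 0")
        frac = 0.0
    else:
        frac = len(non_focus & set(seeds.genes)) / len(non_focus)
    return NeighborhoodReport(
        focus_genes=frozenset(focus),
        neighborhood=net.subgraph(hood_nodes),
        seed_fraction=frac,
    )


def export_subnetwork(result: SteinerResult, seeds: SeedList,
                      prefix: str | Path) -> list[Path]:
    """Write the subnetwork as SIF + TSV + GraphML with seed/connector roles,
    and the connector list as a single-column TSV."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    g = nx.Graph(result.subnetwork.graph)
    role = {n: ("seed" if n in result.terminals_included else "connector")
            for n in g.nodes}
    nx.set_node_attributes(g, role, "role")
    paths = []
    p = prefix.with_suffix(".sif")
    with open(p, "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in g.edges):
            fh.write(f"{u}\tpp\t{v}\n")
    paths.append(p)
    p = prefix.with_suffix(".tsv")
    with open(p, "w") as fh:
        fh.write("node_a\tnode_b\trole_a\trole_b\n")
        for u, v in sorted(tuple(sorted(e)) for e in g.edges):
            fh.write(f"{u}\t{v}\t{role[u]}\t{role[v]}\n")
    paths.append(p)
    p = prefix.with_suffix(".graphml")
    nx.write_graphml(g, p)
    paths.append(p)
    p = prefix.parent / (prefix.name + "_connectors.tsv")
    with open(p, "w") as fh:
        for c in sorted(result.connectors):
            fh.write(c + "\n")
    paths.append(p)
    return paths
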
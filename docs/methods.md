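# Methods

## Scope and data model

`seednet` analyses a curated disease gene list ("seeds") in three stages:
gene-set over-representation, pathway cross-talk network construction, and
Steiner-tree subnetwork extraction from a protein–protein interactome.
Gene identity is the uppercase symbol string throughout; no identifier
resolution is attempted, so inputs must already share a symbol namespace.
Gene sets travel as GMT, interactomes as two-column TSV or SIF edge lists,
networks leave as SIF/GraphML/TSV for Cytoscape.

The bundled fixtures transcribe the published artifacts of a
major-depressive-disorder gene curation: 73 KEGG pathways enriched in the
candidate genes, each restricted to its candidate-gene members; the
35 connector genes of the originally reported disease subnetwork; and a
131-gene seed list (the union of the pathway memberships plus the
individually named candidate genes). The full 255-gene curation exists
only as supplementary material that is not machine-readable here, so the
bundled seed list is a documented subset; the cross-talk analysis needs
only the pathway memberships and is unaffected.

## Enrichment

For universe size `N`, seed count `n`, set size `K` and overlap `k`, the
p-value is the hypergeometric upper tail `P(X ≥ k)`, the one-sided Fisher
exact enrichment test. It is computed as an exact rational
(`math.comb` tail sum) and converted to float at the end, so values such
as `1e-18` carry no cancellation error; `scipy.stats.hypergeom` agrees to
1e-10 relative and serves as an independent cross-check in the tests,
alongside a draw-enumeration oracle that is exact. A two-sided variant
(sum of outcomes no more probable than observed) is available behind a
flag; one-sided is the enrichment convention and the default.

The background universe defaults to the union of all genes in the tested
collection and can be overridden. Published enrichment servers use their
own (unstated) universes, so printed p/FDR values from such services are
not expected to reproduce exactly; the fixtures therefore carry the
original p/FDR strings only as annotations, and nothing asserts them.

Benjamini–Hochberg is the plain step-up over all sets tested in one run:
`q_(i) = min_{j≥i} p_(j)·m/j` capped at 1, returned in input order, with a
clamp `q ≥ p` guarding against float rounding (the inequality is exact
mathematics). Survivor filters (`k ≥ 5` seed members, `FDR < 0.05`) match
common practice for this analysis type. Note an interaction worth knowing:
with pathway sizes near the minimum (5–8 genes) and a partial seed
planting, a genuinely enriched set can carry `k < 5` and be filtered;
rank-based diagnostics therefore use `keep_all=True`, which returns every
tested set FDR-annotated and rank-sorted. An optional subset-pruning flag
(drop a survivor whose seed members are contained in a better-ranked
survivor) stands in for semantic redundancy removal of GO terms; it is off
by default and deliberately crude — no ontology structure is consulted.

## Cross-talk network

Pathways are compared on their seed-restricted memberships, not full
pathway rosters: the question is how the disease genes distribute across
functions, not how KEGG overlaps with itself. Two pathways connect when
they share `min_shared ≥ 3` seed genes; Jaccard, Overlap and their mean
score the edge. The mean is bracketed by its parts
(`jaccard ≤ score ≤ overlap`), which the tests assert as a property. No
score threshold applies by default; `score_cutoff` exists for explicit
pruning.

### Cross-talk network density

From the bundled 73 memberships the ≥3-shared-genes rule yields 72 nodes
and 877 edges. The originally published figure for this construction
reports 68 nodes and 325 edges. These cannot be reconciled from the
published tables: an exhaustive search over candidate pruning rules —
higher `min_shared` (4 gives exactly 68 nodes but 548 edges), cutoffs on
jaccard/overlap/mean score, top-N-by-score, and exclusion of promiscuous
genes — found no one-parameter rule matching both counts, and only the
two-parameter combination `min_shared ≥ 4` with mean score ≈ 0.388 matches
exactly. Fitting two free parameters to two printed integers has no
independent support, so the package implements the stated rule and reports
its honest counts; the acceptance suite records the mismatch with an
audit dump rather than adopting a reverse-engineered cutoff. Users who
want a sparser display network can set `min_shared=4` and `score_cutoff`
explicitly.

## Interactome and Steiner extraction

Interactomes are cleaned on ingest (uppercase symbols; self-loops and
duplicate pairs in either orientation dropped and counted) and merged by
edge-set union; cleaning is idempotent and merging commutative, asserted
as properties. Edges are unweighted: confidence scores, if present in the
input, are ignored by the algorithms.

The subnetwork extraction uses the classic shortest-path 2-approximation
of the Steiner minimal tree on unit edge weights: BFS metric closure over
the terminals, minimum spanning tree of the closure (Kruskal), expansion
of closure edges into concrete shortest paths, a second spanning-tree pass
over the expanded subgraph, then iterative pruning of non-terminal leaves.
Minimising edges of an unweighted tree is the tractable proxy for
"fewest interlinking nodes"; a node-weighted variant (entering a
non-terminal costs 1, a terminal 0) is available via `node_weighted=True`.
Every tie — BFS predecessor, MST edge order, component choice — breaks
lexicographically on node names, so identical inputs give byte-identical
exports. The tree spans every terminal of the connected component holding
the most terminals; terminals missing from the graph or stranded
elsewhere are reported as unreachable, never fatal (real curations
routinely contain genes absent from any interactome). `forest=True`
builds one tree per component with ≥ 2 terminals; `induce_edges=True`
re-adds all interactome edges among tree nodes afterwards, which explains
how a reported subnetwork can carry more edges than a tree (415 edges
over 203 nodes in the original full-scale analysis, against the 202 a
tree would have) — the result is then flagged as not-a-tree.

`brute_force_steiner` enumerates connector subsets in increasing size
(lexicographic within a size) on instances of ≤ 16 nodes and is the exact
oracle: the acceptance suite checks the heuristic stays within the 2×
bound on 100 random instances and is exactly optimal on trees, where the
connecting structure is unique. The full-scale published subnetwork
(203 nodes, 415 edges, 35 connectors, a 54/69 seed fraction around six
hub genes) depends on an unreleased merged six-database interactome and is
out of reach by construction; planted synthetic replays cover the same
machinery instead (exact connector recovery, tree identity, a planted
54-of-69 hub neighborhood).

## Synthetic studies

The generator emulates the shape of the real inputs at a configurable,
desk-sized scale. Defaults: a connected Barabási–Albert interactome with
2,000 genes and 3 attachment edges (heavy-tailed degrees standing in for a
full-scale interactome of ~16k proteins / ~228k interactions); 50
annotation sets of 5–40 genes; 5 designated enriched pathways; a 150-gene
seed list containing 60% of each enriched pathway's members plus uniform
background. One `rng_seed` drives three deterministic substreams
(interactome / annotations / seeds), so regenerating one stage never
perturbs another and all emitted files are byte-identical per seed.
Membership is sampled independently of graph topology except under
`connector_planting`, which attaches fresh terminal leaves to a designated
hub so the optimal connector is known exactly. What the generator does not
emulate: literature-curation bias, correlated pathway membership, KEGG's
actual topology, or false-positive interactome edges — passing recovery
tests demonstrates the statistics and algorithms, not robustness to those
artifacts.

Calibration facts the acceptance suite recomputes: with the defaults, all
5 planted pathways rank in the FDR top 10 (over all tested sets) in
≥ 95 of 100 replicates; with no planting, the mean fraction of raw
p < 0.05 across 100 replicates stays within [0.02, 0.09] — below-nominal
on average because the hypergeometric is discrete at these margins.

## Pipeline

`run_pipeline` executes load → enrichment → cross-talk → subnetwork with
one structured log line per stage and writes a JSON manifest carrying each
output's SHA-256 checksum plus the headline counts; determinism is
asserted by re-running and comparing checksums. In fixtures mode the
bundled pathway memberships are already the enriched seed-restricted sets,
so the enrichment stage is skipped and cross-talk runs directly on them.
Any stage failure aborts with the stage name and leaves a `.failed`
marker beside the partial outputs.

## Known limitations

- Symbol-string identity: synonyms or outdated symbols silently fail to
  match across inputs.
- The bundled seed list is a subset of the original 255-gene curation
  (see above); analyses needing the full list must supply it.
- The Steiner heuristic guarantees a 2× edge bound, not optimality, and
  the "least interlinking nodes" objective is served by proxy unless
  `node_weighted` is set.
- BH controls FDR under independence/PRDS; enrichment tests on
  overlapping gene sets are positively dependent in practice, which is
  the standard, if imperfect, setting for this analysis.
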
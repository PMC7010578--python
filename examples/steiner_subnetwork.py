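"""Extract a seed-gene subnetwork with the approximate Steiner tree.

Plants a hub gene with six leaf terminals inside a 500-gene scale-free
interactome; the minimal structure connecting the terminals must pass
through the hub, so the extraction should report exactly that hub as the
single connector ("novel") gene.
"""

from seednet import SeedList, SyntheticConfig, approximate_steiner_tree
from seednet.synthetic import generate_interactome

cfg = SyntheticConfig(rng_seed=42, n_genes=500,
                      connector_planting={"hub": "HUB", "n_leaves": 6})
net, truth = generate_interactome(cfg)
terminals = SeedList(label="planted", genes=frozenset(truth.planted_terminals))

result = approximate_steiner_tree(net, terminals)
print(f"interactome: {net.n_nodes} genes, {net.n_edges} interactions")
print(f"tree: {result.n_nodes} nodes, {result.n_edges} edges "
      f"(tree identity: edges = nodes - 1)")
print(f"terminals connected: {sorted(result.terminals_included)}")
print(f"connector genes introduced: {sorted(result.connectors)} "
      f"(planted: {sorted(truth.planted_connectors)})")
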
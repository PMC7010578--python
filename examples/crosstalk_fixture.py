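"""Build the pathway cross-talk network from the bundled disease fixtures.

Loads the 73 enriched pathways (each restricted to its seed-gene members),
connects every pair sharing at least three seed genes, and prints the
strongest cross-talk edges.  The score is the mean of the Jaccard and
Overlap coefficients of the two membership lists: 1.0 means one pathway's
seed genes are a subset of the other's.
"""

from seednet import build_crosstalk_network, load_mdd_fixtures

seeds, pathways, _ = load_mdd_fixtures()
net = build_crosstalk_network(pathways, min_shared=3)

print(f"{len(pathways)} pathways, {len(seeds)} seed genes")
print(f"cross-talk network: {net.n_nodes} nodes, {net.n_edges} edges")
print("\nstrongest cross-talk (top 5):")
for e in net.edges[:5]:
    print(f"  {e.set_a!r} -- {e.set_b!r}  "
          f"shared={len(e.shared)} jaccard={e.jaccard:.3f} "
          f"overlap={e.overlap:.3f} score={e.score:.3f}")
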
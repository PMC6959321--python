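"""Detect dense clusters (candidate guilds) with MCODE.

Shows the three MCODE stages on a toy graph, then ranks clusters on a
simulated co-occurrence network. Scores are density x size, so large tight
clusters rank first.
"""

import networkx as nx

import guildnet as gn
from guildnet.mcode import McodeParams, compute_weights

# toy: two cliques of different size
toy = nx.disjoint_union(nx.complete_graph(6), nx.complete_graph(4))
weights = compute_weights(toy)
print("vertex weights (core-density):",
      sorted(set(round(w, 2) for w in weights.values())))
for c in gn.run_mcode(toy):
    print(f"  rank {c.rank}: {len(c.members)} nodes, "
          f"{c.n_edges} edges, score {c.score:.3f}")

# simulated network: the planted guild structure surfaces as the top cluster
spec = gn.SimulationSpec(n_samples=200, seed=1)
table, truth = gn.simulate_counts(spec)
net = gn.build_network(gn.filter_low_abundance(table))
clusters = gn.run_mcode(net, McodeParams(vwp=0.2, haircut=True))
print(f"\nsimulated network: {net.number_of_nodes()} nodes, "
      f"{net.number_of_edges()} edges -> {len(clusters)} clusters")
for c in clusters[:3]:
    inside = len(c.members & (truth.block_members(0) | truth.block_members(1)))
    print(f"  rank {c.rank}: {len(c.members)} nodes "
          f"(all {inside} from planted blocks), score {c.score:.2f}")

print("\nBackground OTUs never enter a cluster: MCODE isolates the planted")
print("dense blocks, with the antagonist guards attached to the top cluster.")
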
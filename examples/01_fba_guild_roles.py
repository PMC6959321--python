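"""Classify guard and civilian nodes in the packaged oral FBA guild.

Loads the transcribed reference data for the strongest cluster of a healthy
oral microbiome co-occurrence network — 55 OTUs split into an
Actinobacteria-dominant sub-guild (ASG) and a Firmicutes-dominant sub-guild
(FBSG), plus the 39 negative correlations running between them — and
re-derives each node's role from the edge signs alone.
"""

import networkx as nx

import guildnet as gn

membership = gn.load_fba_membership()
edges = gn.load_fba_negative_edges()

graph = nx.Graph()
graph.add_nodes_from(membership)
for e in edges:
    graph.add_edge(e.node_a, e.node_b, r=e.r, sign="negative")

groups = {}
for node, rec in membership.items():
    groups.setdefault(rec.sub_guild, set()).add(node)
partition = gn.SubGuildPartition(
    groups=[frozenset(groups["FBSG"]), frozenset(groups["ASG"])],
    frustrated_edges=[], names=["FBSG", "ASG"],
)

roles = gn.classify_roles(graph, partition)
for name in ("ASG", "FBSG"):
    guards = sorted(r.node for r in roles
                    if r.sub_guild == name and r.role == "guard")
    civilians = [r for r in roles if r.sub_guild == name and r.role == "civilian"]
    print(f"{name}: {len(guards)} guards, {len(civilians)} civilians")
    print(f"  guards: {', '.join(guards[:5])}, ...")

pmap = gn.default_phylum_map()
comp = gn.phylum_composition(membership.keys(), pmap)
print("guild composition:", {p: f"{c} ({pct}%)" for p, (c, pct) in comp.items()})

print("\nEvery node with a cross-sub-guild negative edge is a guard; nodes")
print("holding only positive links are civilians. The guard counts (14 vs 16)")
print("and the phylum mix identify the F+B alliance facing Actinobacteria.")
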
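"""End-to-end recovery of planted guild structure from simulated counts.

Runs the full pipeline (simulate -> filter -> network -> MCODE -> guild
report) in power mode (200 samples) and scores the result against the
recorded ground truth.
"""

import guildnet as gn

spec = gn.SimulationSpec(n_samples=200, seed=1)
table, truth = gn.simulate_counts(spec)
filtered = gn.filter_low_abundance(table)
net = gn.build_network(filtered)
clusters = gn.run_mcode(net)
report = gn.guild_report(net, clusters[0].members, gn.default_phylum_map())

print(f"top cluster: {len(clusters[0].members)} nodes, "
      f"score {clusters[0].score:.2f}")
print(f"sub-guilds found: {[len(g) for g in report.partition.groups]}, "
      f"balanced={report.partition.balanced}")
print("role counts:", report.role_counts())

metrics = gn.evaluate_recovery(truth, report, clusters)
for k, v in metrics.to_dict().items():
    print(f"  {k}: {v:.3f}")

print("\nGuard recall/precision of 1.0 means every planted guard was")
print("re-identified from edge signs alone; ARI 1.0 means the sub-guild")
print("partition matches the planted blocks exactly on the clustered nodes.")
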
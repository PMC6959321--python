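import networkx as nx
import numpy as np
import pytest

import guildnet as gn


@pytest.fixture(scope="session")
def membership():
    return gn.load_fba_membership()


@pytest.fixture(scope="session")
def negative_edges():
    return gn.load_fba_negative_edges()


@pytest.fixture(scope="session")
def phylum_map():
    return gn.default_phylum_map()


@pytest.fixture(scope="session")
def fba_graph(membership, negative_edges):
    """Signed graph of the transcribed guild: 55 nodes, 39 negative edges."""
    g = nx.Graph()
    g.add_nodes_from(membership)
    for e in negative_edges:
        g.add_edge(e.node_a, e.node_b, r=e.r, p=e.p_value, sign="negative")
    return g


@pytest.fixture(scope="session")
def fba_partition(membership):
    asg = frozenset(k for k, v in membership.items() if v.sub_guild == "ASG")
    fbsg = frozenset(k for k, v in membership.items() if v.sub_guild == "FBSG")
    return gn.SubGuildPartition(groups=[fbsg, asg], frustrated_edges=[],
                                names=["FBSG", "ASG"])


@pytest.fixture(scope="session")
def small_spec():
    """Fast simulation conditions for repeated-replicate tests."""
    return gn.SimulationSpec(
        n_samples=29, block_sizes=(6, 8), guard_fraction=(0.5, 0.5),
        n_background=10, n_rare=5, seed=0,
    )


@pytest.fixture(scope="session")
def power_run():
    """One end-to-end pipeline run in power mode (n = 200), shared by tests."""
    spec = gn.SimulationSpec(n_samples=200, seed=1)
    table, truth = gn.simulate_counts(spec)
    filtered = gn.filter_low_abundance(table)
    net = gn.build_network(filtered)
    clusters = gn.run_mcode(net)
    report = gn.guild_report(net, clusters[0].members, gn.default_phylum_map())
    metrics = gn.evaluate_recovery(truth, report, clusters)
    return dict(spec=spec, table=table, truth=truth, filtered=filtered,
                net=net, clusters=clusters, report=report, metrics=metrics)


def spearman_oracle(x, y):
    """Brute-force Spearman: explicit mid-ranking then the Pearson formula.

    Independent of scipy's ranking/correlation code paths on purpose.
    """
    def midranks(v):
        v = list(v)
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    n = len(rx)
    mx = sum(rx) / n
    my = sum(ry) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    vx = sum((a - mx) ** 2 for a in rx)
    vy = sum((b - my) ** 2 for b in ry)
    return cov / np.sqrt(vx * vy)
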
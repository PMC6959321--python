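"""Signed Spearman co-occurrence network construction and topology statistics.

The pipeline here mirrors standard microbiome correlation-network practice:
drop OTUs whose total reads across all samples fall below a minimum (the
singleton-removal convention, default 30), compute all pairwise Spearman rank
correlations R with two-sided p-values from the t approximation, and keep an
edge wherever |R| >= r_min and p <= p_max (inclusive, defaults 0.6 / 0.05).
Edges carry their correlation sign; the positive-to-negative link (P/N) ratio
summarises the balance between cooperative and competitive associations.

No multiple-testing correction is applied by default (edge selection on raw
p-values is deliberate, matching the thresholding convention this pipeline
reproduces); Benjamini-Hochberg is available behind ``adjust="bh"``.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Literal

import networkx as nx
import numpy as np
from scipy import stats

from .otu_io import OtuTable

__all__ = [
    "filter_low_abundance",
    "spearman_with_p",
    "spearman_matrix",
    "build_network",
    "local_clustering",
    "pn_ratio",
    "format_ratio",
    "NetworkStats",
    "network_stats",
    "write_edge_list",
    "write_graphml",
]

logger = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"


def filter_low_abundance(table: OtuTable, min_total: int = 30) -> OtuTable:
    """Retain OTUs whose total reads across all samples are >= ``min_total``.

    The default of 30 removes roughly one-read-per-sample OTUs in a 29-sample
    study; ``min_total=0`` is the identity. An empty result warns rather than
    raising, so parameter sweeps fail loudly downstream instead of here.
    """
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    totals = table.row_totals()
    keep = [o for o, t in zip(table.otu_ids, totals) if t >= min_total]
    if not keep:
        warnings.warn("all OTUs removed by abundance filter", stacklevel=2)
    out = table.select_otus(keep)
    logger.info("abundance filter: %d -> %d OTUs (min_total=%d)",
                table.n_otus, out.n_otus, min_total)
    return out


def spearman_with_p(
    x: np.ndarray,
    y: np.ndarray,
    p_method: Literal["t", "exact"] = "t",
) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Mid-ranks handle ties; the p-value comes from the t approximation
    t = r*sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom, with |r| = 1 mapped
    to p = 0. ``p_method="exact"`` enumerates the permutation null instead
    (n <= 8 only; factorial cost).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: Spearman correlation undefined")
    if p_method == "exact":
        return _spearman_exact(x, y)
    r, p = stats.spearmanr(x, y)
    r = float(r)
    if abs(r) >= 1.0 - 1e-15:
        return (math.copysign(1.0, r), 0.0)
    return r, float(p)


def _spearman_exact(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    # Exact two-sided permutation p: share of pairings with |r| >= |r_obs|.
    n = x.size
    if n > 8:
        raise ValueError("exact permutation p-value limited to n <= 8")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    r_obs = float(np.corrcoef(rx, ry)[0, 1])
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = float(np.corrcoef(rx, ry[list(perm)])[0, 1])
        if abs(r) >= abs(r_obs) - 1e-12:
            count += 1
        total += 1
    return r_obs, count / total


def spearman_matrix(
    table: OtuTable,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """All-pairs Spearman R and two-sided p over the rows of an OTU table.

    Constant (e.g. all-zero) OTU vectors have no defined rank correlation;
    they are excluded with a logged warning and absent from the returned id
    list.
    """
    counts = table.counts
    keep = [i for i in range(table.n_otus)
            if not np.all(counts[i] == counts[i, 0])]
    dropped = sorted(set(table.otu_ids) - {table.otu_ids[i] for i in keep})
    if dropped:
        logger.warning("skipping %d constant OTU vector(s): %s",
                       len(dropped), ", ".join(dropped[:5]) + ("..." if len(dropped) > 5 else ""))
    ids = [table.otu_ids[i] for i in keep]
    sub = counts[keep, :]
    if len(keep) < 2:
        raise ValueError("fewer than 2 non-constant OTUs: no pairs to test")
    res = stats.spearmanr(sub.T)
    r = np.atleast_2d(np.asarray(res.statistic, dtype=float))
    p = np.atleast_2d(np.asarray(res.pvalue, dtype=float))
    if r.shape == (1, 1):  # scipy collapses the 2-variable case to scalars
        r = np.array([[1.0, r[0, 0]], [r[0, 0], 1.0]])
        p = np.array([[0.0, p[0, 0]], [p[0, 0], 0.0]])
    # |r| = 1 has p = 0 under the t approximation.
    p[np.abs(r) >= 1.0 - 1e-15] = 0.0
    return r, p, ids


def build_network(
    table: OtuTable,
    r_min: float = 0.6,
    p_max: float = 0.05,
    drop_isolated: bool = True,
    adjust: Literal[None, "bh"] = None,
) -> nx.Graph:
    """Build the signed co-occurrence network from a filtered OTU table.

    Every OTU pair is tested; pairs with |R| >= r_min and p <= p_max (both
    inclusive) become edges with attributes ``r``, ``p`` and ``sign``. Nodes
    left without any edge are dropped by default — thresholding typically
    strands a few filtered OTUs outside the network. ``adjust="bh"`` replaces
    raw p-values by Benjamini-Hochberg adjusted ones before thresholding.
    """
    if table.n_otus < 2:
        raise ValueError("need at least 2 OTUs to build a network")
    r, p, ids = spearman_matrix(table)
    m = len(ids)
    iu = np.triu_indices(m, k=1)
    pvals = p[iu]
    if adjust == "bh":
        pvals = stats.false_discovery_control(pvals, method="bh")
    rvals = r[iu]
    ok = (np.abs(rvals) >= r_min) & (pvals <= p_max)
    g = nx.Graph()
    g.add_nodes_from(ids)
    for i, j, rv, pv in zip(iu[0][ok], iu[1][ok], rvals[ok], pvals[ok]):
        g.add_edge(ids[i], ids[j], r=float(rv), p=float(pv),
                   sign=POSITIVE if rv > 0 else NEGATIVE)
    if drop_isolated:
        g.remove_nodes_from(list(nx.isolates(g)))
    g.graph.update(r_min=r_min, p_max=p_max, adjust=adjust or "none")
    logger.info("network: %d nodes, %d edges", g.number_of_nodes(), g.number_of_edges())
    return g


def local_clustering(net: nx.Graph, node) -> float:
    """Local clustering coefficient C_i = 2n / (k_i (k_i - 1)).

    k_i is the degree of ``node`` and n the number of edges among its
    neighbours (signs ignored); vertices with fewer than two neighbours have
    C_i = 0 by convention.
    """
    if node not in net:
        raise KeyError(f"node {node!r} not in network")
    return float(nx.clustering(net, node))


def pn_ratio(n_positive: int, n_negative: int) -> float:
    """Positive-to-negative link ratio.

    Returns ``inf`` when there are positive links but no negative ones and
    ``nan`` for the degenerate 0/0 case (rendered "Inf" / "NA" by
    :func:`format_ratio`).
    """
    if n_positive < 0 or n_negative < 0:
        raise ValueError("link counts must be non-negative")
    if n_negative == 0:
        return math.inf if n_positive > 0 else math.nan
    return n_positive / n_negative


def format_ratio(value: float, decimals: int = 3) -> str:
    if math.isnan(value):
        return "NA"
    if math.isinf(value):
        return "Inf"
    return f"{value:.{decimals}f}"


@dataclass
class NetworkStats:
    """Whole-network topology summary of a signed co-occurrence graph."""

    n_nodes: int
    n_edges: int
    n_positive: int
    n_negative: int
    pn_ratio: float
    average_degree: float
    average_local_clustering: float
    diameter: int
    average_path_length: float
    n_components: int
    density: float
    modularity: float
    n_communities: int
    community_method: str = "greedy_modularity"

    def to_dict(self) -> dict:
        return asdict(self)


def network_stats(
    net: nx.Graph,
    community_method: Literal["greedy_modularity"] = "greedy_modularity",
) -> NetworkStats:
    """Compute the summary statistics of a signed network.

    Path-based metrics (diameter, average shortest path length) are computed
    on the largest connected component when the graph is disconnected; the
    component count is reported alongside so the convention is visible.
    Community structure is detected on the unsigned topology.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    n_nodes = net.number_of_nodes()
    n_edges = net.number_of_edges()
    signs = [d.get("sign", POSITIVE) for _, _, d in net.edges(data=True)]
    n_pos = sum(1 for s in signs if s == POSITIVE)
    n_neg = n_edges - n_pos
    components = list(nx.connected_components(net))
    giant = net.subgraph(max(components, key=len))
    if giant.number_of_nodes() > 1:
        diameter = nx.diameter(giant)
        apl = nx.average_shortest_path_length(giant)
    else:
        diameter, apl = 0, 0.0
    if community_method != "greedy_modularity":
        raise ValueError(f"unknown community method {community_method!r}")
    if n_edges > 0:
        communities = list(nx.community.greedy_modularity_communities(net))
        modularity = nx.community.modularity(net, communities)
    else:
        communities, modularity = [set(net.nodes)], 0.0
    return NetworkStats(
        n_nodes=n_nodes,
        n_edges=n_edges,
        n_positive=n_pos,
        n_negative=n_neg,
        pn_ratio=pn_ratio(n_pos, n_neg),
        average_degree=2 * n_edges / n_nodes,
        average_local_clustering=float(np.mean(list(nx.clustering(net).values()))),
        diameter=diameter,
        average_path_length=apl,
        n_components=len(components),
        density=2 * n_edges / (n_nodes * (n_nodes - 1)) if n_nodes > 1 else 0.0,
        modularity=modularity,
        n_communities=len(communities),
        community_method=community_method,
    )


def write_edge_list(net: nx.Graph, path: str | Path, digits: int = 6) -> None:
    """Write edges as TSV columns (source, target, r, p_value, sign)."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\tr\tp_value\tsign\n")
        for u, v, d in sorted(net.edges(data=True)):
            fh.write(f"{u}\t{v}\t{d['r']:.{digits}g}\t{d['p']:.{digits}g}\t{d['sign']}\n")


def write_graphml(net: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(net, Path(path))
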
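"""MCODE (Molecular Complex Detection) graph clustering, implemented fresh.

MCODE finds locally dense regions of a graph in three stages:

1. *Vertex weighting* — every vertex is scored by the density of its
   neighbourhood. The canonical weight is the core-density: take the closed
   neighbourhood N[v], find its highest k-core, and set
   ``weight = k_max * density(highest k-core)``. A simpler variant uses the
   local clustering coefficient C_i directly; both modes are exposed because
   abridged descriptions of the algorithm often state the C_i form.
2. *Cluster prediction* — seeds are taken in decreasing weight order; from
   each unassigned seed a breadth-first expansion adds unassigned neighbours
   whose weight is at least ``(1 - vwp) * weight(seed)`` (inclusive), where
   vwp is the vertex weight percentage. Each vertex joins at most one cluster.
3. *Post-processing* — candidate clusters lacking a 2-core (more generally a
   ``kcore_filter``-core) are discarded; *haircut* iteratively strips members
   with a single intra-cluster connection; *fluff* (off by default) adds
   boundary vertices whose closed-neighbourhood density exceeds a cutoff.

Clusters are scored by ``density * size`` and ranked by descending score.
Edge signs are ignored throughout: MCODE clusters the unsigned topology, and
sign structure is analysed downstream by :mod:`guildnet.guilds`. All
tie-breaks (equal weights, equal scores) fall back to lexicographic node
order, so runs are fully deterministic.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping

import networkx as nx

__all__ = ["McodeParams", "Cluster", "k_core", "vertex_weight",
           "compute_weights", "find_clusters", "post_process",
           "score_cluster", "run_mcode", "write_clusters"]


@dataclass(frozen=True)
class McodeParams:
    """Tunable MCODE parameters (defaults follow the published algorithm)."""

    vwp: float = 0.2
    haircut: bool = True
    fluff: bool = False
    fluff_density_cutoff: float = 0.1
    kcore_filter: int = 2
    max_depth: int = 100
    weight_mode: Literal["core_density", "simple_clustering"] = "core_density"

    def __post_init__(self) -> None:
        if not 0.0 <= self.vwp <= 1.0:
            raise ValueError("vwp must lie in [0, 1]")
        if self.kcore_filter < 2:
            raise ValueError("kcore_filter must be >= 2")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")


@dataclass
class Cluster:
    """A detected cluster: member set, edge count, density score and rank."""

    members: frozenset
    n_edges: int
    score: float
    rank: int
    seed: object

    def __len__(self) -> int:
        return len(self.members)


def _density(n_nodes: int, n_edges: int) -> float:
    if n_nodes < 2:
        return 0.0
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


def k_core(graph: nx.Graph, k: int) -> nx.Graph:
    """Maximal subgraph in which every vertex has degree >= k (may be empty)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    core_num = nx.core_number(graph)
    nodes = [n for n, c in core_num.items() if c >= k]
    return graph.subgraph(nodes).copy()


def vertex_weight(
    graph: nx.Graph,
    node,
    mode: Literal["core_density", "simple_clustering"] = "core_density",
) -> float:
    """Local-density weight of a vertex.

    ``core_density``: k_max times the density of the highest k-core of the
    closed neighbourhood (vertex plus neighbours). ``simple_clustering``: the
    clustering coefficient C_i = 2n / (k_i (k_i - 1)). Both are 0 whenever the
    neighbourhood holds no edges beyond the star around the vertex.
    """
    if node not in graph:
        raise KeyError(f"node {node!r} not in graph")
    if mode == "simple_clustering":
        return float(nx.clustering(graph, node))
    if mode != "core_density":
        raise ValueError(f"unknown weight mode {mode!r}")
    closed = list(graph.neighbors(node)) + [node]
    sub = graph.subgraph(closed)
    core_num = nx.core_number(sub)
    k_max = max(core_num.values())
    if k_max < 2:
        # a pendant/star neighbourhood carries no cohesive core
        return 0.0
    core_nodes = [n for n, c in core_num.items() if c >= k_max]
    core_sub = sub.subgraph(core_nodes)
    return k_max * _density(core_sub.number_of_nodes(), core_sub.number_of_edges())


def compute_weights(graph: nx.Graph, mode: str = "core_density") -> dict:
    return {n: vertex_weight(graph, n, mode) for n in graph.nodes}


def _sorted_nodes(nodes: Iterable, weights: Mapping) -> list:
    # decreasing weight, lexicographic label for determinism
    return sorted(nodes, key=lambda n: (-weights[n], str(n)))


def find_clusters(
    graph: nx.Graph,
    weights: Mapping,
    params: McodeParams = McodeParams(),
) -> list[frozenset]:
    """Seeded breadth-first cluster prediction (unscored candidates).

    Seeds are processed in decreasing weight order; a neighbour joins the
    expansion iff it is not yet in any cluster and its weight is >=
    ``(1 - vwp) * weight(seed)``. Depth is counted in BFS layers from the
    seed. Zero-weight vertices never seed (an edgeless graph yields nothing).
    """
    assigned: set = set()
    clusters: list[frozenset] = []
    threshold_base = 1.0 - params.vwp
    for seed in _sorted_nodes(graph.nodes, weights):
        if seed in assigned or weights[seed] <= 0.0:
            continue
        cutoff = threshold_base * weights[seed]
        members = {seed}
        frontier = deque([(seed, 0)])
        while frontier:
            node, depth = frontier.popleft()
            if depth >= params.max_depth:
                continue
            for nb in sorted(graph.neighbors(node), key=str):
                if nb in members or nb in assigned:
                    continue
                if weights[nb] >= cutoff:
                    members.add(nb)
                    frontier.append((nb, depth + 1))
        assigned |= members
        clusters.append(frozenset(members))
    return clusters


def _haircut(sub: nx.Graph) -> set:
    """Iteratively remove vertices with a single intra-cluster connection."""
    keep = set(sub.nodes)
    changed = True
    while changed:
        changed = False
        view = sub.subgraph(keep)
        trim = [n for n in keep if view.degree(n) < 2]
        if trim:
            keep -= set(trim)
            changed = True
    return keep


def post_process(
    graph: nx.Graph,
    clusters: Iterable[frozenset],
    params: McodeParams = McodeParams(),
) -> list[frozenset]:
    """Filter candidate clusters: k-core test, optional haircut and fluff."""
    out: list[frozenset] = []
    for members in clusters:
        sub = graph.subgraph(members)
        core_num = nx.core_number(sub)
        if not core_num or max(core_num.values()) < params.kcore_filter:
            continue
        kept = set(members)
        if params.haircut:
            kept = _haircut(sub)
            if not kept:
                continue
        if params.fluff:
            boundary = set()
            for n in kept:
                for nb in graph.neighbors(n):
                    if nb in kept or nb in boundary:
                        continue
                    closed = list(graph.neighbors(nb)) + [nb]
                    nb_sub = graph.subgraph(closed)
                    if _density(nb_sub.number_of_nodes(),
                                nb_sub.number_of_edges()) > params.fluff_density_cutoff:
                        boundary.add(nb)
            kept |= boundary
        out.append(frozenset(kept))
    return out


def score_cluster(graph: nx.Graph, members: Iterable) -> float:
    """Cluster score = density x size (a singleton scores 0)."""
    members = list(members)
    if not members:
        raise ValueError("empty cluster")
    sub = graph.subgraph(members)
    return _density(len(members), sub.number_of_edges()) * len(members)


def run_mcode(graph: nx.Graph, params: McodeParams = McodeParams()) -> list[Cluster]:
    """Full MCODE pass: weight, predict, post-process, score and rank.

    Deterministic: ranking is by descending score, then descending size, then
    the lexicographically smallest member label.
    """
    if graph.number_of_nodes() == 0:
        return []
    weights = compute_weights(graph, params.weight_mode)
    candidates = find_clusters(graph, weights, params)
    final = post_process(graph, candidates, params)
    scored = []
    for members in final:
        sub = graph.subgraph(members)
        seed = _sorted_nodes(members, weights)[0]
        scored.append((score_cluster(graph, members), len(members),
                       min(map(str, members)), sub.number_of_edges(), members, seed))
    scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
    return [
        Cluster(members=members, n_edges=n_edges, score=score, rank=i + 1, seed=seed)
        for i, (score, _, _, n_edges, members, seed) in enumerate(scored)
    ]


def write_clusters(clusters: Iterable[Cluster], path: str | Path) -> None:
    """Write cluster membership as TSV (cluster_id, node, score, rank)."""
    with open(path, "w") as fh:
        fh.write("cluster_id\tnode\tscore\trank\n")
        for c in clusters:
            for node in sorted(map(str, c.members)):
                fh.write(f"{c.rank}\t{node}\t{c.score:.6g}\t{c.rank}\n")
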
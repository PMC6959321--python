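"""Signed-structure analysis of a network cluster ("guild").

A guild — a dense cluster in the co-occurrence network — is dissected by the
sign pattern of its edges:

* *Sub-guilds* are the connected components of the positive-edge subgraph.
  In a structurally balanced cluster every within-group edge is positive and
  every between-group edge negative; negative edges landing inside a group
  are reported as frustrated. The number of groups is an emergent result,
  not fixed at two.
* *Guard* nodes hold at least one negative edge towards another sub-guild and
  none within their own; *civilian* nodes hold no negative edges at all;
  nodes with a within-group negative edge are flagged *anomalous*.
* Phylum composition and phylum-pair positive/negative counts (with P/N
  ratios) summarise which taxa carry the cooperative and competitive links.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .netbuild import NEGATIVE, POSITIVE, pn_ratio
from .otu_io import UNKNOWN_PHYLUM, parse_taxon_label, LabelParseError

__all__ = [
    "SubGuildPartition",
    "NodeRole",
    "PhylumPairSummary",
    "GuildReport",
    "partition_subguilds",
    "min_frustration_bipartition",
    "classify_roles",
    "phylum_composition",
    "phylum_pair_summary",
    "guild_report",
    "node_phylum",
    "MAJOR_PHYLA",
    "OTHERS",
]

MAJOR_PHYLA = ("Actinobacteria", "Firmicutes", "Bacteroidetes")
OTHERS = "Others"

GUARD = "guard"
CIVILIAN = "civilian"
ANOMALOUS = "anomalous"


@dataclass
class SubGuildPartition:
    """Disjoint node groups covering a cluster, ordered by descending size."""

    groups: list[frozenset]
    frustrated_edges: list[tuple]
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.names:
            self.names = [f"SG{i + 1}" for i in range(len(self.groups))]
        if len(self.names) != len(self.groups):
            raise ValueError("names and groups length mismatch")
        self._index = {n: i for i, grp in enumerate(self.groups) for n in grp}

    @property
    def balanced(self) -> bool:
        return not self.frustrated_edges

    def group_of(self, node) -> int:
        return self._index[node]

    def name_of(self, node) -> str:
        return self.names[self._index[node]]


@dataclass(frozen=True)
class NodeRole:
    node: object
    role: str       # guard | civilian | anomalous
    sub_guild: str  # group name


@dataclass(frozen=True)
class PhylumPairSummary:
    phylum_a: str
    phylum_b: str
    n_total: int
    n_positive: int
    n_negative: int
    pn_ratio: float


class _DSU:
    def __init__(self, nodes: Iterable) -> None:
        self.parent = {n: n for n in nodes}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _edge_sign(data: Mapping) -> str:
    sign = data.get("sign")
    if sign is None:
        sign = POSITIVE if data.get("r", 0.0) > 0 else NEGATIVE
    return sign


def partition_subguilds(cluster: nx.Graph) -> SubGuildPartition:
    """Partition a signed cluster subgraph by positive-edge connectivity.

    Union-find merges the endpoints of every positive edge; the resulting
    groups are separated only by negative edges when the cluster is balanced.
    Negative edges falling inside a group are recorded as frustrated (positive
    edges between groups cannot occur by construction). Groups come out in
    descending size order, ties broken by smallest member label.
    """
    dsu = _DSU(cluster.nodes)
    for u, v, d in cluster.edges(data=True):
        if _edge_sign(d) == POSITIVE:
            dsu.union(u, v)
    members: dict = {}
    for n in cluster.nodes:
        members.setdefault(dsu.find(n), set()).add(n)
    groups = sorted(members.values(), key=lambda g: (-len(g), min(map(str, g))))
    groups = [frozenset(g) for g in groups]
    index = {n: i for i, g in enumerate(groups) for n in g}
    frustrated = [
        (u, v)
        for u, v, d in cluster.edges(data=True)
        if _edge_sign(d) == NEGATIVE and index[u] == index[v]
    ]
    return SubGuildPartition(groups=groups, frustrated_edges=frustrated)


def min_frustration_bipartition(cluster: nx.Graph) -> tuple[frozenset, frozenset, int]:
    """Exhaustive frustration-minimising 2-partition (test oracle, n <= 20).

    Frustration of a bipartition counts positive edges crossing it plus
    negative edges inside a side. Ties resolve to the lexicographically
    smallest membership vector with the first node on side A.
    """
    nodes = sorted(cluster.nodes, key=str)
    n = len(nodes)
    if n > 20:
        raise ValueError("exhaustive bipartition limited to 20 nodes")
    edges = [(u, v, _edge_sign(d)) for u, v, d in cluster.edges(data=True)]
    best = None
    for bits in range(2 ** max(n - 1, 0)):
        side = {nodes[0]: 0}
        for i in range(1, n):
            side[nodes[i]] = (bits >> (i - 1)) & 1
        frus = sum(
            1
            for u, v, s in edges
            if (side[u] == side[v]) == (s == NEGATIVE)
        )
        key = (frus, bits)
        if best is None or key < best[0]:
            best = (key, side)
    side = best[1]
    a = frozenset(x for x in nodes if side[x] == 0)
    b = frozenset(x for x in nodes if side[x] == 1)
    return a, b, best[0][0]


def classify_roles(
    cluster: nx.Graph, partition: SubGuildPartition
) -> list[NodeRole]:
    """Assign guard / civilian / anomalous roles given a sub-guild partition.

    A node with any within-group negative edge is anomalous; otherwise it is a
    guard if it holds a negative edge to another group, else a civilian.
    """
    roles: list[NodeRole] = []
    for node in sorted(cluster.nodes, key=str):
        neg_within = neg_cross = 0
        for nb in cluster.neighbors(node):
            if _edge_sign(cluster.edges[node, nb]) == NEGATIVE:
                if partition.group_of(nb) == partition.group_of(node):
                    neg_within += 1
                else:
                    neg_cross += 1
        if neg_within:
            role = ANOMALOUS
        elif neg_cross:
            role = GUARD
        else:
            role = CIVILIAN
        roles.append(NodeRole(node=node, role=role, sub_guild=partition.name_of(node)))
    return roles


def round_half_up(value: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def node_phylum(node, phylum_map: Mapping[str, str]) -> str:
    """Grouped phylum of an OTU label: one of the majors, else "Others".

    Labels that fail to parse, names absent from the map and phyla outside
    the three majors all collapse into the "Others" group.
    """
    try:
        info = parse_taxon_label(str(node), phylum_map)
    except LabelParseError:
        return OTHERS
    if info.phylum in MAJOR_PHYLA:
        return info.phylum
    return OTHERS


def phylum_composition(
    members: Iterable,
    phylum_map: Mapping[str, str],
) -> dict[str, tuple[int, float]]:
    """Per-phylum member counts and percentages (1 decimal, half-up).

    Phyla outside the three majors (including unmapped/unparseable names)
    are grouped under "Others". Returns ``{phylum: (count, percent)}``;
    empty input yields an empty summary.
    """
    members = list(members)
    counts: dict[str, int] = {}
    for node in members:
        ph = node_phylum(node, phylum_map)
        counts[ph] = counts.get(ph, 0) + 1
    total = len(members)
    order = [p for p in (*MAJOR_PHYLA, OTHERS) if p in counts]
    order += sorted(set(counts) - set(order))
    return {
        p: (counts[p], round_half_up(100.0 * counts[p] / total, 1)) for p in order
    }


def phylum_pair_summary(
    cluster: nx.Graph,
    phylum_map: Mapping[str, str],
    include_within: bool = False,
) -> list[PhylumPairSummary]:
    """Count positive/negative edges between each unordered phylum pair.

    Only inter-phylum edges (endpoints in two different grouped phyla) are
    tabulated by default; ``include_within=True`` adds (phylum, phylum)
    diagonal entries. Pairs are ordered by the canonical phylum order.
    """
    tally: dict[tuple[str, str], list[int]] = {}
    order = {p: i for i, p in enumerate((*MAJOR_PHYLA, OTHERS))}
    for u, v, d in cluster.edges(data=True):
        pu, pv = node_phylum(u, phylum_map), node_phylum(v, phylum_map)
        if pu == pv and not include_within:
            continue
        key = tuple(sorted((pu, pv), key=lambda p: (order.get(p, 99), p)))
        counts = tally.setdefault(key, [0, 0])
        counts[0 if _edge_sign(d) == POSITIVE else 1] += 1
    out = []
    for (pa, pb) in sorted(tally, key=lambda k: (order.get(k[0], 99), order.get(k[1], 99))):
        pos, neg = tally[(pa, pb)]
        out.append(
            PhylumPairSummary(
                phylum_a=pa, phylum_b=pb, n_total=pos + neg,
                n_positive=pos, n_negative=neg, pn_ratio=pn_ratio(pos, neg),
            )
        )
    return out


@dataclass
class GuildReport:
    """Bundle: partition, roles, compositions, pair summaries, dominants."""

    partition: SubGuildPartition
    roles: list[NodeRole]
    composition: dict[str, tuple[int, float]]
    group_compositions: list[dict[str, tuple[int, float]]]
    pair_summaries: list[PhylumPairSummary]
    dominant_phyla: list[dict]

    def role_counts(self) -> dict[str, dict[str, int]]:
        out: dict[str, dict[str, int]] = {}
        for r in self.roles:
            out.setdefault(r.sub_guild, {}).setdefault(r.role, 0)
            out[r.sub_guild][r.role] += 1
        return out

    def to_dict(self) -> dict:
        return {
            "groups": [sorted(map(str, g)) for g in self.partition.groups],
            "group_names": list(self.partition.names),
            "balanced": self.partition.balanced,
            "frustrated_edges": [list(map(str, e)) for e in self.partition.frustrated_edges],
            "roles": [asdict(r) for r in self.roles],
            "role_counts": self.role_counts(),
            "composition": {k: list(v) for k, v in self.composition.items()},
            "group_compositions": [
                {k: list(v) for k, v in comp.items()} for comp in self.group_compositions
            ],
            "pair_summaries": [
                {**asdict(s), "pn_ratio": None if s.pn_ratio != s.pn_ratio else s.pn_ratio}
                for s in self.pair_summaries
            ],
            "dominant_phyla": self.dominant_phyla,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=str)

    def write_roles_tsv(self, path: str | Path, phylum_map: Mapping[str, str]) -> None:
        with open(path, "w") as fh:
            fh.write("node\tsub_guild\trole\tphylum\n")
            for r in self.roles:
                fh.write(f"{r.node}\t{r.sub_guild}\t{r.role}\t"
                         f"{node_phylum(r.node, phylum_map)}\n")


def guild_report(
    network: nx.Graph,
    cluster_members: Iterable,
    phylum_map: Mapping[str, str],
    partition: SubGuildPartition | None = None,
) -> GuildReport:
    """Full guild analysis of a cluster within a signed network.

    Derives the sub-guild partition (unless one is supplied, e.g. from an
    external membership table), classifies node roles, and summarises phylum
    composition per group, phylum-pair P/N ratios, and each group's dominant
    phylum (all tied phyla are reported, flagged as a tie).
    """
    members = list(cluster_members)
    sub = network.subgraph(members)
    if partition is None:
        partition = partition_subguilds(sub)
    roles = classify_roles(sub, partition)
    group_comps = [phylum_composition(g, phylum_map) for g in partition.groups]
    dominants = []
    for name, comp, group in zip(partition.names, group_comps, partition.groups):
        if not comp:
            dominants.append({"group": name, "phyla": [], "fraction": 0.0, "tied": False})
            continue
        top = max(c for c, _ in comp.values())
        tied = sorted(p for p, (c, _) in comp.items() if c == top)
        dominants.append(
            {
                "group": name,
                "phyla": tied,
                "fraction": round_half_up(100.0 * top / len(group), 1),
                "tied": len(tied) > 1,
            }
        )
    return GuildReport(
        partition=partition,
        roles=roles,
        composition=phylum_composition(members, phylum_map),
        group_compositions=group_comps,
        pair_summaries=phylum_pair_summary(sub, phylum_map),
        dominant_phyla=dominants,
    )
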
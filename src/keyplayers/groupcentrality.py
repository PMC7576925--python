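"""Group generalizations of degree, betweenness, and closeness centrality.

Each metric collapses to the corresponding normalized single-node centrality
when the group has exactly one member, which is the defining property of the
group-centrality family.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from . import _core
from .graph import Graph, GraphError, as_members

CLOSENESS_METHODS = ("min", "max", "mean")


@dataclass(frozen=True)
class GroupCentralityScore:
    metric: str
    value: float
    group: tuple[str, ...]
    closeness_method: Optional[str] = None


def group_degree(g: Graph, group: Iterable[str]) -> float:
    """Distinct outside neighbors of the group over the outside-node count.

    Multiple ties from different members to the same outside node count
    once, so the value lies in [0, 1].
    """
    members = as_members(group)
    idx = g._indices(members)
    if g.n - len(members) < 1:
        raise GraphError("the group must leave at least one outside node")
    return _core.group_degree(g.adjacency, idx)


def group_betweenness(g: Graph, group: Iterable[str]) -> float:
    """Average over outside pairs of the share of shortest paths through K.

    For each unordered pair of outside nodes, the contribution is the
    fraction of their shortest paths with at least one interior vertex in
    the group.  Outside pairs that are disconnected in the intact graph are
    left out of the average entirely.
    """
    members = as_members(group)
    idx = g._indices(members)
    if g.n - len(members) < 2:
        raise GraphError("group betweenness needs at least two outside nodes")
    dist = g.shortest_path_matrix().values
    counts = _core.shortest_path_counts(g.adjacency, dist)
    return _core.group_betweenness(g.adjacency, dist, counts, idx)


def group_closeness(
    g: Graph,
    group: Iterable[str],
    method: str = "min",
    strict: bool = True,
) -> float:
    """Reciprocal of the mean group-to-outside distance; higher = closer.

    ``method`` picks how the distance from the group to one outside node is
    aggregated over members: the minimum (default), maximum, or mean of the
    member distances.  The score is (n - k) / sum_j dbar_Kj, in (0, 1].
    With ``strict`` (default) an outside node unreachable from every member
    raises; otherwise the score is defined as 0.
    """
    if method not in CLOSENESS_METHODS:
        raise GraphError(f"closeness method must be one of {CLOSENESS_METHODS}")
    members = as_members(group)
    idx = g._indices(members)
    if g.n - len(members) < 1:
        raise GraphError("the group must leave at least one outside node")
    dist = g.shortest_path_matrix().values
    try:
        return _core.group_closeness(dist, idx, method=method, strict=strict)
    except ValueError as exc:
        raise GraphError(str(exc)) from None


def score(
    g: Graph,
    group: Iterable[str],
    metric: str,
    closeness_method: str = "min",
) -> GroupCentralityScore:
    """Evaluate one of the three group metrics by name (GD / GB / GC)."""
    members = tuple(as_members(group))
    key = metric.upper()
    if key in ("GD", "DEGREE"):
        return GroupCentralityScore("GD", group_degree(g, members), members)
    if key in ("GB", "BETWEENNESS"):
        return GroupCentralityScore("GB", group_betweenness(g, members), members)
    if key in ("GC", "CLOSENESS"):
        return GroupCentralityScore(
            "GC", group_closeness(g, members, closeness_method), members,
            closeness_method=closeness_method)
    raise GraphError(f"unknown group-centrality metric {metric!r}")


# -- single-node centralities (the k = 1 specializations) -------------------

def degree_centrality(g: Graph, node: str) -> float:
    """deg(v) / (n - 1); equals group degree of the singleton {v}."""
    return group_degree(g, [node])


def closeness_centrality(g: Graph, node: str, strict: bool = True) -> float:
    """(n - 1) / sum of distances from v; the singleton group closeness."""
    return group_closeness(g, [node], method="min", strict=strict)


def betweenness_centrality(g: Graph, node: str | None = None):
    """Pair-normalized betweenness of one node, or of all nodes as a dict.

    Normalization matches the group definition at k = 1: the dependency sum
    is divided by the number of connected pairs not involving v.
    """
    dist = g.shortest_path_matrix().values
    counts = _core.shortest_path_counts(g.adjacency, dist)
    values = _core.node_betweenness(g.adjacency, dist, counts)
    table = {lab: float(v) for lab, v in zip(g.nodes, values)}
    if node is None:
        return table
    if node not in table:
        raise GraphError(f"unknown node {node!r}")
    return table[node]
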
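"""Key-player metrics: fragmentation (KPP-Neg) and reach (KPP-Pos).

Two families of group-importance scores for undirected, unweighted graphs:

* KPP-Neg asks how badly the network falls apart when a group K is removed.
  ``F`` measures fragmentation from the sizes of the surviving components;
  ``DF`` weights every surviving pair by the reciprocal of its shortest-path
  distance, so it distinguishes "connected but stretched" from "tight".
  Both reach their maximum of 1 on a fully isolated node set and 0 on a
  connected (F) or complete (DF) graph.

* KPP-Pos asks how well a group K covers the rest of the network while it
  stays in place.  ``DR`` is the sum over outside nodes of the reciprocal
  minimum distance to the group, divided by the total number of nodes n, so
  it peaks at (n-k)/n when every outside node is adjacent to the group.
  ``m_reach`` counts the distinct outside nodes within m hops of any member;
  the conventional percentage includes the group itself: (count + k)/n.

Unreachable pairs always contribute 1/d = 0, which makes disconnected input
legal for every metric here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from . import _core
from .graph import Graph, GraphError, as_members


@dataclass(frozen=True)
class KpScore:
    """Result of a key-player metric evaluation."""

    metric: str
    value: float
    group: tuple[str, ...]
    m: Optional[int] = None
    count: Optional[int] = None
    baseline: Optional[float] = None


def fragmentation(g: Graph, metric: str = "DF") -> float:
    """Fragmentation of the graph as it stands (no removal).

    ``F``  = 1 - sum_k s_k (s_k - 1) / (n (n - 1)) over component sizes s_k.
    ``DF`` = 1 - 2 sum_{i>j} (1/d_ij) / (n (n - 1)), with 1/d = 0 for
    unreachable pairs.
    """
    if g.n < 2:
        raise GraphError("fragmentation needs at least 2 nodes")
    metric = metric.upper()
    if metric == "F":
        return _core.fragmentation_f(g.adjacency)
    if metric == "DF":
        return _core.fragmentation_df(g.adjacency)
    raise GraphError(f"unknown fragmentation metric {metric!r}")


def kp_neg(g: Graph, group: Iterable[str], metric: str = "DF") -> KpScore:
    """Fragmentation caused by removing ``group``; baseline is the intact value.

    The score is the F or DF of the residual graph after deleting the group
    and its incident edges.
    """
    members = as_members(group)
    g._indices(members)  # validates membership
    if len(members) >= g.n - 1:
        raise GraphError("removal must leave at least 2 nodes")
    residual = g.remove_nodes(members)
    return KpScore(
        metric=metric.upper(),
        value=fragmentation(residual, metric),
        group=tuple(members),
        baseline=fragmentation(g, metric),
    )


def dR(g: Graph, group: Iterable[str]) -> float:
    """Distance-weighted reach of the group on the intact graph."""
    members = as_members(group)
    idx = g._indices(members)
    dist = g.shortest_path_matrix().values
    return _core.reach_dr(dist, idx)


def m_reach(g: Graph, group: Iterable[str], m: int) -> tuple[int, float]:
    """Nodes within ``m`` hops of the group.

    Returns ``(count, percentage)`` where count is the number of outside
    nodes reached and the percentage additionally includes the group nodes
    themselves: 100 * (count + k) / n.
    """
    if m < 0:
        raise GraphError("m must be non-negative")
    members = as_members(group)
    idx = g._indices(members)
    dist = g.shortest_path_matrix().values
    count = _core.mreach_count(dist, idx, m)
    pct = 100.0 * (count + len(members)) / g.n
    return count, pct


def kp_pos(g: Graph, group: Iterable[str], metric: str = "DR", m: int = 2) -> KpScore:
    """Reach score of a group (DR or MREACH) as a :class:`KpScore`."""
    members = as_members(group)
    metric = metric.upper()
    if metric == "DR":
        return KpScore(metric="DR", value=dR(g, members), group=tuple(members))
    if metric == "MREACH":
        count, pct = m_reach(g, members, m)
        return KpScore(metric="MREACH", value=pct, group=tuple(members),
                       m=m, count=count)
    raise GraphError(f"unknown reach metric {metric!r}")
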
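"""Simple undirected graph with string node labels.

The graph is immutable: every transforming operation returns a new object.
Node identity is the label itself; the contiguous integer indexing used by
the numeric kernels is internal and never leaks through the public surface.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import numpy as np

from . import _core

logger = logging.getLogger(__name__)


class _Unreachable:
    """Sentinel for node pairs with no connecting path."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - trivial
        return "UNREACHABLE"

    def __bool__(self) -> bool:
        return False


#: Distance value reported for disconnected node pairs.  A distinct object,
#: deliberately not a large finite number: reciprocal-distance metrics treat
#: it as 1/d = 0.
UNREACHABLE = _Unreachable()


class GraphError(ValueError):
    """Invalid graph construction or operation."""


def _check_label(label) -> str:
    if not isinstance(label, str) or label == "":
        raise GraphError(f"node labels must be non-empty strings, got {label!r}")
    return label


class Graph:
    """Simple undirected unweighted graph.

    Parameters
    ----------
    edges:
        Iterable of (u, v) label pairs.  Duplicate edges and reversed
        duplicates collapse to a single undirected edge.
    nodes:
        Additional (possibly isolated) node labels.
    strict:
        If True (default), a self-loop raises :class:`GraphError`; otherwise
        self-loops are dropped with a warning.
    """

    __slots__ = ("_labels", "_index", "_adj", "_edges", "graph_attrs",
                 "node_attrs", "edge_attrs")

    def __init__(
        self,
        edges: Iterable[tuple[str, str]] = (),
        nodes: Iterable[str] = (),
        strict: bool = True,
    ):
        edge_set: set[frozenset[str]] = set()
        node_set: set[str] = set()
        dup = 0
        for label in nodes:
            node_set.add(_check_label(label))
        for u, v in edges:
            u, v = _check_label(u), _check_label(v)
            if u == v:
                if strict:
                    raise GraphError(f"self-loop on node {u!r}")
                warnings.warn(f"dropping self-loop on node {u!r}", stacklevel=2)
                node_set.add(u)
                continue
            e = frozenset((u, v))
            if e in edge_set:
                dup += 1
            edge_set.add(e)
            node_set.update(e)
        if dup:
            logger.warning("collapsed %d duplicate/multi-edges to simple edges", dup)
        self._labels: tuple[str, ...] = tuple(sorted(node_set))
        self._index = {lab: i for i, lab in enumerate(self._labels)}
        n = len(self._labels)
        adj = np.zeros((n, n), dtype=bool)
        for e in edge_set:
            u, v = tuple(e)
            adj[self._index[u], self._index[v]] = True
            adj[self._index[v], self._index[u]] = True
        self._adj = adj
        self._adj.flags.writeable = False
        self._edges = frozenset(edge_set)
        self.graph_attrs: dict = {}
        self.node_attrs: dict[str, dict[str, object]] = {}
        self.edge_attrs: dict[frozenset, dict[str, object]] = {}

    # -- basic accessors ---------------------------------------------------
    @property
    def nodes(self) -> tuple[str, ...]:
        """Node labels in sorted order."""
        return self._labels

    @property
    def edges(self) -> list[tuple[str, str]]:
        """Edges as sorted (u, v) tuples, listed in sorted order."""
        return sorted(tuple(sorted(e)) for e in self._edges)

    @property
    def n(self) -> int:
        return len(self._labels)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def __contains__(self, label: str) -> bool:
        return label in self._index

    def __iter__(self) -> Iterator[str]:
        return iter(self._labels)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Graph):
            return NotImplemented
        return self._labels == other._labels and self._edges == other._edges

    def __hash__(self):
        return hash((self._labels, self._edges))

    def __repr__(self) -> str:
        return f"Graph(n={self.n}, edges={self.n_edges})"

    def has_edge(self, u: str, v: str) -> bool:
        return frozenset((u, v)) in self._edges

    def degree(self, label: str) -> int:
        return int(self._adj[self._require(label)].sum())

    def neighbors(self, label: str) -> tuple[str, ...]:
        row = self._adj[self._require(label)]
        return tuple(self._labels[i] for i in np.where(row)[0])

    def _require(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise GraphError(f"unknown node {label!r}") from None

    # -- index translation (internal use by metric/search layers) ---------
    def _indices(self, labels: Iterable[str]) -> np.ndarray:
        out = np.array([self._require(lab) for lab in labels], dtype=np.int64)
        if len(set(out)) != len(out):
            raise GraphError("duplicate node labels in group")
        return out

    @property
    def adjacency(self) -> np.ndarray:
        """Boolean adjacency matrix in sorted-label order (read-only)."""
        return self._adj

    # -- derived structure -------------------------------------------------
    def connected_components(self) -> list[set[str]]:
        """Partition of the node set into connected components."""
        labels = _core.component_labels(self._adj)
        comps: dict[int, set[str]] = {}
        for lab, cid in zip(self._labels, labels):
            comps.setdefault(int(cid), set()).add(lab)
        return [comps[cid] for cid in sorted(comps)]

    def shortest_path_matrix(self, workers: int = 1) -> "DistanceMatrix":
        """All-pairs BFS hop distances.

        The computation is partitioned by source node across ``workers``
        blocks and reassembled in order, so the result does not depend on
        the worker count.
        """
        dist = _core.all_pairs_distances(self._adj, workers=workers)
        return DistanceMatrix(self._labels, dist)

    def remove_nodes(self, group: Iterable[str]) -> "Graph":
        """New graph without the given nodes and their incident edges."""
        drop = {*(self._labels[i] for i in self._indices(group))}
        new = Graph(
            edges=[e for e in self.edges if not (set(e) & drop)],
            nodes=[lab for lab in self._labels if lab not in drop],
        )
        new.graph_attrs = dict(self.graph_attrs)
        new.node_attrs = {a: {nd: v for nd, v in table.items() if nd not in drop}
                          for a, table in self.node_attrs.items()}
        new.edge_attrs = {e: dict(v) for e, v in self.edge_attrs.items()
                          if not (set(e) & drop)}
        return new

    def subgraph(self, keep: Iterable[str]) -> "Graph":
        keep_set = {self._labels[i] for i in self._indices(keep)}
        drop = [lab for lab in self._labels if lab not in keep_set]
        return self.remove_nodes(drop)

    def relabel(self, mapping: Mapping[str, str]) -> "Graph":
        """New graph with node labels replaced according to ``mapping``."""
        def m(x: str) -> str:
            return mapping.get(x, x)
        new_labels = [m(x) for x in self._labels]
        if len(set(new_labels)) != len(new_labels):
            raise GraphError("relabel mapping collapses distinct nodes")
        return Graph(edges=[(m(u), m(v)) for u, v in self.edges],
                     nodes=new_labels)


@dataclass(frozen=True)
class NodeGroup:
    """A set of k distinct node labels of a graph."""

    members: frozenset[str]

    def __init__(self, members: Iterable[str]):
        ms = frozenset(_check_label(x) for x in members)
        if not ms:
            raise GraphError("a node group must contain at least one node")
        object.__setattr__(self, "members", ms)

    @property
    def k(self) -> int:
        return len(self.members)

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.members))


def as_members(group) -> list[str]:
    """Normalize a NodeGroup / iterable of labels to a sorted label list."""
    if isinstance(group, NodeGroup):
        return sorted(group.members)
    if isinstance(group, str):
        raise GraphError("a group must be an iterable of labels, not a string")
    return sorted(set(group))


class DistanceMatrix:
    """All-pairs shortest-path hop counts with an explicit unreachable marker."""

    __slots__ = ("_labels", "_index", "_dist")

    def __init__(self, labels: tuple[str, ...], dist: np.ndarray):
        self._labels = labels
        self._index = {lab: i for i, lab in enumerate(labels)}
        self._dist = dist
        self._dist.flags.writeable = False

    @property
    def labels(self) -> tuple[str, ...]:
        return self._labels

    def get(self, u: str, v: str):
        """Distance between u and v: an int, or UNREACHABLE."""
        d = self._dist[self._index[u], self._index[v]]
        return UNREACHABLE if d >= _core.INF else int(d)

    def group_distance(self, group, v: str):
        """Minimum distance from any group member to v (d_Kj)."""
        rows = [self._index[u] for u in as_members(group)]
        d = self._dist[rows, self._index[v]].min()
        return UNREACHABLE if d >= _core.INF else int(d)

    @property
    def values(self) -> np.ndarray:
        """Raw integer matrix in sorted-label order (internal marker for
        unreachable pairs); intended for the metric kernels."""
        return self._dist


def build_graph(
    edges: Iterable[tuple[str, str]] = (),
    isolated_nodes: Iterable[str] = (),
    strict: bool = True,
) -> Graph:
    """Construct a validated simple undirected graph."""
    return Graph(edges=edges, nodes=isolated_nodes, strict=strict)
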
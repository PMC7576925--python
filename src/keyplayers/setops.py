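"""Set operations on graphs: union, intersection, difference.

Node identity across graphs is label equality.  Union keeps every node and
edge from either operand; intersection keeps only shared nodes and shared
edges; difference keeps the nodes unique to the first operand and then
drops any edge that lost an endpoint, so the result is always a valid
simple graph.  Difference is deliberately not symmetric.
"""

from __future__ import annotations

import logging

from .graph import Graph, GraphError

logger = logging.getLogger(__name__)

OPERATIONS = ("union", "intersection", "difference")


def _merge_attrs(g1: Graph, g2: Graph, out: Graph, mode: str) -> None:
    if mode == "union":
        out.graph_attrs = {**g2.graph_attrs, **g1.graph_attrs}
        conflicts = {k for k in g1.graph_attrs if k in g2.graph_attrs
                     and g1.graph_attrs[k] != g2.graph_attrs[k]}
        if conflicts:
            logger.warning("graph attribute conflicts resolved in favor of "
                           "the first operand: %s", sorted(conflicts))
        for attrs1, attrs2, dest, keys in (
            (g1.node_attrs, g2.node_attrs, out.node_attrs, out.nodes),
            (g1.edge_attrs, g2.edge_attrs, out.edge_attrs,
             [frozenset(e) for e in out.edges]),
        ):
            for name in {*attrs1, *attrs2}:
                merged = {}
                for key in keys:
                    if name in attrs1 and key in attrs1[name]:
                        merged[key] = attrs1[name][key]
                    elif name in attrs2 and key in attrs2[name]:
                        merged[key] = attrs2[name][key]
                if merged:
                    dest[name] = merged
    elif mode == "intersection":
        out.graph_attrs = {k: v for k, v in g1.graph_attrs.items()
                           if g2.graph_attrs.get(k) == v}
        for attrs1, attrs2, dest, keys in (
            (g1.node_attrs, g2.node_attrs, out.node_attrs, out.nodes),
            (g1.edge_attrs, g2.edge_attrs, out.edge_attrs,
             [frozenset(e) for e in out.edges]),
        ):
            for name in attrs1:
                if name not in attrs2:
                    continue
                kept = {key: attrs1[name][key] for key in keys
                        if key in attrs1[name]
                        and attrs2[name].get(key) == attrs1[name][key]}
                if kept:
                    dest[name] = kept
    else:  # difference keeps the first operand's annotations
        out.graph_attrs = dict(g1.graph_attrs)
        kept_nodes = set(out.nodes)
        kept_edges = {frozenset(e) for e in out.edges}
        out.node_attrs = {a: {nd: v for nd, v in tab.items() if nd in kept_nodes}
                          for a, tab in g1.node_attrs.items()}
        out.edge_attrs = {e: dict(v) for e, v in g1.edge_attrs.items()
                          if e in kept_edges}


def graph_union(g1: Graph, g2: Graph) -> Graph:
    """(V1 | V2, E1 | E2)."""
    out = Graph(edges=[*g1.edges, *g2.edges],
                nodes=[*g1.nodes, *g2.nodes])
    _merge_attrs(g1, g2, out, "union")
    return out


def graph_intersection(g1: Graph, g2: Graph) -> Graph:
    """(V1 & V2, E1 & E2)."""
    nodes = set(g1.nodes) & set(g2.nodes)
    edges = {frozenset(e) for e in g1.edges} & {frozenset(e) for e in g2.edges}
    out = Graph(edges=[tuple(sorted(e)) for e in edges], nodes=nodes)
    _merge_attrs(g1, g2, out, "intersection")
    return out


def graph_difference(g1: Graph, g2: Graph) -> Graph:
    """(V1 - V2, E1 - E2), then pruning edges that lost an endpoint."""
    nodes = set(g1.nodes) - set(g2.nodes)
    drop_edges = {frozenset(e) for e in g2.edges}
    edges = [e for e in g1.edges
             if frozenset(e) not in drop_edges and set(e) <= nodes]
    out = Graph(edges=edges, nodes=nodes)
    _merge_attrs(g1, g2, out, "difference")
    return out


def set_operation(g1: Graph, g2: Graph, op: str) -> Graph:
    """Apply a named set operation (union / intersection / difference)."""
    if op == "union":
        return graph_union(g1, g2)
    if op == "intersection":
        return graph_intersection(g1, g2)
    if op == "difference":
        return graph_difference(g1, g2)
    raise GraphError(f"unknown set operation {op!r}; choose from {OPERATIONS}")
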
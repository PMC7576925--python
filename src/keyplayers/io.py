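"""Read and write graphs in the supported interchange formats.

Formats
-------
``sif``
    Cytoscape Simple Interaction Format: ``source <type> target [target2 …]``
    per line, tab- or space-separated.  The interaction-type token is kept
    as an edge attribute but plays no topological role; a line with a single
    token declares an isolated node.
``edge_list``
    Two whitespace-separated node labels per line; ``#`` starts a comment.
``adjacency_matrix``
    Tab-separated 0/1 square symmetric matrix, zero diagonal, with an
    optional header row and column of node labels.  Values other than 0/1
    and asymmetric matrices are rejected (the model is undirected and
    unweighted).
``dot``
    Undirected ``graph { a -- b; }`` subset; ``digraph`` input is rejected.
``binary``
    A versioned pickled container of node list, edge list, and attributes.
    Internal to this package; no cross-language durability is claimed.
"""

from __future__ import annotations

import pickle
import re
from dataclasses import dataclass, field
from pathlib import Path

from .graph import Graph, GraphError

FORMATS = ("sif", "edge_list", "adjacency_matrix", "dot", "binary")

_BINARY_MAGIC = b"KEYPLAYERS-GRAPH"
_BINARY_VERSION = 1


class FormatError(GraphError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        prefix = f"line {line}: " if line is not None else ""
        super().__init__(prefix + message)


@dataclass(frozen=True)
class FormatSpec:
    """Parsing/serialization options for one of the supported formats."""

    format: str
    header: bool = True          # adjacency matrix only
    separator: str | None = None  # None = any whitespace
    comment: str = "#"

    def __post_init__(self):
        if self.format not in FORMATS:
            raise FormatError(f"unknown format {self.format!r}; "
                              f"choose from {FORMATS}")
        if self.separator is not None and len(self.separator) != 1:
            raise FormatError("separator must be a single character")


def _lines(text: str, comment: str):
    for i, raw in enumerate(text.splitlines(), start=1):
        line = raw.split(comment)[0].rstrip("\n") if comment else raw
        if line.strip():
            yield i, line


def _split(line: str, sep: str | None) -> list[str]:
    return line.split(sep) if sep else line.split()


# ---------------------------------------------------------------------------
# readers

def _read_sif(text: str, spec: FormatSpec) -> Graph:
    edges, nodes, types = [], [], {}
    for ln, line in _lines(text, spec.comment):
        tokens = _split(line, spec.separator)
        if len(tokens) == 1:
            nodes.append(tokens[0])
        elif len(tokens) >= 3:
            src, itype = tokens[0], tokens[1]
            for tgt in tokens[2:]:
                edges.append((src, tgt))
                types[frozenset((src, tgt))] = itype
        else:
            raise FormatError(
                "a SIF line needs 1 token (isolated node) or >= 3 "
                f"(source type target...), got {len(tokens)}", ln)
    g = Graph(edges=edges, nodes=nodes)
    if types:
        g.edge_attrs["interaction"] = types
    return g


def _read_edge_list(text: str, spec: FormatSpec) -> Graph:
    edges = []
    for ln, line in _lines(text, spec.comment):
        tokens = _split(line, spec.separator)
        if len(tokens) == 1:
            # tolerated extension so isolated nodes survive a round-trip
            edges.append((tokens[0],))
        elif len(tokens) == 2:
            edges.append(tuple(tokens))
        else:
            raise FormatError(
                f"an edge-list line needs exactly 2 tokens, got {len(tokens)}", ln)
    return Graph(edges=[e for e in edges if len(e) == 2],
                 nodes=[e[0] for e in edges if len(e) == 1])


def _read_adjacency(text: str, spec: FormatSpec) -> Graph:
    rows = []
    for ln, line in _lines(text, spec.comment):
        rows.append((ln, _split(line, spec.separator or "\t")))
    if not rows:
        return Graph()
    if spec.header:
        header = rows[0][1]
        labels = header[1:] if len(header) == len(rows) else header
        body = rows[1:]
        if len(body) != len(labels):
            raise FormatError(
                f"matrix has {len(body)} rows for {len(labels)} labels")
    else:
        body = rows
        labels = [str(i + 1) for i in range(len(body))]
    n = len(labels)
    matrix = []
    for ln, tokens in body:
        values = tokens[1:] if spec.header and len(tokens) == n + 1 else tokens
        if len(values) != n:
            raise FormatError(f"expected {n} values, got {len(values)}", ln)
        row = []
        for v in values:
            if v not in ("0", "1"):
                raise FormatError(
                    f"adjacency values must be 0 or 1, got {v!r}", ln)
            row.append(int(v))
        matrix.append(row)
    for i in range(n):
        if matrix[i][i] != 0:
            raise FormatError(f"non-zero diagonal at {labels[i]!r}")
        for j in range(i + 1, n):
            if matrix[i][j] != matrix[j][i]:
                raise FormatError(
                    f"asymmetric adjacency at ({labels[i]!r}, {labels[j]!r}); "
                    "only undirected graphs are supported")
    edges = [(labels[i], labels[j]) for i in range(n)
             for j in range(i + 1, n) if matrix[i][j]]
    return Graph(edges=edges, nodes=labels)


_DOT_EDGE = re.compile(r'^\s*"?([^"\s]+)"?\s*--\s*"?([^"\s;]+)"?\s*;?\s*$')
_DOT_NODE = re.compile(r'^\s*"?([^"\s;{}=\[]+)"?\s*;\s*$')


def _read_dot(text: str, spec: FormatSpec) -> Graph:
    stripped = re.sub(r"//.*", "", text)
    stripped = re.sub(r"/\*.*?\*/", "", stripped, flags=re.S)
    m = re.search(r"\b(strict\s+)?(graph|digraph)\b([^{]*)\{(.*)\}",
                  stripped, flags=re.S)
    if not m:
        raise FormatError("no graph block found in dot input")
    if m.group(2) == "digraph":
        raise FormatError("directed graphs (digraph) are not supported; "
                          "use an undirected 'graph { }' block")
    body = m.group(4)
    edges, nodes = [], []
    for stmt in re.split(r"[;\n]", body):
        stmt = stmt.strip()
        if not stmt or stmt.startswith(("node", "edge", "graph", "label")):
            continue
        if "->" in stmt:
            raise FormatError("directed edge operator '->' in an undirected graph")
        if "--" in stmt:
            parts = [p.strip().strip('"') for p in stmt.split("--")]
            if any(not p for p in parts):
                raise FormatError(f"malformed edge statement {stmt!r}")
            for a, b in zip(parts[:-1], parts[1:]):
                edges.append((a.split("[")[0].strip().strip('"'),
                              b.split("[")[0].strip().strip('"')))
        else:
            token = stmt.split("[")[0].strip().strip('"')
            if token and "=" not in token:
                nodes.append(token)
    return Graph(edges=edges, nodes=nodes)


def _read_binary(path: Path) -> Graph:
    with open(path, "rb") as fh:
        magic = fh.read(len(_BINARY_MAGIC))
        if magic != _BINARY_MAGIC:
            raise FormatError("not a keyplayers binary graph file")
        payload = pickle.load(fh)
    if payload.get("version") != _BINARY_VERSION:
        raise FormatError(f"unsupported binary version {payload.get('version')!r}")
    g = Graph(edges=payload["edges"], nodes=payload["nodes"])
    g.graph_attrs = payload.get("graph_attrs", {})
    g.node_attrs = payload.get("node_attrs", {})
    g.edge_attrs = {frozenset(k): v for k, v
                    in payload.get("edge_attrs", {}).items()}
    return g


def read_graph(path, spec: FormatSpec | str) -> Graph:
    """Load a graph from ``path`` according to ``spec`` (or a format name)."""
    if isinstance(spec, str):
        spec = FormatSpec(format=spec)
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if spec.format == "binary":
        return _read_binary(path)
    text = path.read_text()
    reader = {"sif": _read_sif, "edge_list": _read_edge_list,
              "adjacency_matrix": _read_adjacency, "dot": _read_dot}[spec.format]
    return reader(text, spec)


# ---------------------------------------------------------------------------
# writers

def _write_sif(g: Graph, spec: FormatSpec) -> str:
    sep = spec.separator or "\t"
    types = g.edge_attrs.get("interaction", {})
    lines = []
    seen = set()
    for u, v in g.edges:
        itype = types.get(frozenset((u, v)), "interacts")
        lines.append(f"{u}{sep}{itype}{sep}{v}")
        seen.update((u, v))
    for node in g.nodes:
        if node not in seen:
            lines.append(node)
    return "\n".join(lines) + ("\n" if lines else "")


def _write_edge_list(g: Graph, spec: FormatSpec) -> str:
    sep = spec.separator or "\t"
    lines = [f"{u}{sep}{v}" for u, v in g.edges]
    linked = {x for e in g.edges for x in e}
    lines += [node for node in g.nodes if node not in linked]
    return "\n".join(lines) + ("\n" if lines else "")


def _write_adjacency(g: Graph, spec: FormatSpec) -> str:
    sep = spec.separator or "\t"
    labels = list(g.nodes)
    lines = []
    if spec.header:
        lines.append(sep.join([""] + labels))
    for u in labels:
        row = ["1" if g.has_edge(u, v) else "0" for v in labels]
        lines.append(sep.join(([u] if spec.header else []) + row))
    return "\n".join(lines) + ("\n" if lines else "")


def _write_dot(g: Graph, spec: FormatSpec) -> str:
    lines = ["graph {"]
    linked = {x for e in g.edges for x in e}
    for node in g.nodes:
        if node not in linked:
            lines.append(f'    "{node}";')
    for u, v in g.edges:
        lines.append(f'    "{u}" -- "{v}";')
    lines.append("}")
    return "\n".join(lines) + "\n"


def write_graph(g: Graph, path, spec: FormatSpec | str) -> Path:
    """Serialize ``g`` to ``path``; a later :func:`read_graph` reproduces it."""
    if isinstance(spec, str):
        spec = FormatSpec(format=spec)
    path = Path(path)
    if spec.format == "binary":
        payload = {
            "version": _BINARY_VERSION,
            "nodes": list(g.nodes),
            "edges": list(g.edges),
            "graph_attrs": g.graph_attrs,
            "node_attrs": g.node_attrs,
            "edge_attrs": {tuple(sorted(k)): v for k, v in g.edge_attrs.items()},
        }
        with open(path, "wb") as fh:
            fh.write(_BINARY_MAGIC)
            pickle.dump(payload, fh)
        return path
    writer = {"sif": _write_sif, "edge_list": _write_edge_list,
              "adjacency_matrix": _write_adjacency, "dot": _write_dot}[spec.format]
    path.write_text(writer(g, spec))
    return path


# ---------------------------------------------------------------------------
# attribute tables

def attach_attributes(g: Graph, table: dict, target: str = "node",
                      name: str = "attribute", on_missing: str = "error") -> Graph:
    """Attach a name -> value table to nodes, edges, or the graph itself.

    ``table`` maps node labels (or (u, v) pairs for edges) to values; for
    ``target='graph'`` it is stored as-is.  Unknown names either raise or
    are skipped with a warning, per ``on_missing``.
    """
    import warnings

    if target not in ("node", "edge", "graph"):
        raise GraphError("target must be 'node', 'edge', or 'graph'")
    out = g.remove_nodes([])  # cheap attribute-preserving copy
    if target == "graph":
        out.graph_attrs[name] = table
        return out
    store: dict = {}
    for key, value in table.items():
        if target == "node":
            if key not in g:
                if on_missing == "error":
                    raise GraphError(f"unknown node {key!r} in attribute table")
                warnings.warn(f"skipping unknown node {key!r}", stacklevel=2)
                continue
            store[key] = value
        else:
            u, v = key
            if not g.has_edge(u, v):
                if on_missing == "error":
                    raise GraphError(f"unknown edge {key!r} in attribute table")
                warnings.warn(f"skipping unknown edge {key!r}", stacklevel=2)
                continue
            store[frozenset((u, v))] = value
    if store:
        dest = out.node_attrs if target == "node" else out.edge_attrs
        dest.setdefault(name, {}).update(store)
    return out


def read_attributes(path, target: str = "node") -> dict:
    """Load a two-column (or three-column for edges) attribute TSV."""
    table = {}
    for ln, line in _lines(Path(path).read_text(), "#"):
        tokens = line.split("\t")
        if target == "edge":
            if len(tokens) != 3:
                raise FormatError("edge attribute rows need 3 columns", ln)
            table[(tokens[0], tokens[1])] = tokens[2]
        else:
            if len(tokens) != 2:
                raise FormatError("node attribute rows need 2 columns", ln)
            table[tokens[0]] = tokens[1]
    return table


def write_attributes(g: Graph, path, name: str, target: str = "node") -> Path:
    """Export one attribute table to TSV (inverse of :func:`read_attributes`)."""
    path = Path(path)
    lines = []
    if target == "node":
        for node, value in sorted(g.node_attrs.get(name, {}).items()):
            lines.append(f"{node}\t{value}")
    else:
        for edge, value in sorted(g.edge_attrs.get(name, {}).items(),
                                  key=lambda kv: tuple(sorted(kv[0]))):
            u, v = sorted(edge)
            lines.append(f"{u}\t{v}\t{value}")
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path
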
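"""Machine-readable run reports.

Every analysis of a graph can be appended to a single JSON report file:
the file keeps one summary of the graph plus a list of timestamped run
entries, so repeated analyses of the same network accumulate instead of
overwriting.  Serialization is deterministic — keys are sorted and floats
are written with four decimals — so identical runs produce byte-identical
entries apart from the isolated timestamp field.
"""

from __future__ import annotations

import dataclasses
import json
from datetime import datetime, timezone
from pathlib import Path

from .graph import Graph

_FLOAT_DECIMALS = 4


def _normalize(obj):
    """Make results JSON-serializable with fixed float formatting."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _normalize(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(_key(k)): _normalize(v) for k, v in sorted(
            obj.items(), key=lambda kv: str(_key(kv[0])))}
    if isinstance(obj, float):
        return round(obj, _FLOAT_DECIMALS)
    if isinstance(obj, (list, tuple, set, frozenset)):
        items = [_normalize(v) for v in obj]
        return sorted(items, key=repr) if isinstance(obj, (set, frozenset)) else items
    return obj


def _key(k):
    if isinstance(k, (tuple, frozenset)):
        return ",".join(sorted(map(str, k)))
    return k


def graph_summary(g: Graph) -> dict:
    return {
        "nodes": g.n,
        "edges": g.n_edges,
        "components": len(g.connected_components()),
    }


def render_report(results, fmt: str = "json") -> str:
    """Serialize analysis results deterministically as JSON or aligned text."""
    data = _normalize(results)
    if fmt == "json":
        return json.dumps(data, sort_keys=True, indent=2) + "\n"
    if fmt == "text":
        lines = []

        def walk(prefix, node):
            if isinstance(node, dict):
                for k, v in node.items():
                    walk(f"{prefix}{k}.", v) if isinstance(v, (dict, list)) \
                        else lines.append(f"{prefix}{k}\t{v}")
            elif isinstance(node, list):
                lines.append(f"{prefix.rstrip('.')}\t" + "; ".join(map(str, node)))
            else:
                lines.append(f"{prefix.rstrip('.')}\t{node}")
        walk("", data)
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown report format {fmt!r}")


def append_run(path, g: Graph, command: str, parameters: dict, results) -> dict:
    """Append one timestamped run entry to the JSON report at ``path``."""
    path = Path(path)
    if path.exists():
        report = json.loads(path.read_text())
    else:
        report = {"tool": "keyplayers", "graph": graph_summary(g), "runs": []}
    report["graph"] = graph_summary(g)
    report["runs"].append({
        "timestamp": datetime.now(timezone.utc).isoformat(timespec="seconds"),
        "command": command,
        "parameters": _normalize(parameters),
        "results": _normalize(results),
    })
    path.write_text(json.dumps(report, sort_keys=True, indent=2) + "\n")
    return report
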
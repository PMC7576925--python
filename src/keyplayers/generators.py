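"""Random-graph generators and the packaged 24-node example network.

The Erdős–Rényi G(n, p) generator is first-class and fully seeded: each of
the C(n, 2) possible edges is drawn independently with probability p.
Scale-free (Barabási–Albert) and small-world (Watts–Strogatz) generation
delegate to networkx, relabelled to this package's string-label convention.

The example network is a 24-node, 24-edge connected graph shipped as
package data.  Its edge list is a synthetic reconstruction: the original
figure it emulates is published only as a drawing, so the topology here was
rebuilt by constraint search until it reproduced every printed fact about
that network — node degrees and degree ranking, inter-hub distances, all
twelve group-centrality and twelve key-player table values, and the
exhaustive-search optima for group sizes 2, 5, and 6.
:func:`validate_fixture` re-checks all of those facts and is run by the
test suite on every build.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import networkx as nx

from .graph import Graph, GraphError

__all__ = [
    "erdos_renyi", "barabasi_albert", "watts_strogatz",
    "example_network", "validate_fixture", "FixtureValidation",
]


def _labels(n: int) -> list[str]:
    return [str(i + 1) for i in range(n)]


def erdos_renyi(n: int, p: float, seed: int | None = None) -> Graph:
    """G(n, p): every possible edge appears independently with probability p."""
    if n < 1:
        raise GraphError("n must be at least 1")
    if not 0.0 <= p <= 1.0:
        raise GraphError("edge probability must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, 1)
    draws = rng.random(len(iu[0])) < p
    labels = _labels(n)
    edges = [(labels[i], labels[j])
             for i, j, keep in zip(iu[0], iu[1], draws) if keep]
    return Graph(edges=edges, nodes=labels)


def _from_networkx(gnx) -> Graph:
    return Graph(edges=[(str(u + 1), str(v + 1)) for u, v in gnx.edges()],
                 nodes=[str(v + 1) for v in gnx.nodes()])


def barabasi_albert(n: int, m: int, seed: int | None = None) -> Graph:
    """Scale-free preferential-attachment graph (networkx construction)."""
    return _from_networkx(nx.barabasi_albert_graph(n, m, seed=seed))


def watts_strogatz(n: int, k: int, p: float, seed: int | None = None) -> Graph:
    """Small-world ring-rewiring graph (networkx construction)."""
    return _from_networkx(nx.watts_strogatz_graph(n, k, p, seed=seed))


def example_network() -> Graph:
    """The packaged 24-node example network (see module docstring)."""
    text = (resources.files("keyplayers.data") / "example24.tsv").read_text()
    edges = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        u, v = line.split()
        edges.append((u, v))
    return Graph(edges=edges)


@dataclass(frozen=True)
class FixtureValidation:
    """Outcome of checking the example network against its documented facts."""

    checks: tuple  # (name, expected, observed, passed)

    @property
    def all_pass(self) -> bool:
        return all(c[3] for c in self.checks)

    def failures(self):
        return [c for c in self.checks if not c[3]]


def validate_fixture(g: Graph) -> FixtureValidation:
    """Check a graph against every documented fact of the example network."""
    from . import keyplayer as kp
    from . import groupcentrality as gc

    checks: list[tuple] = []

    def expect(name, expected, observed, tol=None):
        # `observed` may be a thunk so that one failing computation (e.g.
        # closeness on a disconnected perturbation) is recorded, not raised
        if callable(observed):
            try:
                observed = observed()
            except Exception as exc:  # noqa: BLE001 - recorded as evidence
                checks.append((name, expected, f"error: {exc}", False))
                return
        if tol is None:
            ok = expected == observed
        else:
            ok = abs(expected - observed) <= tol
        checks.append((name, expected, observed, ok))

    expect("node count", 24, g.n)
    expect("connected", 1, len(g.connected_components()))
    expect("degree of node 2", 7, g.degree("2"))
    expect("degree of node 9", 6, g.degree("9"))
    expect("degree of node 16", 5, g.degree("16"))
    expect("degree of node 21", 4, g.degree("21"))
    ranked = sorted(g.nodes, key=lambda v: (-g.degree(v), int(v)))
    expect("degree ranking starts 2,9,16,21", ("2", "9", "16", "21"),
           tuple(ranked[:4]))
    expect("node 9 adjacent to 16", True, g.has_edge("9", "16"))
    expect("node 9 adjacent to 21", True, g.has_edge("9", "21"))
    dm = g.shortest_path_matrix()
    expect("distance between 2 and 9", 5, lambda: dm.get("2", "9"))

    # group-centrality table
    expect("GD {2,21}", 0.50, lambda: gc.group_degree(g, ["2", "21"]), 0.005)
    expect("GD {2,9}", 0.59, lambda: gc.group_degree(g, ["2", "9"]), 0.005)
    expect("GD {21,9}", 0.36, lambda: gc.group_degree(g, ["21", "9"]), 0.005)
    expect("GD {2,9,21}", 0.71, lambda: gc.group_degree(g, ["2", "9", "21"]), 0.005)
    expect("GB {2,21}", 0.39, lambda: gc.group_betweenness(g, ["2", "21"]), 0.005)
    expect("GB {2,9}", 0.43, lambda: gc.group_betweenness(g, ["2", "9"]), 0.005)
    expect("GB {21,9}", 0.35, lambda: gc.group_betweenness(g, ["21", "9"]), 0.005)
    expect("GB {2,9,21}", 0.45, lambda: gc.group_betweenness(g, ["2", "9", "21"]), 0.005)
    expect("GC {2,21}", 0.58, lambda: gc.group_closeness(g, ["2", "21"]), 0.005)
    expect("GC {2,9}", 0.69, lambda: gc.group_closeness(g, ["2", "9"]), 0.005)
    expect("GC {21,9}", 0.38, lambda: gc.group_closeness(g, ["21", "9"]), 0.005)
    expect("GC {2,9,21}", 0.75, lambda: gc.group_closeness(g, ["2", "9", "21"]), 0.005)

    # key-player table (m-reach percentages are exact fractions of 24)
    expect("baseline DF", 0.66, lambda: kp.fragmentation(g, "DF"), 0.005)
    expect("DF minus {2,21}", 0.87, kp.kp_neg(g, ["2", "21"]).value, 0.005)
    expect("DF minus {2,9}", 0.91, kp.kp_neg(g, ["2", "9"]).value, 0.005)
    expect("DF minus {21,9}", 0.84, kp.kp_neg(g, ["21", "9"]).value, 0.005)
    expect("DF minus {2,9,21}", 0.93, kp.kp_neg(g, ["2", "9", "21"]).value, 0.005)
    expect("m-reach {2,21}", 19 / 24 * 100, kp.m_reach(g, ["2", "21"], 2)[1], 1e-9)
    expect("m-reach {2,9}", 23 / 24 * 100, kp.m_reach(g, ["2", "9"], 2)[1], 1e-9)
    expect("m-reach {21,9}", 15 / 24 * 100, kp.m_reach(g, ["21", "9"], 2)[1], 1e-9)
    expect("m-reach {2,9,21}", 23 / 24 * 100,
           kp.m_reach(g, ["2", "9", "21"], 2)[1], 1e-9)
    expect("DR {2,21}", 0.65, kp.dR(g, ["2", "21"]), 0.005)
    expect("DR {2,9}", 0.72, kp.dR(g, ["2", "9"]), 0.005)
    expect("DR {21,9}", 0.53, kp.dR(g, ["21", "9"]), 0.005)
    expect("DR {2,9,21}", 0.74, kp.dR(g, ["2", "9", "21"]), 0.005)

    # headline facts from the narrative
    expect("{5,9} reaches all outside nodes in 2 hops", 22,
           lambda: kp.m_reach(g, ["5", "9"], 2)[0])
    six = ["2", "9", "11", "14", "16", "21"]
    expect("DF = 1 after removing the six-node set", 1.0,
           lambda: kp.kp_neg(g, six).value, 1e-12)
    for grp in (["2", "9", "11", "16", "21"], ["2", "9", "10", "16", "21"]):
        expect(f"GD = 1 for {{{','.join(grp)}}}", 1.0,
               lambda grp=grp: gc.group_degree(g, grp), 1e-12)
        expect(f"DR = 19/24 for {{{','.join(grp)}}}", 19 / 24,
               lambda grp=grp: kp.dR(g, grp), 1e-12)
    expect("best size-5 betweenness 0.497", 0.497,
           lambda: gc.group_betweenness(g, ["2", "9", "11", "16", "21"]), 0.0005)
    return FixtureValidation(checks=tuple(checks))
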
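"""Group degree, betweenness, and closeness.

Group betweenness normalizes the unordered-pair sum by the ordered pair
count (n-k)(n-k-1), so a group lying on every outside shortest path scores
0.5; the k = 1 specialization uses the same convention, which equals half
of the networkx-normalized node betweenness.
"""

import itertools
import random

import networkx as nx
import pytest

from keyplayers import (
    GraphError,
    betweenness_centrality,
    build_graph,
    closeness_centrality,
    degree_centrality,
    group_betweenness,
    group_closeness,
    group_degree,
)
from keyplayers.groupcentrality import score

from conftest import random_graph, to_networkx


def connected_random_graph(seed, n=9):
    for attempt in range(50):
        g = random_graph(seed * 100 + attempt, n=n, p=0.35)
        if len(g.connected_components()) == 1:
            return g
    raise AssertionError("no connected graph found")


class TestGroupDegree:
    def test_star_center_singleton_is_one(self):
        g = build_graph([("c", f"l{i}") for i in range(5)])
        assert group_degree(g, ["c"]) == 1.0

    def test_shared_neighbor_counted_once(self):
        g = build_graph([("a", "x"), ("b", "x"), ("a", "y")])
        # neighbors of {a,b} outside the group: x, y -> 2 of 2
        assert group_degree(g, ["a", "b"]) == 1.0

    def test_whole_node_set_rejected(self):
        g = build_graph([("a", "b")])
        with pytest.raises(GraphError):
            group_degree(g, ["a", "b"])

    @pytest.mark.parametrize("seed", range(10))
    def test_adding_boundary_edge_never_lowers_it(self, seed):
        g = random_graph(seed, n=9, p=0.3)
        rng = random.Random(seed)
        group = rng.sample(list(g.nodes), 3)
        outside = [v for v in g.nodes if v not in group]
        missing = [(u, v) for u in group for v in outside if not g.has_edge(u, v)]
        if not missing:
            pytest.skip("group already saturated")
        u, v = rng.choice(missing)
        denser = build_graph(g.edges + [(u, v)], isolated_nodes=g.nodes)
        assert group_degree(denser, group) >= group_degree(g, group) - 1e-12


class TestGroupBetweenness:
    def test_path_interior_carries_every_pair(self):
        g = build_graph([("a", "b"), ("b", "c")])
        # the single outside pair (a, c) depends entirely on b: sum = 1,
        # normalized by the ordered pair count 2
        assert group_betweenness(g, ["b"]) == pytest.approx(0.5)

    def test_star_center_and_leaf(self):
        g = build_graph([("c", f"l{i}") for i in range(4)])
        assert group_betweenness(g, ["c"]) == pytest.approx(0.5)
        assert group_betweenness(g, ["l0"]) == 0.0

    def test_too_few_outside_nodes_rejected(self):
        g = build_graph([("a", "b"), ("b", "c")])
        with pytest.raises(GraphError):
            group_betweenness(g, ["a", "b"])

    @pytest.mark.parametrize("seed", range(10))
    def test_exhaustive_path_enumeration_oracle(self, seed):
        """Counting-based GB equals explicit enumeration of shortest paths."""
        g = connected_random_graph(seed, n=8)
        gnx = to_networkx(g)
        rng = random.Random(seed)
        group = set(rng.sample(list(g.nodes), 2))
        outside = [v for v in g.nodes if v not in group]
        total = 0.0
        for u, v in itertools.combinations(outside, 2):
            paths = list(nx.all_shortest_paths(gnx, u, v))
            through = sum(1 for p in paths if group & set(p[1:-1]))
            total += through / len(paths)
        npairs = len(outside) * (len(outside) - 1)
        assert group_betweenness(g, group) == pytest.approx(total / npairs)

    def test_disconnected_pairs_are_excluded(self):
        g = build_graph([("a", "b"), ("b", "c"), ("x", "y")])
        # outside pairs of {b}: (a,c) connected through b; (a,x),(a,y),
        # (c,x),(c,y) disconnected and excluded; (x,y) connected, not via b
        assert group_betweenness(g, ["b"]) == pytest.approx(1 / 4)


class TestGroupCloseness:
    def test_star_center_is_one(self):
        g = build_graph([("c", f"l{i}") for i in range(6)])
        assert group_closeness(g, ["c"], "min") == 1.0

    def test_methods_order_on_a_path(self):
        g = build_graph([("a", "b"), ("b", "c"), ("c", "d")])
        gmin = group_closeness(g, ["a", "d"], "min")
        gmax = group_closeness(g, ["a", "d"], "max")
        gmean = group_closeness(g, ["a", "d"], "mean")
        assert gmin >= gmean >= gmax

    def test_unreachable_outside_node_strict_vs_lenient(self):
        g = build_graph([("a", "b")], isolated_nodes=["z"])
        with pytest.raises(GraphError, match="unreachable"):
            group_closeness(g, ["a"], "min")
        assert group_closeness(g, ["a"], "min", strict=False) == 0.0

    def test_unknown_method_rejected(self):
        g = build_graph([("a", "b")])
        with pytest.raises(GraphError, match="method"):
            group_closeness(g, ["a"], "median")


class TestSingletonEquivalence:
    """Each group metric at k = 1 equals the node-level centrality."""

    @pytest.mark.parametrize("seed", range(12))
    def test_degree_matches_networkx(self, seed):
        g = random_graph(seed, n=10)
        oracle = nx.degree_centrality(to_networkx(g))
        for v in g.nodes:
            assert degree_centrality(g, v) == pytest.approx(oracle[v])
            assert group_degree(g, [v]) == pytest.approx(oracle[v])

    @pytest.mark.parametrize("seed", range(12))
    def test_betweenness_matches_networkx_up_to_pair_convention(self, seed):
        g = connected_random_graph(seed, n=9)
        oracle = nx.betweenness_centrality(to_networkx(g), normalized=True)
        ours = betweenness_centrality(g)
        for v in g.nodes:
            assert ours[v] == pytest.approx(oracle[v] / 2)
            assert group_betweenness(g, [v]) == pytest.approx(oracle[v] / 2)

    @pytest.mark.parametrize("seed", range(12))
    def test_closeness_matches_networkx(self, seed):
        g = connected_random_graph(seed, n=9)
        oracle = nx.closeness_centrality(to_networkx(g))
        for v in g.nodes:
            assert closeness_centrality(g, v) == pytest.approx(oracle[v])
            for method in ("min", "max", "mean"):
                assert group_closeness(g, [v], method) == pytest.approx(oracle[v])


class TestRelabelingInvariance:
    @pytest.mark.parametrize("seed", range(8))
    def test_all_three_metrics_survive_relabeling(self, seed):
        g = connected_random_graph(seed, n=8)
        rng = random.Random(seed)
        group = rng.sample(list(g.nodes), 3)
        perm = list(g.nodes)
        rng.shuffle(perm)
        mapping = {old: f"z{new}" for old, new in zip(g.nodes, perm)}
        h = g.relabel(mapping)
        mapped = [mapping[v] for v in group]
        assert group_degree(h, mapped) == pytest.approx(group_degree(g, group))
        assert group_betweenness(h, mapped) == pytest.approx(
            group_betweenness(g, group))
        for method in ("min", "max", "mean"):
            assert group_closeness(h, mapped, method) == pytest.approx(
                group_closeness(g, group, method))


def test_score_dispatcher_names():
    g = build_graph([("a", "b"), ("b", "c")])
    assert score(g, ["b"], "degree").metric == "GD"
    assert score(g, ["b"], "GB").value == pytest.approx(0.5)
    assert score(g, ["b"], "closeness", closeness_method="mean").closeness_method == "mean"
    with pytest.raises(GraphError):
        score(g, ["b"], "pagerank")
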
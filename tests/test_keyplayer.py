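"""Fragmentation (F, DF) and reach (DR, m-reach) metrics."""

import itertools
import random

import networkx as nx
import pytest

from keyplayers import (
    UNREACHABLE,
    GraphError,
    build_graph,
    dR,
    fragmentation,
    kp_neg,
    kp_pos,
    m_reach,
)

from conftest import random_graph, to_networkx


def complete(n):
    labels = [f"k{i}" for i in range(n)]
    return build_graph(list(itertools.combinations(labels, 2)))


class TestFragmentation:
    def test_all_isolates_score_one(self):
        g = build_graph([], isolated_nodes=[f"i{i}" for i in range(6)])
        assert fragmentation(g, "F") == 1.0
        assert fragmentation(g, "DF") == 1.0

    def test_complete_graph_scores_zero(self):
        g = complete(5)
        assert fragmentation(g, "F") == 0.0
        assert fragmentation(g, "DF") == 0.0

    def test_two_components_hand_value(self):
        # {1 node} + {2 nodes}: F = 1 - 2/6 = 2/3
        g = build_graph([("c", "d")], isolated_nodes=["a"])
        assert fragmentation(g, "F") == pytest.approx(2 / 3)

    def test_single_node_rejected(self):
        with pytest.raises(GraphError, match="at least 2"):
            fragmentation(build_graph([], isolated_nodes=["a"]), "F")

    @pytest.mark.parametrize("seed", range(15))
    def test_f_zero_iff_connected_df_zero_iff_complete(self, seed):
        g = random_graph(seed)
        is_connected = len(g.connected_components()) == 1
        is_complete = g.n_edges == g.n * (g.n - 1) // 2
        assert (fragmentation(g, "F") == 0) == is_connected
        assert (fragmentation(g, "DF") == 0) == is_complete

    @pytest.mark.parametrize("seed", range(10))
    def test_adding_an_edge_never_increases_df(self, seed):
        g = random_graph(seed, n=9, p=0.3)
        missing = [(u, v) for u, v in itertools.combinations(g.nodes, 2)
                   if not g.has_edge(u, v)]
        if not missing:
            pytest.skip("graph already complete")
        u, v = random.Random(seed).choice(missing)
        denser = build_graph(g.edges + [(u, v)], isolated_nodes=g.nodes)
        assert fragmentation(denser, "DF") <= fragmentation(g, "DF") + 1e-12


class TestKpNeg:
    def test_path_minus_middle(self):
        g = build_graph([("a", "b"), ("b", "c"), ("c", "d")])
        score = kp_neg(g, ["b"], "F")
        # remaining components {a}, {c,d}: F = 1 - 2/6
        assert score.value == pytest.approx(2 / 3)
        assert score.baseline == 0.0

    def test_triangle_minus_one_node_df_zero(self):
        g = build_graph([("a", "b"), ("b", "c"), ("a", "c")])
        assert kp_neg(g, ["a"], "DF").value == 0.0

    def test_whole_node_set_rejected(self):
        g = build_graph([("a", "b"), ("b", "c")])
        with pytest.raises(GraphError, match="at least 2"):
            kp_neg(g, ["a", "b"], "DF")

    @pytest.mark.parametrize("seed", range(10))
    def test_enlarging_the_group_never_raises_pair_connectivity(self, seed):
        """Removing more nodes can only shrink the connected-pair count.

        The normalized F itself is not monotone (its denominator shrinks
        with every removed node), so the invariant is stated on the raw
        count of ordered connected pairs sum s_k (s_k - 1).
        """
        g = random_graph(seed, n=10, p=0.35)
        rng = random.Random(seed)
        nodes = list(g.nodes)
        small = rng.sample(nodes, 2)
        big = small + rng.sample([v for v in nodes if v not in small], 2)

        def pair_connectivity(group):
            comps = g.remove_nodes(group).connected_components()
            return sum(len(c) * (len(c) - 1) for c in comps)

        assert pair_connectivity(big) <= pair_connectivity(small)


class TestReach:
    def test_star_center_dr(self):
        g = build_graph([("c", f"l{i}") for i in range(7)])
        assert dR(g, ["c"]) == pytest.approx(7 / 8)

    def test_mreach_zero_hops_reaches_nothing(self):
        g = build_graph([("a", "b"), ("b", "c")])
        count, pct = m_reach(g, ["b"], 0)
        assert count == 0
        assert pct == pytest.approx(100 / 3)

    def test_negative_m_rejected(self):
        g = build_graph([("a", "b")])
        with pytest.raises(GraphError, match="non-negative"):
            m_reach(g, ["a"], -1)

    def test_disconnected_outside_node_contributes_zero(self):
        g = build_graph([("a", "b")], isolated_nodes=["z"])
        assert dR(g, ["a"]) == pytest.approx(1 / 3)

    @pytest.mark.parametrize("seed", range(12))
    def test_brute_force_oracle_equivalence(self, seed):
        """dR and m-reach agree with direct enumeration over BFS distances."""
        g = random_graph(seed, n=9)
        gnx = to_networkx(g)
        rng = random.Random(seed)
        group = rng.sample(list(g.nodes), 3)
        sp = {v: nx.single_source_shortest_path_length(gnx, v) for v in group}
        outside = [v for v in g.nodes if v not in group]
        expected_dr = sum(
            1.0 / min(sp[u][v] for u in group if v in sp[u])
            for v in outside if any(v in sp[u] for u in group)
        ) / g.n
        assert dR(g, group) == pytest.approx(expected_dr)
        for m in (1, 2, 3):
            expected = sum(
                1 for v in outside
                if any(v in sp[u] and sp[u][v] <= m for u in group))
            assert m_reach(g, group, m)[0] == expected

    @pytest.mark.parametrize("seed", range(10))
    def test_enlarging_the_group_never_shrinks_coverage(self, seed):
        """Group distances and m-hop coverage are monotone in the group.

        The normalized DR and the bare outside count are not monotone
        (members leave the outside set), but every group-to-node distance
        can only shrink, and the covered set (reached nodes plus the group
        itself) can only grow.
        """
        g = random_graph(seed, n=10, p=0.3)
        rng = random.Random(seed)
        nodes = list(g.nodes)
        small = rng.sample(nodes, 2)
        big = small + rng.sample([v for v in nodes if v not in small], 2)
        dm = g.shortest_path_matrix()

        def dist_or_inf(group, v):
            d = dm.group_distance(group, v)
            return float("inf") if d is UNREACHABLE else d

        for v in nodes:
            if v in big:
                continue
            assert dist_or_inf(big, v) <= dist_or_inf(small, v)
        for m in (1, 2):
            assert (m_reach(g, big, m)[0] + len(big)
                    >= m_reach(g, small, m)[0] + len(small))

    def test_kp_pos_wrapper_roundtrip(self):
        g = build_graph([("a", "b"), ("b", "c")])
        assert kp_pos(g, ["b"], "DR").value == pytest.approx(dR(g, ["b"]))
        s = kp_pos(g, ["b"], "MREACH", m=1)
        assert s.count == 2 and s.value == pytest.approx(100.0)
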
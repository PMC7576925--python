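"""Low-level numpy kernels shared by the metric and search layers.

Everything here works on a boolean adjacency matrix over contiguous node
indices; translation to and from node labels happens in :mod:`keyplayers.graph`.
Distances use the internal integer ``INF`` marker, which is never exposed to
callers (the public layer converts it to the :data:`keyplayers.graph.UNREACHABLE`
sentinel).
"""

from __future__ import annotations

import numpy as np

#: Internal marker for "no path"; strictly an implementation detail.
INF = np.iinfo(np.int64).max // 4


def bfs_from_sources(adj: np.ndarray, sources: np.ndarray) -> np.ndarray:
    """Hop distances from each source row to every node (vectorized BFS).

    Runs one synchronized breadth-first sweep for all requested sources at
    once: the frontier is a (s, n) boolean matrix and each step is a single
    boolean matrix product.
    """
    n = adj.shape[0]
    s = len(sources)
    dist = np.full((s, n), INF, dtype=np.int64)
    reached = np.zeros((s, n), dtype=bool)
    reached[np.arange(s), sources] = True
    frontier = reached.copy()
    dist[np.arange(s), sources] = 0
    d = 0
    while frontier.any():
        d += 1
        new = (frontier @ adj) & ~reached
        if not new.any():
            break
        dist[new] = d
        reached |= new
        frontier = new
    return dist


def all_pairs_distances(adj: np.ndarray, workers: int = 1) -> np.ndarray:
    """All-pairs hop distances.

    Work is partitioned by source node into ``workers`` contiguous blocks;
    each block is solved independently and the rows are reassembled in source
    order, so the result is identical for any worker count.  With a single
    worker the partition step is skipped entirely.
    """
    n = adj.shape[0]
    if n == 0:
        return np.zeros((0, 0), dtype=np.int64)
    sources = np.arange(n)
    if workers <= 1:
        return bfs_from_sources(adj, sources)
    blocks = np.array_split(sources, min(workers, n))
    return np.vstack([bfs_from_sources(adj, b) for b in blocks])


def shortest_path_counts(adj: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Number of shortest paths between every ordered pair.

    Layered accumulation over the distance matrix: counts at BFS layer l are
    the counts at layer l-1 pushed across one adjacency step.
    """
    n = adj.shape[0]
    if n == 0:
        return np.zeros((0, 0))
    af = adj.astype(np.float64)
    counts = np.eye(n)
    finite = dist[dist < INF]
    maxd = int(finite.max()) if finite.size else 0
    for layer in range(1, maxd + 1):
        prev = counts * (dist == layer - 1)
        counts = counts + (prev @ af) * (dist == layer)
    return counts


def component_labels(adj: np.ndarray) -> np.ndarray:
    """Connected-component id per node (ids ordered by smallest member)."""
    n = adj.shape[0]
    labels = np.full(n, -1, dtype=np.int64)
    nxt = 0
    for start in range(n):
        if labels[start] >= 0:
            continue
        comp = np.zeros(n, dtype=bool)
        comp[start] = True
        frontier = comp.copy()
        while frontier.any():
            new = (frontier @ adj) & ~comp
            comp |= new
            frontier = new
        labels[comp] = nxt
        nxt += 1
    return labels


def submatrix_without(adj: np.ndarray, removed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Adjacency restricted to nodes outside ``removed`` plus the kept index."""
    keep = np.ones(adj.shape[0], dtype=bool)
    keep[removed] = False
    kept = np.where(keep)[0]
    return adj[np.ix_(kept, kept)], kept


# ---------------------------------------------------------------------------
# fragmentation metrics on an adjacency matrix (already post-removal)

def fragmentation_f(adj: np.ndarray) -> float:
    """Component-size fragmentation: 1 - sum s_k (s_k - 1) / (n (n-1))."""
    n = adj.shape[0]
    if n < 2:
        raise ValueError("fragmentation requires at least 2 nodes")
    labels = component_labels(adj)
    _, sizes = np.unique(labels, return_counts=True)
    return 1.0 - float((sizes * (sizes - 1)).sum()) / (n * (n - 1))


def fragmentation_df(adj: np.ndarray, dist: np.ndarray | None = None) -> float:
    """Distance-weighted fragmentation: 1 - 2 sum_{i>j} (1/d_ij) / (n (n-1)).

    Unreachable pairs contribute 0, so an edgeless graph scores exactly 1.
    """
    n = adj.shape[0]
    if n < 2:
        raise ValueError("fragmentation requires at least 2 nodes")
    if dist is None:
        dist = all_pairs_distances(adj)
    iu = np.triu_indices(n, 1)
    d = dist[iu]
    inv = np.where(d < INF, 1.0 / np.maximum(d, 1), 0.0)
    return 1.0 - 2.0 * float(inv.sum()) / (n * (n - 1))


# ---------------------------------------------------------------------------
# group metrics on the intact graph

def group_min_dist(dist: np.ndarray, group: np.ndarray) -> np.ndarray:
    """Minimum distance from any group member to every node."""
    return dist[group].min(axis=0)


def reach_dr(dist: np.ndarray, group: np.ndarray) -> float:
    """Distance-weighted reach: sum over outside nodes of 1/d_Kj, over n."""
    n = dist.shape[0]
    dmin = group_min_dist(dist, group)
    out = np.ones(n, dtype=bool)
    out[group] = False
    d = dmin[out]
    inv = np.where(d < INF, 1.0 / np.maximum(d, 1), 0.0)
    return float(inv.sum()) / n


def mreach_count(dist: np.ndarray, group: np.ndarray, m: int) -> int:
    """Outside nodes within m hops of any group member."""
    if m < 0:
        raise ValueError("m must be non-negative")
    n = dist.shape[0]
    dmin = group_min_dist(dist, group)
    out = np.ones(n, dtype=bool)
    out[group] = False
    return int((dmin[out] <= m).sum())


def group_degree(adj: np.ndarray, group: np.ndarray) -> float:
    """Fraction of outside nodes adjacent to at least one group member."""
    n = adj.shape[0]
    k = len(group)
    if n - k < 1:
        raise ValueError("group degree needs at least one outside node")
    nbr = adj[group].any(axis=0)
    nbr[group] = False
    return float(nbr.sum()) / (n - k)


def group_agg_dist(dist: np.ndarray, group: np.ndarray, method: str) -> np.ndarray:
    """Min / max / mean distance from the group to every node.

    Max and mean are computed over reachable members only; a node reachable
    from no member is reported as INF.
    """
    sub = dist[group].astype(np.float64)
    finite = sub < INF
    if method == "min":
        return dist[group].min(axis=0).astype(np.float64)
    if method == "max":
        masked = np.where(finite, sub, -np.inf)
        agg = masked.max(axis=0)
        return np.where(np.isneginf(agg), float(INF), agg)
    if method == "mean":
        cnt = finite.sum(axis=0)
        s = np.where(finite, sub, 0.0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            agg = np.where(cnt > 0, s / np.maximum(cnt, 1), float(INF))
        return agg
    raise ValueError(f"unknown closeness method: {method!r}")


def group_closeness(
    dist: np.ndarray, group: np.ndarray, method: str = "min", strict: bool = True
) -> float:
    """Reciprocal mean group-to-outside distance: (n-k) / sum_j dbar_Kj."""
    n = dist.shape[0]
    k = len(group)
    if n - k < 1:
        raise ValueError("group closeness needs at least one outside node")
    agg = group_agg_dist(dist, group, method)
    out = np.ones(n, dtype=bool)
    out[group] = False
    d = agg[out]
    if (d >= INF).any():
        if strict:
            raise ValueError("some outside node is unreachable from the group")
        return 0.0
    return (n - k) / float(d.sum())


def group_betweenness(
    adj: np.ndarray,
    dist: np.ndarray,
    counts: np.ndarray,
    group: np.ndarray,
) -> float:
    """Mean over outside pairs of the fraction of shortest paths through K.

    A u-v shortest path "passes through" the group when at least one interior
    vertex belongs to it; the fraction for a pair is therefore
    1 - sigma_uv(G - K) / sigma_uv(G) when removing the group preserves the
    u-v distance, and 1 when it does not.  The per-pair fractions are summed
    over unordered outside pairs and normalized by the ordered pair count
    (n-k)(n-k-1), so a group sitting on every outside shortest path scores
    0.5, not 1.  Outside pairs that are already disconnected in the intact
    graph are excluded from both the sum and the normalization.
    """
    n = adj.shape[0]
    if n - len(group) < 2:
        raise ValueError("group betweenness needs at least two outside nodes")
    sub, kept = submatrix_without(adj, group)
    dsub = all_pairs_distances(sub)
    csub = shortest_path_counts(sub, dsub)
    dfull = dist[np.ix_(kept, kept)]
    cfull = counts[np.ix_(kept, kept)]
    iu = np.triu_indices(len(kept), 1)
    connected = dfull[iu] < INF
    preserved = dsub[iu] == dfull[iu]
    denom = np.where(cfull[iu] > 0, cfull[iu], 1.0)
    frac_avoiding = np.where(preserved, csub[iu] / denom, 0.0)
    through = (1.0 - frac_avoiding) * connected
    npairs = int(connected.sum())
    if npairs == 0:
        return 0.0
    return float(through.sum()) / (2 * npairs)


def node_betweenness(adj: np.ndarray, dist: np.ndarray, counts: np.ndarray) -> np.ndarray:
    """Normalized node betweenness via pair-dependency accumulation.

    For every node v, sums sigma_uv * sigma_vw / sigma_uw over pairs (u, w)
    with d(u,v) + d(v,w) = d(u,w); normalized by the ordered count of
    connected pairs excluding v, to match the group definition at k = 1.
    """
    n = adj.shape[0]
    out = np.zeros(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        for v in range(n):
            on_path = (dist[:, v][:, None] + dist[v, None, :]) == dist
            valid = on_path & (dist < INF)
            valid[v, :] = False
            valid[:, v] = False
            np.fill_diagonal(valid, False)
            ratio = (counts[:, v][:, None] * counts[v, None, :]) / np.where(
                counts > 0, counts, 1.0
            )
            total = float((ratio * valid).sum()) / 2.0
            mask = np.ones(n, dtype=bool)
            mask[v] = False
            # ordered connected pairs among V \ {v}: drop the diagonal
            connected_pairs = int((dist[np.ix_(mask, mask)] < INF).sum()) - (n - 1)
            out[v] = total / connected_pairs if connected_pairs else 0.0
    return out
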
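"""Optimal-group discovery: greedy swap heuristic and exhaustive search.

The exhaustive search enumerates every k-subset in lexicographic label
order, optionally split across worker processes.  The combination space is
partitioned statically into contiguous blocks and the per-block maxima are
merged at the end, so the result is identical for any worker count.

The greedy heuristic hill-climbs from a random starting group, repeatedly
applying the best strictly-improving single swap between a member and an
outside node; it stops at the first local optimum.  It is cheap but offers
no optimality guarantee, hence the optional random restarts.
"""

from __future__ import annotations

import math
import itertools
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from datetime import datetime, timezone
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from . import _core
from .graph import Graph, GraphError, as_members

KPNEG_METRICS = ("F", "DF")
KPPOS_METRICS = ("DR", "MREACH")
GROUP_METRICS = ("GD", "GB", "GC")
ALL_METRICS = KPNEG_METRICS + KPPOS_METRICS + GROUP_METRICS

#: Hard cap on exhaustive enumeration size.
DEFAULT_BUDGET = 5_000_000

_CHUNK = 2048


@dataclass(frozen=True)
class SearchResult:
    metric: str
    k: int
    best_groups: tuple[tuple[str, ...], ...]
    best_score: float
    algorithm: str
    parameters: dict = field(default_factory=dict)
    seed: Optional[int] = None
    evaluations: int = 0
    timestamp: str = ""


class _Evaluator:
    """Scores index-groups on a fixed graph; precomputes what it can."""

    def __init__(self, g: Graph, metric: str, m: int = 2,
                 closeness_method: str = "min"):
        metric = metric.upper()
        if metric not in ALL_METRICS:
            raise GraphError(f"unknown metric {metric!r}; choose from {ALL_METRICS}")
        self.metric = metric
        self.m = m
        self.closeness_method = closeness_method
        self.adj = g.adjacency
        self.n = g.n
        self.dist = g.shortest_path_matrix().values
        self.counts = (_core.shortest_path_counts(self.adj, self.dist)
                       if metric == "GB" else None)

    # vectorized evaluation over a (c, k) index array where possible
    def score_chunk(self, combos: np.ndarray) -> np.ndarray:
        metric = self.metric
        if metric in ("DR", "MREACH", "GD") or (
                metric == "GC" and self.closeness_method == "min"):
            c, k = combos.shape
            rows = np.arange(c)[:, None]
            if metric == "GD":
                nbr = self.adj[combos].any(axis=1)
                nbr[rows, combos] = False
                return nbr.sum(axis=1) / (self.n - k)
            dmin = self.dist[combos].min(axis=1).astype(np.float64)
            dmin[rows, combos] = -1.0  # mark group positions
            outside = dmin >= 0
            unreachable = outside & (dmin >= _core.INF)
            if metric == "DR":
                inv = np.where(outside & ~unreachable,
                               1.0 / np.maximum(dmin, 1.0), 0.0)
                return inv.sum(axis=1) / self.n
            if metric == "MREACH":
                return (outside & (dmin <= self.m)).sum(axis=1).astype(np.float64)
            # GC min-method: 0 whenever some outside node is unreachable
            s = np.where(outside & ~unreachable, dmin, 0.0).sum(axis=1)
            bad = unreachable.any(axis=1) | (s <= 0)
            return np.where(bad, 0.0, (self.n - k) / np.maximum(s, 1.0))
        return np.array([self.score_one(c) for c in combos], dtype=np.float64)

    def score_one(self, group_idx: np.ndarray) -> float:
        metric = self.metric
        group_idx = np.asarray(group_idx, dtype=np.int64)
        if metric == "GB":
            return _core.group_betweenness(self.adj, self.dist, self.counts, group_idx)
        if metric in ("F", "DF"):
            sub, _ = _core.submatrix_without(self.adj, group_idx)
            if metric == "F":
                return _core.fragmentation_f(sub)
            return _core.fragmentation_df(sub)
        if metric == "GC":
            try:
                return _core.group_closeness(self.dist, group_idx,
                                             self.closeness_method, strict=True)
            except ValueError:
                return 0.0
        return float(self.score_chunk(group_idx[None, :])[0])


def _validate_k(g: Graph, k: int, metric: str) -> None:
    if not 1 <= k < g.n:
        raise GraphError(f"group size k={k} must satisfy 1 <= k < n={g.n}")
    if metric.upper() in KPNEG_METRICS and g.n - k < 2:
        raise GraphError("fragmentation search must leave at least 2 nodes")
    if metric.upper() == "GB" and g.n - k < 2:
        raise GraphError("betweenness search needs two outside nodes")


def _timestamp() -> str:
    return datetime.now(timezone.utc).isoformat(timespec="seconds")


def _combo_block(n: int, k: int, start: int, stop: int):
    """Combinations with indices in [start, stop) of lexicographic order."""
    it = itertools.combinations(range(n), k)
    return itertools.islice(it, start, stop)


def _scan_block(args):
    """Find the block-local maxima; used both serially and in workers."""
    (adj, dist, counts, metric, m, cmethod, n, k, start, stop) = args
    ev = _Evaluator.__new__(_Evaluator)
    ev.metric, ev.m, ev.closeness_method = metric, m, cmethod
    ev.adj, ev.dist, ev.counts, ev.n = adj, dist, counts, n
    best = -math.inf
    arg: list[tuple[int, ...]] = []
    block = _combo_block(n, k, start, stop)
    while True:
        chunk = np.array(list(itertools.islice(block, _CHUNK)), dtype=np.int64)
        if chunk.size == 0:
            break
        scores = ev.score_chunk(chunk)
        mx = float(scores.max())
        if mx > best + 1e-12:
            best = mx
            arg = [tuple(c) for c in chunk[scores >= mx - 1e-12]]
        elif mx >= best - 1e-12:
            arg.extend(tuple(c) for c in chunk[scores >= best - 1e-12])
    return best, arg


def bruteforce_search(
    g: Graph,
    k: int,
    metric: str,
    workers: int = 1,
    m: int = 2,
    closeness_method: str = "min",
    budget: int | None = None,
) -> SearchResult:
    """Evaluate every k-subset and return all groups tied at the maximum."""
    metric = metric.upper()
    _validate_k(g, k, metric)
    if budget is None:
        budget = DEFAULT_BUDGET
    total = math.comb(g.n, k)
    if total > budget:
        raise GraphError(
            f"C({g.n},{k}) = {total} exceeds the enumeration budget {budget}")
    ev = _Evaluator(g, metric, m=m, closeness_method=closeness_method)
    workers = max(1, int(workers))
    bounds = np.linspace(0, total, workers + 1).astype(int)
    blocks = [(ev.adj, ev.dist, ev.counts, ev.metric, ev.m,
               ev.closeness_method, g.n, k, int(a), int(b))
              for a, b in zip(bounds[:-1], bounds[1:]) if b > a]
    if workers == 1:
        results = [_scan_block(b) for b in blocks]
    else:
        with ProcessPoolExecutor(max_workers=workers) as pool:
            results = list(pool.map(_scan_block, blocks))
    best = max(r[0] for r in results)
    arg = sorted({c for b, cands in results if b >= best - 1e-12
                  for c in cands})
    labels = g.nodes
    groups = tuple(tuple(labels[i] for i in c) for c in arg)
    if metric == "MREACH":
        best = 100.0 * (best + k) / g.n
    params = {"m": m} if metric == "MREACH" else {}
    if metric == "GC":
        params["closeness_method"] = closeness_method
    return SearchResult(metric=metric, k=k, best_groups=groups,
                        best_score=float(best), algorithm="bruteforce",
                        parameters={**params, "workers": workers},
                        evaluations=total, timestamp=_timestamp())


def greedy_search(
    g: Graph,
    k: int,
    metric: str,
    seed: int = 0,
    max_iterations: int = 100,
    restarts: int = 1,
    m: int = 2,
    closeness_method: str = "min",
) -> SearchResult:
    """Hill-climb over single member/outsider swaps from a random start.

    Each round evaluates every (member, outsider) swap in lexicographic
    order and applies the single best strictly improving one; the climb
    stops at the first local optimum or after ``max_iterations`` rounds.
    Deterministic for a given seed.
    """
    metric = metric.upper()
    _validate_k(g, k, metric)
    ev = _Evaluator(g, metric, m=m, closeness_method=closeness_method)
    rng = np.random.default_rng(seed)
    n = g.n
    evaluations = 0
    best_score = -math.inf
    best_groups: set[tuple[int, ...]] = set()
    for _ in range(max(1, restarts)):
        current = np.sort(rng.choice(n, size=k, replace=False))
        score = ev.score_one(current)
        evaluations += 1
        for _round in range(max_iterations):
            members = sorted(current.tolist())
            outside = [v for v in range(n) if v not in set(members)]
            swap_best = score
            swap = None
            for u in members:
                for v in outside:
                    cand = np.sort(np.array(
                        [x for x in members if x != u] + [v], dtype=np.int64))
                    s = ev.score_one(cand)
                    evaluations += 1
                    if s > swap_best + 1e-12:
                        swap_best = s
                        swap = cand
            if swap is None:
                break
            current, score = swap, swap_best
        key = tuple(int(x) for x in np.sort(current))
        if score > best_score + 1e-12:
            best_score, best_groups = score, {key}
        elif score >= best_score - 1e-12:
            best_groups.add(key)
    labels = g.nodes
    groups = tuple(tuple(labels[i] for i in c) for c in sorted(best_groups))
    if metric == "MREACH":
        best_score = 100.0 * (best_score + k) / g.n
    params = {"m": m} if metric == "MREACH" else {}
    if metric == "GC":
        params["closeness_method"] = closeness_method
    return SearchResult(metric=metric, k=k, best_groups=groups,
                        best_score=float(best_score), algorithm="greedy",
                        parameters={**params, "restarts": restarts,
                                    "max_iterations": max_iterations},
                        seed=seed, evaluations=evaluations,
                        timestamp=_timestamp())


# ---------------------------------------------------------------------------
# nestedness of best sets across sizes

@dataclass(frozen=True)
class NestednessReport:
    sets_by_size: dict
    pair_overlaps: tuple
    nrow: float
    overlap_edges: tuple


def nestedness_nrow(sets_by_size: Mapping[int, Sequence[Iterable[str]]]) -> NestednessReport:
    """Average containment of smaller best sets inside larger ones.

    For every pair (S, L) of reported sets with |S| < |L| (all combinations
    when several sets tie at a size), the overlap ratio is |S & L| / |S|;
    ``nrow`` is the plain mean of all these ratios.  ``overlap_edges`` lists
    the pairs with a non-empty overlap, ratio attached, for plotting.
    """
    cleaned: dict[int, list[tuple[str, ...]]] = {}
    for size, groups in sets_by_size.items():
        entries = [tuple(as_members(grp)) for grp in groups]
        for e in entries:
            if len(e) != size:
                raise GraphError(f"group {e} does not have declared size {size}")
        cleaned[int(size)] = entries
    sizes = sorted(cleaned)
    if len(sizes) < 2:
        raise GraphError("nestedness needs at least two distinct set sizes")
    overlaps = []
    edges = []
    for a, b in itertools.combinations(sizes, 2):
        for small in cleaned[a]:
            for large in cleaned[b]:
                ratio = len(set(small) & set(large)) / len(small)
                overlaps.append(((a, small), (b, large), ratio))
                if ratio > 0:
                    edges.append(((a, small), (b, large), ratio))
    nrow = sum(o[2] for o in overlaps) / len(overlaps)
    return NestednessReport(
        sets_by_size={s: tuple(v) for s, v in cleaned.items()},
        pair_overlaps=tuple(overlaps),
        nrow=float(nrow),
        overlap_edges=tuple(edges),
    )
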
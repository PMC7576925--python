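# Methods

## Graph model

Graphs are simple, undirected, and unweighted, with non-empty string labels
as node identity. Self-loops are rejected by default (or dropped with a
warning in lenient mode) and duplicate/multi-edges collapse with a logged
warning. Graph objects are immutable; node removal and set operations
return new graphs. Internally each graph keeps a boolean adjacency matrix
over contiguous indices in sorted-label order; that indexing never reaches
the public API.

All-pairs distances are BFS hop counts computed as a synchronized layered
sweep (the frontier of every source advances via one boolean matrix product
per level). Disconnected pairs are reported as a distinct `UNREACHABLE`
sentinel, never as a large finite number; every reciprocal-distance metric
treats them as 1/d = 0. The matrix computation can be partitioned by source
node into contiguous blocks ("workers") and reassembled in order, which
makes the result bit-identical for any worker count — the same contract the
exhaustive search uses.

## Metrics

Let n = |V|, k = |K|, and d_Kj = min over members i of K of d_ij.

* Fragmentation F and DF are evaluated on the residual graph after removing
  K (with n then the residual node count), and the intact-graph value is
  reported alongside as the baseline. F counts ordered connected pairs via
  component sizes; DF weights every pair by 1/d. DF = 1 exactly when no
  edges survive; F = 0 iff the graph is connected, DF = 0 iff complete.
  Neither normalized score is monotone in K (the denominator shrinks as
  nodes are removed), which is why the property tests assert monotonicity
  of the underlying raw quantities instead: the ordered connected-pair
  count for F, and group distances / m-hop coverage for the reach metrics.
* DR sums 1/d_Kj over outside nodes and divides by n, so its ceiling at
  group size k is (n−k)/n, attained exactly when K dominates the graph.
* m-reach counts outside nodes with d_Kj ≤ m (m ≥ 0); the conventional
  percentage includes the group: 100·(count + k)/n.
* Group degree: distinct outside neighbors of K over (n−k); ties from
  several members to the same node count once.
* Group betweenness: for every unordered pair of outside nodes, the
  fraction of their shortest paths with at least one interior vertex in K —
  computed without path enumeration as 1 − σ'_uv/σ_uv, where σ is the
  shortest-path count in G and σ' the count in G − K when the distance is
  preserved (0 paths otherwise). The pair fractions are summed and divided
  by the ordered outside-pair count (n−k)(n−k−1). This ordered-pair
  normalization, under which a group sitting on every outside geodesic
  scores 0.5 rather than 1, is the convention that reproduces the reference
  values on the packaged example network; the node betweenness exposed by
  the package uses the same convention so that the k = 1 equivalence with
  group betweenness is exact (it equals one half of the networkx-normalized
  value). Outside pairs disconnected in the intact graph are excluded from
  both the sum and the normalization.
* Group closeness: (n−k) / Σ_j d̄_Kj, where d̄_Kj aggregates the member
  distances to j by min (default), max, or mean; higher = more central,
  with 1 attained by a dominating group. An outside node unreachable from
  every member is an error under the default strict mode and defines the
  score as 0 otherwise (searches use the lenient form).

Disconnected inputs are legal for every metric except strict group
closeness, consistently via the 1/d = 0 convention.

## Search

The exhaustive search enumerates all C(n,k) groups in lexicographic label
order, evaluates each, and returns every group tied at the maximum
(tolerance 1e−12). The enumeration range is split into contiguous blocks,
one per worker; block maxima are merged, so the answer is independent of
the worker count; blocks run in a process pool when workers > 1. A budget
(default 5·10⁶ evaluations) guards against accidental combinatorial
explosions. Degree-, reach-, and min-closeness-style metrics are evaluated
in vectorized chunks of 2048 groups; betweenness and fragmentation run one
group at a time on submatrices.

The greedy heuristic draws k distinct nodes uniformly (numpy PCG64, caller
seed), then repeatedly evaluates all k·(n−k) single swaps between a member
and an outsider in lexicographic order, applying the best strictly
improving one; it stops at the first local optimum or after
`max_iterations` (default 100) rounds. Equal-score swaps are not taken
(no plateau walks), which guarantees termination and determinism for a
given seed. Because a single start is easily trapped, `restarts`
(default 3 in the CLI) reruns the climb from fresh random starts and
returns the best groups found; the score can never exceed the exhaustive
optimum, and the test suite checks exactly that on random graphs.

For the fragmentation metrics the search maximizes post-removal
fragmentation; for all others it maximizes the score itself.

Nestedness (Nrow): given best sets per size, every pair (S, L) with
|S| < |L| — all combinations when sizes tie — contributes the ratio
|S∩L|/|S|; Nrow is the plain mean of these ratios, and pairs with a
non-empty overlap are also emitted as labelled edges for plotting.

## Set operations

Union (V1∪V2, E1∪E2), intersection (V1∩V2, E1∩E2), and difference
(V1∖V2 with surviving edges only). The plain set-difference of edges can
leave an edge with a removed endpoint, so the difference additionally drops
any edge that lost an endpoint — the invariant "every output edge has both
endpoints in the output" holds for all three operations. Difference is
intentionally not symmetric. Attribute handling: union keeps the first
operand's value on conflict (logged), intersection keeps only values both
operands agree on, difference keeps the first operand's annotations.

## File formats

SIF (tab- or space-separated; interaction type preserved as an edge
attribute, ignored topologically; a lone token declares an isolated node;
multi-target lines fan out), edge list (two tokens per line, `#` comments;
a single token is tolerated so isolated nodes survive a round-trip),
adjacency matrix (0/1, symmetric, zero diagonal, header optional via an
explicit flag — never auto-guessed), an undirected subset of dot
(`graph { a -- b; }`; `digraph` rejected), and a versioned binary pickle
container for which no cross-language durability is claimed. Round-trip
identity of node and edge sets holds for every format and is
property-tested, including graphs with isolated nodes.

## Random graphs

Erdős–Rényi G(n, p) draws each of the C(n,2) edges independently with
probability p from a seeded numpy generator; the tests check the exact
p = 0 and p = 1 cases, the mean edge count of G(100, 0.3) over 200 seeds
against binomial moments, and a chi-squared fit of the pooled degree
distribution to Binomial(n−1, p). Scale-free (Barabási–Albert) and
small-world (Watts–Strogatz) generation delegate to networkx and are
re-labelled to this package's string convention.

## The example network

The packaged 24-node, 24-edge network used throughout the documentation and
tests is a synthetic reconstruction: the network it emulates is published
only as a drawing, so the edge list was rebuilt by constraint search
(structured enumeration over the adjacency signatures that the documented
facts force, plus simulated annealing as a cross-check) until every stated
fact held simultaneously — hub degrees 7/6/5/4 for nodes 2/9/16/21 with a
clean ranking, 9 adjacent to 16 and 21, d(2,9) = 5, node 21 first and node
9 second by betweenness, all twelve group-centrality and twelve key-player
reference values (m-reach fractions exactly), the uniqueness of {2,9} as
the best pair for F/DF/DR/GD/GB/GC, {5,9} as the unique best m-reach pair
covering all 22 outside nodes within two hops, the exact pair of size-5
optima {2,9,10,16,21} / {2,9,11,16,21} for degree, closeness, and DR
(19/24), the unique size-5 betweenness optimum (0.497), and total
fragmentation (DF = 1) on removing {2,9,11,14,16,21}. Within the space of
graphs consistent with all of those facts, exactly two labelings exist,
isomorphic up to swapping the roles of nodes 14 and 17; the one with 14
adjacent to hub 9 is canonical here. One known tie is documented in the
fixture: {2,9,11,16,17,21} also fragments the network completely, which no
graph consistent with the other facts can avoid; the exhaustive-search
tests therefore assert that the canonical six-node set attains DF = 1, not
that it is unique. `validate_fixture()` re-checks the full fact list and
runs on every build.

## Numerical choices and limitations

* Score ties in searches use an absolute tolerance of 1e−12; reference
  values on the example network are asserted at ±0.005 (two printed
  decimals), m-reach percentages exactly, and the size-5 betweenness
  optimum at ±0.0005.
* Betweenness path counts are floating-point; counts are exact integers up
  to 2⁵³, far beyond any graph this package should see.
* The acceptance script and the heavier tests run exhaustive searches up to
  C(24,6) ≈ 1.3·10⁵ groups, a few seconds each on one CPU; the brute-force
  budget errors out long before memory becomes a concern.
* Synthetic graphs here (Erdős–Rényi and the reconstructed example network)
  are small and unweighted with clean hub structure; passing tests on them
  validates the metric and search implementations, not the biological
  interpretation of key players in any particular real network, and says
  nothing about weighted or directed behavior, which the data model
  deliberately excludes.
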
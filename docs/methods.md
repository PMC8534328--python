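# Methods

## Model

Graph entropy (GE) treats each node as a categorical random variable over
the parts of a division of the graph: if a fraction p(xᵢ) of a node's edges
end in part Cᵢ, the node's entropy is −Σᵢ p(xᵢ) log₂ p(xᵢ) and GE is the sum
over all nodes. GE is zero exactly when every node's edges are confined to
one part, and grows as nodes straddle boundaries, so minimizing GE favors
divisions whose boundaries cut few of any single node's edges. For
seed-growth clustering the division is binary — the seed cluster versus the
rest — and each node contributes the binary entropy of its inside-edge
fraction. Two facts shape the implementation:

* a node's entropy depends only on where the *far* endpoints of its edges
  lie, not on its own membership, so moving one node across the boundary
  changes only its neighbors' entropies;
* nodes with all edges on one side contribute zero, so only the cluster's
  boundary region carries entropy.

The weighted variants replace (GE-WR) or scale (GE-MW) the edge-count ratios
with the inside/outside sums of incident edge weights. GE-WR is bounded by
1 bit per node and collapses to the unweighted entropy under any constant
weighting (the ratios cancel the constant); it is the variant of choice for
weighted networks. GE-MW multiplies each entropy term by its weight mass and
is therefore not normalized — a heavy node can contribute far more than
1 bit — so it is retained as an experimental mode and exercised by the tests
but not recommended as a default.

## Algorithm and its guarantees

Each iteration seeds at the highest-degree uncovered node, initializes the
cluster as the closed neighborhood, makes one pruning pass over the seed's
neighbors (descending degree), then grows to a fixpoint by sweeping the
cluster's outside neighbors (descending degree), accepting a move only if it
strictly decreases GE. Consequences:

* **Termination.** Every emitted cluster contains its seed, and all members
  (including singleton results) are marked covered, so at most N iterations
  occur. Growth performs at most |V| sweeps, each accepting ≥ 1 move or
  terminating.
* **Monotonicity.** GE never increases within a seed's prune+growth phases.
* **Local optimality at termination is one-sided.** The growth fixpoint
  guarantees no single *addition* can strictly lower GE. No such guarantee
  holds for removals: pruning is a single pass over the seed's original
  neighbors executed *before* growth, and later additions can make a
  removal profitable again. This asymmetry is inherent to the 6-step
  procedure, and the tests assert only the addition side.
* **Overlap.** Only the seed must be uncovered; covered nodes re-enter later
  clusters through initialization or growth. Note that overlap requires a
  genuine tie or gain at the shared node: on two K5s sharing one node the
  shared node has the highest degree, its closed neighborhood is the whole
  graph, and the union is a single GE-0 cluster — no overlap is produced.
  Two larger cliques each attached to a shared hub by a strict subset of
  their members do produce overlap (the hub's removal delta is exactly zero
  from either side, so it stays in both clusters).

## Numerical choices

* Entropy in bits (log base 2). The base is a uniform rescaling of GE and
  cannot change any accept/reject decision; bits make the micro-examples
  (H₂(½) = 1) readable. 0·log 0 := 0 throughout; isolated nodes have
  entropy 0 in every mode.
* A move "decreases GE" iff its delta < −1e-12. The strict margin prevents
  oscillation on exact ties (e.g. a hub symmetric between two cliques) and
  makes tie outcomes deterministic rather than dependent on float noise.
* Incremental deltas are validated against full recomputation to 1e-9 over
  randomized graphs in all modes; the state caches per-node inside/outside
  tallies sparsely, so cost scales with the cluster's boundary rather than
  the graph.
* All orderings (seed choice, prune/growth visiting order, tie-breaks) are
  by (degree descending, node identifier ascending). Degree is the
  unweighted edge count even in weighted modes; weights enter the entropy
  only. Output is byte-stable across runs.
* Duplicate input edges collapse to the maximum weight; STRING combined
  scores map to weights as score/1000; Jaccard weights exclude the edge's
  own endpoints from both neighbor sets, with weight 0 when the union is
  empty.

## Evaluation conventions

Reference members absent from the network are removed from references, then
cluster members absent from the filtered reference universe are removed from
clusters; sets emptied by either rule are dropped from the averages (an
average over an empty set is undefined). F := 0 for disjoint pairs. The
homogeneity threshold (best precision ≥ 0.6) is inclusive; the novel-member
threshold (best F > 0.9) is exclusive, and novel-member scoring deliberately
uses *unfiltered* references, since the members absent from the reference
are the proposal. Overlap statistics are computed on the raw cluster set,
before any reference filtering, because overlap is a property of the
clustering itself. Best-match ties between references are broken by
reference name for deterministic reporting; the averaged scores are
tie-independent.

## Synthetic generators: what they do and do not establish

* **Clique unions** are the exactly recoverable limit: each clique is a
  GE-0 cluster and any deviation strictly raises GE. Green tests here
  establish correctness of the search bookkeeping, not robustness.
* **Planted partitions** (blocks dense at p_in, background at p_out,
  optionally sharing nodes between consecutive blocks) test recovery under
  noise. The benchmark setting — 10 blocks of 20 nodes, p_in = 0.9,
  p_out = 0.01 — gives within-block degree ≈ 17 against ≈ 1.8 background
  edges per node, a strongly assortative regime; recovery there does not
  imply recovery near the detectability limit.
* **Erdős–Rényi G(n, m) nulls** (fixed node and edge counts) check the
  negative control: with no planted structure the pruning stage should
  dissolve nearly every seed neighborhood into singletons. At n = 2000,
  m = 8000 the implementation leaves 0% of nodes in non-singleton clusters.

None of the generators emulate the degree heterogeneity (hubs, scale-free
tails), edge-confidence structure, or ascertainment bias of real PPI data,
so green synthetic tests validate the algorithmic machinery, not biological
performance. The generators use a single numpy `default_rng(seed)` stream
per call and are byte-reproducible per seed.

## Known limitations

* The search is greedy and local; it finds a locally minimal cluster per
  seed, not a global optimum, and offers no approximation guarantee.
* GE-MW can assign unbounded per-node entropy and has no normalization; its
  cluster sizes are not comparable across weight scales.
* Identifier mapping (e.g. Ensembl protein IDs to gene symbols) is out of
  scope: inputs are assumed to already use one consistent, upper-casable
  namespace.
* Very dense graphs make the initial neighborhood nearly the whole graph,
  where the binary split carries little signal (the shared-K5 example
  above is the degenerate extreme).
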
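# gecluster

Overlapping functional-module detection in protein–protein interaction (PPI)
networks by **graph-entropy (GE) seed-growth clustering**, with a full
cluster-vs-reference evaluation framework and synthetic benchmark generators.

## Who this is for

Systems biologists and network scientists who have an undirected PPI network
(for example STRING physical links or BioPlex) and want to predict protein
complexes or functional modules — including modules that *share* proteins,
which partition-based methods cannot produce — and then score the predictions
against reference complexes or GO annotation groups.

## The method

For a graph partitioned into subgraphs C₁…C_k, the entropy of a node *v* is
the Shannon entropy of the distribution of its edges over the subgraphs,

```
e(v) = − Σᵢ p(xᵢ) log₂ p(xᵢ),    p(xᵢ) = (edges from v into Cᵢ) / deg(v),
```

and the graph entropy is e(G) = Σᵥ e(v). Lower GE means higher modularity;
a division with no cross-subgraph edges has GE = 0.

Clustering splits the graph in two — a seed cluster C and the rest — so each
node contributes e(v) = H₂(pᵢ) with pᵢ the fraction of its edges ending
inside C. One cluster is grown per seed:

1. pick the highest-degree uncovered node as seed;
2. initialize C = {seed} ∪ N(seed);
3. **prune**: visit the seed's neighbors once, highest degree first, removing
   each one whose removal strictly decreases GE;
4. **grow**: sweep the cluster's outside neighbors, highest degree first,
   adding each one whose addition strictly decreases GE, until a sweep adds
   nothing;
5. emit the cluster; 6. mark members covered and repeat until no seed remains.

Only the seed must be uncovered, so clusters from different seeds can
overlap. Singletons are excluded from the output. For weighted networks two
node-entropy variants are provided, built from the inside/outside weight
sums Wᵢ, Wₒ of a node's incident edges:

* **GE-MW** (multiplied weights): e(v) = −Wᵢ·pᵢ log₂ pᵢ − Wₒ·pₒ log₂ pₒ
* **GE-WR** (weighted ratios): e(v) = H₂(Wᵢ / (Wᵢ + Wₒ))

GE-WR reduces exactly to the unweighted entropy whenever all weights are
equal. Edge weights can come from STRING confidence scores (score/1000,
"probabilistic") or from the Jaccard index of the endpoints' neighborhoods
("topological").

Evaluation matches each cluster to its best reference by F-score
(F = 2PR/(P+R) with P = |C∩r|/|C|, R = |C∩r|/|r|) and reports the average
best F and precision, the proportion of functionally homogeneous clusters
(best precision ≥ 0.6), overlap statistics, and — against unfiltered
references — novel-member proposals from clusters with best F > 0.9.

## Worked example

```bash
# three disjoint cliques of sizes 5, 6, 4 with the cliques as references
gecluster synth --kind clique-union --sizes 5,6,4 --out-prefix demo
gecluster cluster --input demo.edges.tsv --out-prefix demo
gecluster evaluate --clusters demo.clusters.gmt --references demo.refs.gmt \
    --input demo.edges.tsv --out-prefix demo.report
```

prints

```
kind=clique-union seed=0 nodes=15 edges=31
mode=unweighted weighting=none nodes=15 edges=31 clusters=3 average_cluster_size=5.0
n=3 mean_f=1.000 mean_p=1.000 homogeneity_pct=100.0 overlap=0/3 (0.0%) novel=0
```

— the three cliques are recovered exactly (each at GE 0), so the average
F-score and precision against the planted references are 1.0, all clusters
are functionally homogeneous, and no cluster shares a node with another.
The same workflow applies to a real network, e.g.

```bash
gecluster cluster --input string_physical.txt --dialect string-links \
    --weighting probabilistic --mode ge-wr --score-threshold 700 --out-prefix string_run
```

The library mirrors the CLI: `read_edge_list` / `read_string_links`,
`apply_probabilistic_weights` / `apply_topological_weights`, `run_ge`,
`evaluate`, and the `make_*` synthetic generators are all importable from
`gecluster`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the pipeline from scratch at desk scale — exact clique-union
recovery in all three entropy modes, planted-partition recovery (10 blocks
of 20 nodes, p_in = 0.9, p_out = 0.01) with and without planted overlap and
with topological weighting, and the Erdős–Rényi G(2000, 8000) null where a
modularity-seeking method should leave essentially only singletons — logging
the measured accuracy of each stage and writing the JSON result file.
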
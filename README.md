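# funclust

Functional module detection in predicted protein–protein interaction (PPI)
networks.

Sequence-based interaction predictors can produce a genome-scale, noisy,
confidence-weighted PPI network for organisms with no experimental
interactome — corals, dinoflagellate symbionts, or any other non-model
species. `funclust` turns such a network, plus per-protein GO annotations,
into a small number of size-bounded, functionally coherent protein modules
that a biologist can inspect by hand, and quantifies how much functional and
co-expression signal those modules capture.

## Method

Given a weighted undirected network with confidence scores `w(i,j) ∈ (0,1]`:

1. **Diffusion state distance (DSD).** A random walk is biased along
   high-confidence edges, `P[i,j] = w(i,j) / Σ_k w(i,k)`. The visit profile
   `He^k(a,·)` collects the expected number of visits of a k-step walk from
   `a` (counting step 0), and `DSD_k(i,j) = ‖He^k(i,·) − He^k(j,·)‖₁`. As
   `k → ∞` this converges, with closed form
   `DSD(i,j) = ‖(e_i − e_j)ᵀ (I − P + 1πᵀ)⁻¹‖₁` where `π` is the walk's
   stationary distribution. DSD is solved densely per connected component.
2. **Similarity and recursive spectral clustering.** Distances become
   affinities through an RBF kernel `S = exp(−D²/2σ²)`. The network is cut
   into `K = 500` groups by normalized spectral clustering (degree-normalized
   affinity embedding + seeded k-means), and every cluster of size `n` with
   `round(n/D) ≥ 2` is recursively re-split into `round(n/D)` groups
   (`D = 20`), so no retained cluster exceeds `⌈1.5·D⌉ − 1 = 29` nodes;
   clusters below `M = 3` are discarded.
3. **Reconnection.** Spectral clusters can be internally disconnected.
   With `n` members and `c` induced components, the connectivity score is
   `sc = 1 − (c−1)/(n−1)`. Outside proteins touching enough components are
   re-added in increasing order of degree until `sc > 0.75`, up to 20
   additions per cluster, yielding controlled overlap between clusters.
4. **Validation statistics.** Cluster *coherence* is the mean pairwise
   Jaccard similarity of member GO-term sets, tested one-tailed against a
   null that permutes the node→annotation map. Cluster *co-expression* is
   the median pairwise biweight midcorrelation over an expression matrix,
   tested paired against gene-label-shuffled expression.
5. **Cluster graph.** A higher-order graph whose nodes are clusters, edge
   weights counting crossing network edges (re-added nodes excluded), edges
   below `t = 10` dropped; clusters are labeled with their most frequent
   GO-slim term (support ≥ 3) and ranked by betweenness centrality to find
   "bridge" clusters.

A seeded synthetic generator (planted-partition networks with
predictor-like edge scores, block-correlated annotations and expression)
makes every stage testable without any external download.

## Worked example

```python
from funclust import (
    SyntheticSpec, write_synthetic_inputs, load_network, prune_network,
    dsd_converged, rbf_similarity, hierarchical_cluster, ClusteringParams,
    reconnect, RecipeParams, load_annotations, load_slim_map,
    build_cluster_graph, rank_bridge_clusters,
)
from funclust.annotate import annotate_clustering

paths = write_synthetic_inputs(SyntheticSpec(seed=11), "demo")
net = prune_network(load_network(paths["network"], score_threshold=0.5), 3)
print(f"network: {net.number_of_nodes()} proteins, {net.number_of_edges()} edges")

dmat = dsd_converged(net)
S = rbf_similarity(dmat)
clustering = hierarchical_cluster(S, dmat.nodes,
                                  ClusteringParams(K=500, D=20, M=3, seed=0))
clustering, report = reconnect(net, clustering, RecipeParams())
ann = load_annotations(paths["annotations"])
res = annotate_clustering(clustering, ann, net,
                          slim_map=load_slim_map(paths["slim"]),
                          n_perm=10, seed=0)
print(f"coherence: t = {res.t:.2f}, one-tailed p = {res.p:.2e}")
cg = build_cluster_graph(net, clustering, t=10)
top = rank_bridge_clusters(cg)[0]
print(f"top bridge cluster: {top[0]} (betweenness {top[1]:.3f})")
```

prints

```
network: 1030 proteins, 15907 edges
coherence: t = 52.12, one-tailed p = 8.59e-244
top bridge cluster: C0000 (betweenness 0.019)
```

i.e. on this synthetic interactome the 64 retained clusters (3–28 proteins
each) carry vastly more shared GO annotation than the shuffled-function
null, and cluster `C0000` brokers the most shortest paths between other
clusters in the thresholded cluster graph.

The same pipeline runs from the shell: `funclust simulate`, `funclust
cluster`, `funclust recipe`, `funclust annotate`, `funclust cgraph`,
`funclust coexpress`, or end-to-end from a YAML config with `funclust run
--config config.yaml --seed 0` (see `funclust --help`).

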
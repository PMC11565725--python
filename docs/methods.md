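# Methods

## Scope and model

`funclust` operates downstream of a sequence-based PPI predictor and an
HMM-based domain annotator: it consumes the predicted edge list (scores in
[0,1]), optional protein sequences (for length filtering and candidate-pair
enumeration), per-protein GO term sets (given directly or aggregated from
an hmmer per-domain table through a domain→GO map), a GO→GO-slim map, and
an optional expression matrix. Running the predictor, hmmscan, ontology
parsing, or any hosted language model is out of scope; the summary-card
stage produces the prompt text a user could send to an LLM but never calls
one.

## Diffusion state distance

The walk is biased by edge confidences, `P[i,j] = w(i,j)/Σ_k w(i,k)`
(`weighted=False` binarizes). The k-step visit profile includes the 0-step
visit, so its entries sum to `k+1`. The converged distance is computed with
the closed form `‖(e_i − e_j)ᵀ (I − P + 1πᵀ)⁻¹‖₁` using one dense LAPACK
solve per connected component; `π_i ∝ Σ_j w(i,j)` is stationary for the
(reversible) weighted walk. This is tractable to a few ×10⁴ nodes, which
covers the proteome scale the pipeline targets.

Numerical notes:

- Disconnected networks are handled per component; cross-component
  distances are stored as `inf` and become similarity 0 under the RBF
  kernel, since diffusion distances across components are undefined.
  Components smaller than the minimum cluster size `M` (and isolated
  nodes, which have no outgoing transition) are pruned beforehand with a
  logged count.
- For bipartite components the finite-k distances oscillate; the closed
  form equals their Cesàro mean and is used as-is (the two-node component
  has DSD exactly 1). Oracle tests against truncated visit sums therefore
  use non-bipartite fixtures.
- A condition number above 1e12 on `(I − P + W)` triggers a logged warning;
  a singular solve raises with diagnostics (it cannot occur for a connected
  component).

The RBF bandwidth default `"auto"` sets σ to the standard deviation of the
finite off-diagonal distances of the matrix. The choice is a convention —
no bandwidth is canonical here — and it adapts the kernel's scale to each
network; it is configurable everywhere it appears.

## Recursive spectral clustering

`spectral_partition` embeds the affinity sub-matrix with the top `k`
eigenvectors of `D^{-1/2} S D^{-1/2}` (dense symmetric eigensolver),
row-normalizes, and runs seeded k-means (`n_init=10` for `k ≤ 50`, 1 above,
where the embedding is high-dimensional and restarts are expensive). The
literature leaves the normalization variant open; this one is pinned for
reproducibility, and determinism given (S, params, seed) is tested.

The recursion: initial call with `K` groups (`K` is lowered to `n` with a
warning on small networks); every cluster of size `n` with
`round(n/D) ≥ 2` is re-split into `round(n/D)` groups on the sub-block of
the original similarity matrix (no DSD recomputation); `round` takes .5 up,
so the split condition is `n ≥ 1.5·D` and the maximum retained size is
`⌈1.5·D⌉ − 1` (29 at the default `D=20`). Clusters below `M=3` are
discarded with a logged count. If k-means ever collapses to a single group
(possible only with duplicated embedding rows), the group is split by a
deterministic equal chunking so the size bound still holds; the event is
logged. Empty k-means groups are dropped without retrying `k`.

## Reconnection

For a cluster with `n` members whose induced subgraph (edges binarized —
connectivity is topological) has `c` components,
`sc = 1 − (c−1)/(n−1)`; `sc = 1` iff connected, and the denominator is
defined because clusters have ≥ 3 members. Clusters with `c = 1`, or with
`sc` already above the threshold, are untouched.

Candidates are outside nodes with edges into at least
`max(1, floor(connect_ratio · c))` distinct components of the *initial*
component structure. The floor-with-minimum reading of "at least a 10%
fraction" is chosen over a ceiling because it is the only reading
consistent across component counts near the ratio boundary (at `c = 4` a
single touched component qualifies; at `c = 20` two are needed; at `c = 21`
connectors touching two components still qualify). The candidate list and
the degree ordering (increasing full-network degree, ties by node id) are
computed once per cluster; the greedy loop then adds candidates in order,
recomputing `(n, c, sc)` over members ∪ added after each addition, and
stops when `sc > sc_threshold` (default 0.75), at `max_added` additions
(default 20), or on exhaustion. `sc` is non-decreasing along the sequence:
every candidate has an edge into the current subgraph, so `c` cannot grow
while `n` does. Re-added nodes are recorded separately from members and
never removed.

## Coherence and its null

Pair similarity is the Jaccard index of GO-term sets; pairs whose union is
empty are *skipped*, not scored 0 — unannotated proteins carry no evidence
in either direction — and clusters with no valid pair are excluded from
both arms of the test. Cluster coherence is averaged over members ∪
recipe-added nodes, since reconnection is expected to raise coherence and
should be measured on the cluster actually reported. The null permutes the
node→GO-set assignment uniformly over the network's nodes (cluster
structure and degrees untouched, annotation multiset preserved); each
permutation contributes one coherence per cluster. Significance is a
one-tailed independent two-sample t-test (real > null). The global
coherence cutoff is estimated as the left edge of the maximal grid suffix
on which a Gaussian-KDE density of the real sample exceeds the null's
(common grid, configurable bandwidth, Scott's rule by default); when the
real curve never dominates, the threshold is undefined and a diagnostic is
returned instead.

Cluster functions are ranked by raw support (number of member proteins
carrying the term, re-added members included); a hypergeometric enrichment
is deliberately not the default — most-represented terms are what the slim
labeling needs. The slim label is the most frequent slim-projected term
with support ≥ 3, ties broken by term id, else `"unassigned"`.

## Cluster graph

Edge weight (C, D) counts binarized network edges between the two clusters'
*original* member sets; re-added nodes are excluded because overlapping
clusters would double-count. Edges below `t = 10` are dropped at
construction; the stricter cutoffs used for figures are a presentation
parameter of the exporter, not of construction. Bridge ranking uses
normalized betweenness on the unweighted thresholded graph (a
weighted variant using inverse crossing counts is behind a flag), ties by
cluster id.

## Co-expression

`bicor` implements the Tukey biweight midcorrelation
(`u = (x − med x)/(9·MAD x)`, weights `(1−u²)²·1[|u|<1]`); if either
vector's MAD is zero the pair falls back to plain Pearson. A cluster's
score is the median pairwise bicor over member genes present in the matrix
(absent genes dropped with a logged count; id matching is exact string
match). The null permutes the matrix's gene labels — profiles themselves
are untouched — and the test is a paired one-tailed t-test over clusters
scored in both arms, with per-cluster null medians averaged over
permutations. The alternative score `σ₁²/Σσᵢ²` (variance explained by the
first singular component of the row-centered submatrix) is provided; the
exact statistic is not pinned by convention, so variance-explained is
chosen and flagged as such.

## Synthetic study conditions

The generator's defaults define the conditions the tests run under: 22
blocks with sizes drawn uniformly in [10, 80] (~1000 nodes), within-block
edge probability 0.4 over background 0.01, 20 hub nodes of degree 12 wired
across blocks (these recreate the minor-hub fragmentation the reconnection
step exists for), edge scores uniform in (0.70, 0.99) within blocks and
(0.51, 0.90) across (every retained edge is strictly above the 0.5
predictor threshold), 6 GO terms per block received with probability 0.8
(noise terms at 0.05), and 24 expression samples at unit effect size with
noise sd 0.5. Setting signal equal to noise, or effect size to zero, yields
exact null data; the test suite verifies approximately uniform p-values
there and ≥95% rejection at α = 0.01 under the default signal across 20
seeds. Module-level statistical tests use smaller instances of the same
model (6–8 blocks of 10–60 nodes) so the whole suite runs in seconds.

What the generator does not emulate: scale-free degree structure, assortative
mixing, annotation incompleteness correlated with degree, ontology DAG
structure (terms are flat with a two-level slim map), or expression batch
effects. Passing tests demonstrate algorithmic correctness and statistical
calibration under planted structure, not performance guarantees on real
proteomes.

## Other conventions and limitations

- Sequence length filter bounds are inclusive ([50, 800] by default).
- Edge-list loading keeps scores strictly greater than the threshold,
  merges duplicate/reversed pairs by maximum score (conservative and
  order-independent), and drops self-loops.
- The hmmer per-domain table's independent E-value column is compared
  against a configurable cut (default 1e-5; no canonical value exists);
  domains missing from the domain→GO map are skipped with a warning.
- Candidate-pair enumeration takes an explicit keep-set (optionally built
  from a precomputed term→descendant closure TSV) instead of parsing the
  GO DAG.
- Cluster JSON, exports and reports use stable key order and contain no
  timestamps, so a fixed config + seed reproduces byte-identical artifacts;
  the run log (which does carry timestamps) is the only exception.
- The problem sizes used by `scripts/acceptance.py` (20 networks of ~1000
  nodes) match the generator's default study conditions; they are the scale
  at which the size law, reconnection contract and threshold behavior are
  exercised end to end.
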
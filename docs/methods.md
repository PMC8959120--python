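# Methods

## Model

`rewirenet` simulates the structural evolution of binary undirected networks
whose nodes carry coupled chaotic oscillators, under synchronization-driven
adaptive rewiring ("what fires together, wires together" at network level).

**Node dynamics.** Each node i carries a logistic map
`x -> 1 - alpha_i * x^2` with amplitude `alpha_i` in the chaotic regime
(default 1.8). At every discrete step all nodes update synchronously, mixing
each node's own map with the mean map of its graph neighbors `B_i` in
proportion to a coupling strength `eps_i` (default 0.4):

    x_i(t+1) = (1 - eps_i) * f(x_i) + eps_i / |B_i| * sum_{j in B_i} f_i(x_j)

with `f_i(x) = 1 - alpha_i * x^2`. Note the amplitude convention: by default
the receiving node's `alpha_i` is applied to the neighbors' activities, which
gives the clean vectorized form
`X+ = 1 - alpha .* [(1-eps) .* X.^2 + eps .* (A X.^2) ./ (A 1)]`. The
alternative convention — each neighbor contributes through its own
`alpha_j` — is available via `ParameterSet(neighbor_amplitude="neighbor")`;
for families that perturb only the coupling (SC/HC) the two conventions
coincide because `alpha` is uniform. After one update every activation lies
in `[1 - max(alpha), 1]` analytically, so no clipping is applied and all
arithmetic is double precision.

**Adaptive rewiring.** After every 20 dynamics updates (one *attempt*), a
pivot node is drawn uniformly at random. Distances `d_j = |x_j - x_pivot|`
and similarities `s = 1 - d` are computed; the pivot disconnects from its
most dissimilar neighbor (argmax of `d` over neighbors) and connects to its
most similar non-neighbor (argmax of `s` over non-neighbors). Ties at either
argmax are broken toward the lowest node index, making trajectories
reproducible. Each successful attempt conserves the edge count exactly.

**Pathological termination.** Two failure modes are detected and recorded
rather than prevented: a pivot connected to every other node has no
non-neighbor to gain (`no_non_neighbor`), and a removal can strand a node at
degree zero, making the next neighbor average undefined (`isolated_node`).
A terminated model is frozen — it stops evolving, its metric series ends at
the termination attempt, and it is excluded from all family-level summaries
and comparisons.

## Study conditions

The reference configuration is 300 nodes and 5,200 edges (density ~0.116),
evolved for 1 million rewiring attempts (20 million updates) in the full
study. The first 50 nodes form the *minority* partition; the remaining 250
the *majority*. Five parameter families perturb only the minority:

| family | minority alpha | minority eps | reading |
|--------|---------------|--------------|------------------|
| BL | 1.8 | 0.4 | baseline (uniform) |
| LC | 1.7 | 0.4 | less chaotic |
| MC | 1.9 | 0.4 | more chaotic |
| SC | 1.8 | 0.3 | sub-coupled |
| HC | 1.8 | 0.5 | hyper-coupled |

Initial graphs are uniform random simple graphs with exactly 5,200 edges;
initial activations are i.i.d. Uniform(0, 1). All randomness derives from a
single master seed through named substreams: the initialization stream
depends only on (seed, instantiation index), so the initial graph and
activations are *identical across families* for a given instantiation —
family comparisons are paired by construction. Dynamics streams depend on
(seed, family, instantiation); baseline/null ensembles use their own
streams.

## Network statistics

Six statistics are checkpointed during evolution for four scopes (whole
network, induced minority and majority subgraphs, and the interpartition
graph that keeps only cross edges):

- **edge density** — realized fraction of the scope's node pairs; the
  interpartition denominator is `|V_min| * |V_maj|` (each cross pair once).
- **global clustering** — closed over connected triplets via the trace
  formula `Tr(A^3) / (sum(A^2) - Tr(A^2))`; 0 when no triplet exists.
- **average path length** — mean shortest-path length over ordered pairs
  with disconnected pairs contributing 0. This convention (rather than
  restricting to the giant component) keeps the statistic defined on
  fragmented subgraphs; it deflates the value when fragmentation occurs.
- **small-world index** — clustering / path length. The normalized variant
  is obtained by dividing by the random-baseline value (below); because all
  models share one size and density, evolution plots use the raw index.
- **modularity** — Newman's Q with the standard `m = |E|` normalization, at
  the partition found by Clauset–Newman–Moore fast-greedy agglomeration
  (igraph's implementation, C speed). Greedy Q is a lower bound on the true
  optimum; the tests verify it never exceeds the exhaustive-search maximum
  on small graphs.
- **degree assortativity** — Pearson correlation of end-point degrees over
  both orientations of every edge. Undefined (NaN) on regular graphs; NaNs
  are dropped from window averages.

**Normalization.** Following the matched-baseline design, each metric (except
assortativity, reported raw) is divided by its ensemble mean over 100
fixed-edge-count random graphs. Subgraph scopes are matched per scope: a
scope of `n_s` nodes is normalized against random graphs on `n_s` nodes with
`round(density * pairs(n_s))` edges, where `density` is the whole-network
density (0.116) — the density every scope has at initialization. Matching to
the *evolved* subgraph density would force normalized edge density to 1 by
construction and is therefore not meaningful; a `match="whole"` switch
normalizes every scope by the whole-network ensemble instead.

**Rich club.** RC(k) is the edge density among nodes of degree >= k,
computed for all k up to the maximum degree via a suffix-sum histogram. The
normalized coefficient divides by the mean RC(k) of 200 degree-preserving
randomizations (double-edge swaps, 10x|E| attempted swaps per replicate — a
standard mixing heuristic; the original randomizer is unspecified).
Significance per k uses a one-sided one-sample Wilcoxon signed-rank test of
the null values against the observed coefficient at alpha = 0.01; with 200
replicates the exact distribution is impractical, so the normal
approximation with continuity correction is used.

## Model comparison

- **Functional connectivity** is the momentary matrix `|x_i - x_j|` at the
  final state; for graph-based comparison it is binarized by keeping the
  5,200 most similar pairs (ties toward the lexicographically lower pair),
  matching the anatomical edge count.
- **NetSimile** signatures aggregate 7 per-node features (degree, local
  clustering, mean neighbor degree, mean neighbor clustering, egonet edge
  count, egonet outgoing edges, egonet neighbor count) with 5 statistics
  (median, mean, SD, skewness, excess kurtosis) into a 35-vector; distances
  are Canberra, and a model-collection matrix is normalized to [0, 1] by its
  maximum. Skewness/kurtosis of a constant feature are defined as 0.
- **HHG** tests independence of two models' node-feature clouds, paired by
  shared node identity, from their Euclidean distance matrices
  (2x2 ball-membership tables with strict inequalities, summed Pearson
  chi-square). P-values come from permuting the node pairing of one side
  (default 1,000 permutations, add-one convention), so they are valid by
  construction. Per the study design a *high* p-value is read as low
  resemblance — an acknowledged unorthodox usage, reported only alongside
  NetSimile.
- **Contrast** is the block mean of a dissimilarity matrix over family
  assignments, dividing by the full block size (diagonal blocks include the
  zero self-pairs). **Differentiation** of a family is its within-family
  resemblance `(1 - contrast)` divided by the mean between-family
  resemblance; defined only for the [0, 1]-normalized NetSimile matrices.
  Terminated models are excluded before block averaging, so block sizes
  shrink rather than being padded.

## Numerical and performance choices

The experiment driver uses a numba-compiled fused kernel (edge-list neighbor
sums, O(|E|) per update) rather than the dense matrix-vector product —
about 2.5x faster at the reference scale and the difference grows with
sparsity. The pure-numpy operations in `dynamics` and `rewiring` define the
reference semantics; the test suite checks the kernel against them over a
full epoch at 1e-12. Bitwise equality *between* the two paths over long
horizons is not guaranteed (BLAS and loop summation orders differ at the
1e-16 level, which chaotic dynamics amplify); each path individually is
bit-reproducible under a fixed master seed, which is the reproducibility
contract.

Metric cadence is configurable; long runs default to a checkpoint every
1,000 attempts (window averages over >= 140 checkpoints are insensitive to
this thinning), while short validation runs can record every attempt.

## Desk-scale reproduction

The full 50-model, 1M-attempt study is deliberately scaled down for desk
validation: all tracked statistics plateau after roughly 60,000 attempts, so
windowed means over `[60k, end]` from 3-instantiation batteries at
150k–200k attempts estimate the same plateau quantities. The acceptance
script (`scripts/acceptance.py`) runs 3 BL and 3 HC models to 200k attempts
and 3 MC models to 150k, computes per-scope metrics every 1,000 attempts,
normalizes against 100 random baseline graphs, and reports windowed means.

## What the generator does and does not emulate

The synthetic-data stage reproduces the study's *stated* conditions exactly:
fixed-edge-count uniform random graphs, uniform initial activations, the
five parameter families, matched initializations. It does not model any
feature of real neural data — no spatial embedding, no weighted or directed
connections, no noise in the dynamics — so passing tests demonstrate
properties of the model class, not of biological networks.

Known discrepancy: under the baseline condition all nodes are statistically
exchangeable, so the expected minority-subgraph density ratio is exactly 1;
simulations confirm this (ratio ~1.0 with no drift). The published
minority-subgraph summary for the baseline condition reports a much larger
ratio, which cannot follow from the stated procedure; the perturbed
families do shift minority statistics here (the hyper-coupled minority
densifies strongly, to near-saturation over long runs — stronger than the
published minority values). Family-averaged minority quantities land near
the published ones, single-family ones may not.

## Known limitations

- The fast-greedy modularity partition is a heuristic; Q values are lower
  bounds (typically within a few percent on these graphs).
- The path-length convention (0 for disconnected pairs) makes small-world
  indices of fragmented subgraphs hard to interpret; the rich-club and
  density measures are unaffected.
- HHG on 300-node feature clouds costs O(n^3) per permutation; full 50-model
  batteries with 1,000 permutations are compute-intensive (hours, not
  minutes, on one core).
- Weighted/directed rewiring variants and continuous-time neural-mass
  dynamics are out of scope.
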
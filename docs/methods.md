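# Methods

## Bigram extraction

A domain hit is one assignment row: a domain id plus one or more
1-based inclusive residue segments. Discontinuous hits are treated as
a single unit via their envelope (first start, last end), both for
N→C ordering and for gap computation; this is the simplest convention
that keeps a split domain one object. Hits are sorted by envelope
start, ties by envelope end then domain id.

For consecutive hits the gap is `start(next) − end(prev) − 1`
residues. A bigram is emitted iff the gap is **strictly below 30**
and the two domain types differ. The complementary definition of
network peripheral domains ("at least 30 residues from any distinct
neighbour") fixes the boundary: a gap of exactly 30 is non-adjacent.
Overlapping and nested hits (gap ≤ 0) are consecutive after sorting
and count as adjacent — a covalent linkage exists either way.
Adjacent same-type pairs (tandem repeats) are never bigrams; they are
tallied in a diagnostic counter only. Only *consecutive* pairs are
considered, never all co-occurring pairs: co-occurrence would inflate
large architectures into cliques.

## Network statistics

Networks are undirected simple graphs; edges carry occurrence counts
but every statistic is computed on the unweighted topology (the
k-core decomposition the versatility index rests on is defined for
unweighted graphs, and all other statistics are kept consistent with
it). Clustering is `C(i) = 2n_i/(k_i(k_i−1))`, defined as 0 for
degree < 2; the network average is the mean over *all* vertices,
isolated ones contributing 0.

The average distance is computed on the largest connected component
(distances between components are undefined; the component used is
recorded in the summary output). Two conventions are exposed:

- `inclusive` (default): `l = 2/(n(n+1)) · Σ_{i≥j} d_ij`, with the
  `n(n+1)` denominator and the zero diagonal included in the sum. On
  a path A–B–C this gives 2/3; on a single edge, 1/3.
- `standard`: the mean over the `n(n−1)/2` distinct pairs (4/3 and 1
  on the same graphs).

The inclusive form is the default; the standard form is the one
comparable across the literature. Both appear in the summary JSON.

## Power-law fits

α (degree) and γ (clustering spectrum) are estimated by ordinary
least squares on `(log10 k, log10 value)` over the raw unbinned
points, excluding zeros and k < 1; the exponent is the negated slope.
This matches how log–log plots of `n(k)` and `c(k)` are read and is
exact (r² = 1) on noise-free power laws. A discrete Hill-type MLE for
α is available behind `method="mle"` for comparison; it estimates the
tail exponent of the degree *sample* rather than the histogram slope,
so the two need not agree on finite data.

## Null model

"Random networks with the same degree distribution" is implemented
as exact degree-*sequence* preservation by double-edge swaps
(10·|E| successful swaps per replicate; swaps creating self-loops or
parallel edges are rejected), not as a configuration model: swap
chains guarantee simple graphs and exact degrees. Connectivity is not
enforced. Rigid graphs (e.g. stars) admit no legal swap; they are
returned unchanged with a warning and yield a zero-spread ensemble
flagged degenerate rather than a z-score. Replicate seeds are spawned
from the master seed via `numpy.random.SeedSequence`, so ensembles
are reproducible and any single replicate can be regenerated.

## Module hierarchy

The topological overlap variant used is
`OT(i,j) = (|N(i)∩N(j)| + a_ij)/min(k_i,k_j)` with `OT = 0` when
either degree is 0 and a unit diagonal; a `plus_one` denominator
variant (`min(k)+1−a_ij`) sits behind a flag. Thresholds are heights
in dissimilarity `d = 1 − OT`: this is the reading under which the
0.95 cut yields coarse modules and 0.3 fragments them into few-domain
groups, i.e. the cuts peel nested modules from coarse to fine. A
module at threshold t is a maximal cluster whose internal merges are
all strictly below t, so partitions at lower thresholds refine those
above.

All vertices are clustered in one pooled linkage rather than one
linkage per connected component: cross-component overlap is exactly
0, hence cross-component dissimilarity exactly 1, and under average
linkage inter-component cluster distances remain exactly 1 — so
components merge only at height 1.0 and every cut below 1 equals the
per-component result (asserted by a test). Module tables carry
component membership for reporting. Leaves are sorted
lexicographically before linkage, which makes tie-breaking
deterministic; singleton modules are reported but countable
separately. When distinct merges tie exactly in height, the flat
partition at a threshold genuinely depends on which merge is taken
first, so partitions are invariant under relabelings that preserve
the lexicographic vertex order (and under arbitrary relabeling
whenever the dissimilarities are tie-free), not under arbitrary
renames of a tied matrix — no deterministic tie rule could be.

## k-core decomposition

Shell indices are computed by bucket peeling in O(V+E): repeatedly
remove a minimum-degree vertex, assigning it the running maximum of
the minimum degree seen. Removal order cannot change shell indices;
within a bucket, vertices peel in lexicographic order for
deterministic traces. Peripheral domains (zero bigrams) merge into
the shell table at index 0; any vertex with an edge has shell ≥ 1.
The nested-core count is the number of distinct nonzero shell values.
Tests cross-check the implementation against an exhaustive
subset-union oracle (shell(v) = max over vertex subsets containing v
of the induced minimum degree) and against networkx's independent
`core_number`.

## Conservation statistic

Pairwise percent identity between two aligned family members is
`100 · matches / columns` where both have a residue; columns with a
gap in either member are dropped from the denominator. This is the
common symmetric convention (the alternative — dividing by full
alignment length — penalises indels twice). Pairs with no mutually
ungapped column are excluded and counted. Family summaries are mean
± SD over included pairs; the core-vs-peripheral comparison reports
group means and a two-sided Mann–Whitney U over family means,
descriptively. Families dominated by short tandem repeats are removed
by an explicit blocklist, not detected automatically. Alignments are
inputs; no aligner is run.

## Synthetic data

The generator's role is to plant known truth, not biological realism:

- **Architectures** are random walks on the target network (geometric
  length, mean 3, max 6 domains), so consecutive distinct-domain
  pairs are always target edges; one two-domain protein per edge
  guarantees coverage, making the round trip
  `network → genome → bigrams → network` exact.
- **Gaps**: linked pairs uniform on [0, 29], unlinked on [30, 100] —
  only the side of the 30-residue threshold matters downstream.
- **Peripheral domains** appear in single-domain proteins or at
  unlinked distances only.
- **Hierarchical graphs** use the deterministic replica construction
  (level-1 clique; each level replicates the structure base−1 times
  and wires replica peripheral vertices to the hub), which carries
  the C(k) ~ k⁻¹ signature; at base 5, levels 3 (125 vertices) the
  fitted γ is ≈ 1.14.
- **Two-level modular graphs** couple cliques strongly (two bridges)
  within top-level modules and weakly (one bridge) between them,
  which separates the dendrogram heights into three bands; the 0.95
  cut recovers top-level modules and the 0.7 cut the cliques,
  exactly.
- **Multi-group plans** build each group's innermost core as a clique
  (distinct sizes per group) containing the globally shared domains,
  the pair-shared domains, and group-specific fillers, surrounded by
  pendant paths of shell 1 — so planted core overlaps (by default 6
  shared by all four groups, 18 by at least two, inclusive) are
  recovered by decomposition alone.
- **Alignment families** mutate a random ancestor per site with
  probability p, giving expected identity ≈ 100·((1−p)² + p²/19).

What passing on synthetic data does *not* show: robustness to
assignment noise (missed or spurious domain hits), to paralog
inflation of edge counts, or to the huge size and skew of real
kingdom-level networks; the generator makes no attempt at realistic
domain duplication/loss dynamics.

## Problem sizes and numerics

Tests run hierarchical networks at 64–125 vertices, oracle sweeps at
≤ 12 vertices (200 graphs), round trips at ≤ 40 vertices (50
networks) and null ensembles at 100 replicates, sizes at which the
planted guarantees are exact and the whole suite stays fast; the
library itself has no such limits, and the replicate default is 1000.
Threshold cuts use `nextafter(t, −∞)` so that merges at exactly t are
split ("strictly below t"); dissimilarity symmetry is validated to
1e−12; power-law exactness holds to machine precision. Stage seeds
derive from the master seed by CRC32 of the stage name, keeping every
stage independently reproducible and all seeds below 2³¹.

## Pipeline

Each stage writes its tables plus a provenance JSON (config hash —
output directory excluded, it does not define the analysis — derived
seed, package version, input checksums) and removes partial outputs
on failure. Defaults are the analysis defaults: gap 30, thresholds
0.95/0.9/0.7/0.5/0.3, 1000 replicates, `paper` distance convention,
`ravasz` overlap variant.
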
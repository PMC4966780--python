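# Methods

## Model and assumptions

Each GO aspect is treated as a self-contained rooted DAG whose root is
the aspect node (`biological_process`, `molecular_function` or
`cellular_component`), not the top-level GO root. Only the hierarchical
relations `is_a` and `part_of` are traversed, both unweighted; other GO
relations (`regulates` and friends) are dropped with a logged count, as
are cross-aspect `part_of` links, so that every aspect is acyclic and
single-rooted. Obsolete terms never enter the graph.

Information content is corpus-based: IC(t) = −log(G_t/G_Tot) with
annotation counts propagated to ancestors (a gene annotated to t counts
for t and every ancestor of t). Consequences of that convention:

* IC is monotone non-increasing toward the root and the aspect root has
  IC 0 whenever any gene reaches it;
* an unannotated term gets the +∞ sentinel — it stays traversable and
  contributes 0 to IIC sums (1/∞), which keeps sparse corpora usable;
* a non-root term with IC 0 (annotating every gene) also contributes 0,
  consistent with the root's exclusion, and is flagged in logs.

The logarithm base defaults to the natural log, the common IC
convention; it is configurable (`compute_ic(log_base=...)`,
`--log-base`) because IIC ratios are not base-invariant.

## Path machinery

IIC(P) = Σ 1/IC(t) over a path's nodes, aspect root excluded. The
node-weighted selection problems are solved exactly:

* **Minimum-IIC path t→x** by Dijkstra on the upward graph where edge
  (u→v) carries 1/IC(v) and the start node's 1/IC is added once. Ties on
  IIC break toward shorter length, then the lexicographically smallest
  node sequence, so selection is deterministic.
* **Maximum-IIC path x→root** by dynamic programming in topological
  order over x's ancestor subgraph; ties break toward longer length,
  then lexicographic order.

The *weighting by length* is applied after selection: the selected
path's IIC multiplied by its edge count. The combined path t1→x←t2 sums
the two one-sided IICs with the hinge x counted once, and its length is
the sum of the two one-sided edge counts. Both conventions are fixed by
the published worked example (five IIC terms with multiplier 4 = 2+2
edges on one branch; four terms with multiplier 3 = 2+1 on the other).

Disjunctive common ancestors are implemented as the minimal elements
(the antichain) of the common-ancestor set under the ancestor partial
order: x qualifies iff none of x's immediate children is also a common
ancestor. The set-theoretic phrasing sometimes used for this concept
("no child of x on a path from x to the root") is vacuous in an rDAG;
the antichain reading is the one that reproduces the worked example's
two disjunctive ancestors. A term counts as its own ancestor inside
`common_ancestors` only, which makes t1 = t2 ⇒ D = 0 fall out naturally;
`ancestors()` proper excludes self.

The minimisation over disjunctive ancestors runs the shortest path
*through each ancestor separately* (not a global shortest path); its
tie-break is the smaller combined path weight, then the smaller ancestor
ID. If the only disjunctive common ancestor is the aspect root, D = +∞
and S = 0; the identity rule S(t, t) = 1 takes precedence (relevant only
for the root paired with itself).

## Gene-level aggregation

The n×m term-similarity matrix is aggregated with `rcmax` by default —
max of the two directional best-match averages — with `bma` and `avg`
available. Evidence codes are not weighted. A gene with no annotation
in the requested aspect raises an explicit error rather than scoring 0,
because silent zeros would bias IntraSet statistics; the CLI offers
`--on-missing skip` for batch jobs. Term-pair results are memoised per
(graph, IC table) cache with the unordered pair as key, since batch
workloads are quadratic in annotations.

## Baseline measures

* **IntelliGO**: cosine of annotation vectors with basis dot products
  2·Depth(LCA)/(MinSPL + 2·Depth(LCA)). The inverse annotation frequency
  is not given a formula in the original description; we use the
  standard IDF analogue log(G_Tot/G_t) on propagated counts (0 at the
  root), and evidence-code weights default to 1. The 0/0 case (both
  terms the root) is defined as 1; genes whose vectors carry no
  information (all-zero coefficients) score 1 against an identical term
  set and 0 otherwise.
* **Wang**: S-values with w(is_a) = 0.8, w(part_of) = 0.6, BMA
  aggregation.
* **Resnik/Lord**: IC of the LCA, averaged over the term grid. LCA means
  the *deepest* common ancestor (depth = longest upward path, ties
  lexicographic), shared with IntelliGO's machinery; a `max_ic` switch
  selects the max-IC-ancestor semantics instead, since the two can
  differ.
* **Al-Mubaid**: exp(−0.2 × mean shortest through-any-common-ancestor
  path length); the constant is exposed as a parameter.
* **SimGIC**: IC-weighted Jaccard over annotation ancestor closures;
  +∞ ICs are excluded from both sums and 0/0 is defined as 0.

## Evaluation statistics

IntraSet similarity is the mean over all n² within-set gene pairs —
self-pairs included, implementing the n² denominator literally. InterSet
is the grand mean over the n×m cross pairs. DP(S_k) =
(p−1)·IntraSet(S_k)/Σ_{i≠k}InterSet(S_k,S_i) and IDP = IntraSet × DP.
A zero DP denominator yields +∞ with a warning.

The empirical distance covariance uses the standard energy-statistics
estimator dcov² = S1 + S2 − 2·S3 over pairwise Euclidean distance
matrices; tiny negative dcov² values (floating error near independence)
are clamped to 0 before square roots, and dcor is defined 0 when either
marginal dcov² vanishes.

Grouped expression-vs-annotation correlation partitions (r, s) pairs
deterministically — quantile bins on r or a fixed 2-D grid — instead of
a stochastic self-organising map; the grouping is pluggable
(`group_fn`), so a trained SOM can be injected, and the ≥ 0.5
within-group threshold for a group to count is kept. Degenerate groups
(fewer than two points, or constant in either coordinate) are skipped
with a warning; if no group qualifies the result is NaN.

Spearman p-values are exact (full permutation enumeration, two-sided)
for n ≤ 10 and use the t-approximation otherwise; constant inputs use
the convention r = 0, p = 1.

The annotation-length-bias audit draws, for each group size k in a
range, a fixed number of random same-size term-group pairs (uniform over
the graph's terms, seeded), scores them with the supplied group measure
and reports the Spearman correlation between group size and mean score.

## Synthetic data

The worked-example fixture injects the published IC values directly — it
does not recompute them from any annotation release, whose exact
settings are unknowable — and commits to the minimal DAG consistent with
every printed path length and IC membership (`docs/fig2_fixture.md`).
Random rDAGs give node i (in topological order) 1–3 parents among
earlier nodes; random corpora annotate each synthetic gene to 1–10
uniform terms (1–4 in the smaller test corpora). These generators are
pure functions of their spec and seed.

What the synthetic fixtures do *not* emulate: the real GO's depth
profile (~17 levels vs ~5 here), its heavy-tailed branching, biased
annotation frequencies, or evidence-code composition. Passing tests
therefore demonstrate the algorithms' correctness against their
definitions and exhaustive oracles, not measure performance on real
annotation corpora; benchmark figures on curated gene sets depend on the
GO/GOA release and are out of scope.

## Problem sizes and numerical choices

Exhaustive-oracle suites use 500 random DAGs of 4–12 nodes (where path
enumeration is tractable) for the term distance and the five baselines;
the bias audit runs at 10 sizes × 100 pairs over a 200-term DAG; the
discriminating-power check partitions 30 exchangeable synthetic genes
into three sets, where DP = 1 holds to within Monte-Carlo error (±0.1).
API-level comparisons use 1e−9 absolute tolerance; the CLI writes six
decimals; dcov² agreement with the brute-force summation is required to
1e−10.

## Known limitations

* No OWL parsing, no `consider`/`replaced_by` remapping, no live GO
  download.
* Lin/Jiang normalisations and the CESSM comparison variants are not
  implemented.
* Resnik/Lord values are unbounded (not mapped to [0, 1]); terms with
  infinite IC can surface as infinite Resnik scores on sparse corpora.
* Worst-case cost of a term pair is dominated by the per-ancestor
  Dijkstra runs; batch jobs rely on the term-pair cache rather than
  parallelism.
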
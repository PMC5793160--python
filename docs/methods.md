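# Methods

This note documents the models and procedures implemented in `congems`, the
parameter choices that matter, what the synthetic generators do and do not
emulate, and the numerical conventions adopted where the design was open.

## Differential expression

Genes are normalized row-wise to mean 0 and unit standard deviation; the
sample (m−1) divisor is used, the convention of expression pipelines (a
`ddof` argument exposes the population variant).  Genes in the lowest
variance quantile (default 30%, configurable down to 0) are dropped first —
a constant gene cannot be normalized and near-constant genes contribute
discretization noise.

The two-group test is a moderated *t*: the pooled residual variance s²_g of
each gene (d_g = n₁+n₂−2 degrees of freedom) is shrunk toward a prior s₀²
with prior degrees of freedom d₀,

    s̃²_g = (d₀ s₀² + d_g s²_g) / (d₀ + d_g),
    t̃_g  = (x̄₁ − x̄₂) / (s̃_g √(1/n₁ + 1/n₂)),   df = d₀ + d_g.

d₀ and s₀² are fitted by method of moments on log s²_g using the
digamma/trigamma identities of the scaled-F model (trigamma inversion by
Newton iteration, tolerance 1e−10).  When the observed variance spread is
tighter than chi-square sampling noise the moment equation has no positive
solution; d₀ = ∞ is used and every gene receives s₀² (a limit, not an
error).  With shrinkage disabled (d₀ = 0) the statistic is exactly the
pooled two-sample *t*; the test suite verifies this to 1e−10 and also
cross-checks the full empirical-Bayes fit against the Bioconductor limma
implementation on a heterogeneous-variance fixture (agreement to ~1e−8).
A plug-in path exists implicitly: `select_degs`/`rank_and_weight` consume
plain per-gene records, so any external test's p-values can be substituted.

Fold change is the ratio of group means; for log₂-scale input (the default
assumption, `log2_input=True`) it is 2^(mean difference), which keeps the
ratio meaningful for mean-zero data.  Multiple probes per gene collapse to
the probe with the lowest raw p-value *before* any filtering.  DEGs require
BH-corrected p < 0.05 and fold change outside (0.7, 1.4) by default.

Ranking for the weights sorts by corrected p.  The BH step function creates
ties; they are broken by raw p and then input order so that ranks — and
hence the weights w_i = (rank_max − (rank_i − 1))/rank_max — are
deterministic.  The weights are linear from 1 down to 1/rank_max in steps
of 1/rank_max.

## Discretization and transactions

The normalized DEG matrix is transposed (samples × genes) and thresholded
at 0; a value of exactly 0 maps to 1 so that every entry is defined.
Post-discretization doubles the columns into signed items: column k holds
the above-mean state g+ and column re_n+k its complement g−, so each gene
is in exactly one state per sample.  Samples are the transactions.

## Weighted rule mining

A signed item inherits its base gene's rank weight.  The weighted measures
follow a mean-item-weight convention,

    wsupp(X)     = sup(X) · (Σ_{i∈X} w_i)/|X|,
    wconf(A⇒C)   = conf(A⇒C) · (Σ_{i∈A∪C} w_i)/|A∪C|,

kept behind two small scoring functions so the convention can be swapped.
Because every weight is ≤ 1, wsupp ≤ sup; a level-wise (Apriori) search on
plain support at the weighted threshold is therefore a lossless superset of
the weighted result, and the weighted filters are applied afterwards.  The
miner is hand-written (the search scale here is hundreds of items and tens
of samples; no high-performance engine is needed) and is verified against
exhaustive enumeration over all itemsets and bipartitions on random
matrices.  Itemsets containing both g+ and g− of one gene are discarded:
complementarity makes their support 0, and such rules would be
self-contradictory at the sample level.  `max_itemset_size` defaults to 4
(markers of interest have at most ~3 genes per side) and bounds the search.

Rules are ranked by wconf descending, then wsupp descending, then a
serialized lexicographic key (sorted antecedent, "=>", sorted consequent)
for a deterministic total order.  The per-rule dynamic thresholds retain
rules with wsupp and wconf at or above mean + z·sd of the mined set
(population sd; z defaults to 0), after which the top `number_ERules` are
kept.

## Rule similarity

Weighted Jaccard sums the weights of items shared on each of the four side
combinations (LHS∩LHS, RHS∩RHS, LHS∩RHS, RHS∩LHS) over the weights of the
four corresponding unions; 0/0 is defined as 0.  For any valid rule the
self-score is exactly 1/3: the two same-side unions reproduce the rule once
while the two cross-side unions each duplicate it.  Weighted cosine embeds
each rule as a 2n-vector over the sorted universe of items occurring in the
selected rules — antecedent weights in the first half, consequent weights
in the second — so a shared item only contributes when it is on the same
side of both rules; the self-score is 1.  Matching is over *signed* items:
g+ and g− are distinct mined states and are treated as different entities
even though they share a base gene (the alternative, gene-level matching,
would make a rule and its complementary mirror maximally similar, which
contradicts their disjoint sample support).

The blended similarity e₁·WJaccard + e₂·WCos (defaults 0.5/0.5, e₁+e₂ ≤ 1)
gives the dissimilarity 1 − blend.  The diagonal of the dissimilarity
matrix is forced to 0 — the linkage input contract — although the
off-diagonal formula would give 1 − e₁/3 − e₂ for a rule against a copy of
itself; the off-diagonal math is untouched, and the duplicate-rule value
1/3 (at the default blend) is asserted in the tests.

## Clustering and tree cut

Average linkage is a hand-written O(n³) UPGMA with deterministic
smallest-index tie-breaking (rule sets at desk scale are a few hundred
objects); it is validated against scipy's UPGMA by cophenetic-distance
equality on random matrices.  The dendrogram exports to Newick with merge
heights as branch lengths.

The tree cut is a dynamic hybrid variant: (1) a static cut at 99% of the
top merge height isolates branches joined near the root; (2) each branch is
recursively split where the joining height stands clear of its
sub-branches' internal heights by at least a clearance fraction
(1 − deep_split/4)·0.5 of its own height — deep_split ∈ 0..4, default 2,
higher values splitting more aggressively; (3) branches below
`min_module_size` (default 3) are dissolved and their members assigned
PAM-style to the closest module when their average dissimilarity to it does
not exceed that module's own radius, otherwise they stay grey.  Colors come
from the standard fixed palette (turquoise, blue, brown, ...) by decreasing
module size, ties by smallest member index.  The reference partition for
the external indices is PAM (BUILD + steepest-descent SWAP, plus 10 seeded
random restarts because single-swap descent demonstrably hits local optima
even at n = 5, k = 3) with k fixed to the module count.

## Network baselines

Gene-module comparators build |cor|^β adjacencies (Pearson or Spearman,
β = 6 by default — the standard weighted-network convention; an optional
scale-free-fit selector picks the smallest β ∈ 1..20 with R² ≥ 0.8).  TOM
is computed entrywise from the adjacency (valid for weighted and binary
input, unit diagonal).  GTOM of degree m is defined on a binary graph —
weighted adjacencies are binarized at τ (default 0.5) first — with
N_m(i) = {u ≠ i : dist(u, i) ≤ m}; degree 0 returns the adjacency itself
and degree 1 coincides with TOM on binary graphs (asserted on random
graphs).  1 − similarity feeds the same linkage/tree-cut pipeline.

## Validity indices and comparison

avgDI is the classical global Dunn index (minimum inter-cluster distance
over maximum intra-cluster diameter); no per-module averaging is defined
for it here, the "avg" prefix notwithstanding, because none is standard.
All-singleton partitions give diameter 0 and hence Inf, which is preserved
as a distinct marker.  avgSW is the mean silhouette width over clustered
objects (scikit-learn, precomputed metric).  The five network concepts use
the fundamental formulas (k_i = Σ a_ij; scaled connectivity k_i/max k;
clustering coefficient Σ a_ij a_jq a_qi / (k_i² − Σ a_ij²); maximum
adjacency ratio Σ a_ij²/Σ a_ij; density; centralization
n/(n−2)·(max k/(n−1) − density)), evaluated per module on the similarity
matrix the method actually clusters (integrated rule similarity for rule
partitions, TOM-family similarity for gene partitions), node-averaged and
then unweighted-averaged across non-grey modules; undefined denominators
mark the index invalid for that module.  Rand and adjusted Rand come from
scikit-learn.

Win-draw-loss compares two methods index by index: both invalid (or Inf) is
a draw, a finite value beats an invalid/Inf one, equal values draw, and
otherwise the orientation decides — scaled connectivity is the one
lower-better index.  Treating Inf as invalid is not arbitrary: it is the
only convention that reproduces all twenty published summary triples of the
two shipped case-study tables, which the tests assert.

## Synthetic data: what it emulates and what it does not

`simulate_expression` draws genes i.i.d. Normal(0, σ²), overlays
equicorrelated blocks through one latent factor per block per sample
(pairwise correlation ρ, marginal variance preserved), and shifts case
means of DE genes by ±δ with alternating signs so both up- and
down-regulated paths are exercised.  Block membership and DE status may
overlap, which is exactly how co-expressed DE blocks — the structure the
rule clustering targets — arise.  It does **not** emulate microarray
probe-level artifacts, batch effects, heavy-tailed noise, or
methylation-specific beta distributions; passing tests demonstrate
correctness of the machinery on clean planted structure, not robustness to
those real-data features.  `simulate_transactions` plants itemsets directly
in boolean transactions with per-transaction embedding probabilities over
Bernoulli background noise.

### The recovery experiment and an identifiability limit

The standard recovery scenario (in `congems.experiments`) plants two
disjoint 6-gene blocks, all DE, with ρ = 0.9, δ = 3σ and 20 samples per
group, mines pair rules at (wsupp ≥ 0.1, wconf ≥ 0.3) over the 12 planted
genes, and scores the adjusted Rand index between rule-module labels and
each rule's pattern of origin.  What does a rule's "origin" mean here?
After per-gene discretization at the overall mean, a 3σ-shifted gene's
above/below state is essentially its sample's group label (flip probability
Φ(−1.5) ≈ 0.067).  Every DE gene therefore contributes one signed item to
the *case signature* and the complementary item to the *control signature*:
these two complementary co-occurrence patterns are the rule-generating
structure the scenario plants, and they are what origin refers to.  The
pipeline recovers them with ARI 1.0 across seeds.

Block identity *within* a signature is a different matter: cross-block item
pairs co-occur through the shared group dichotomy with confidence ≈ 0.875
versus ≈ 0.915 within a block (the ρ-driven correlated flips are the only
separation), a gap inside sampling noise at 40 samples.  Roughly half of
all mined rules legitimately span both blocks, and no threshold can
separate them reliably.  Finer-than-signature recovery is thus not
identifiable under these conditions — a property of discretized two-group
data at large effect sizes, not of the implementation.  The complementary
transaction-level experiment plants two disjoint itemsets directly (no
group confound) and recovers the two pattern modules with ARI 1.0,
demonstrating the multi-pattern case.

Calibration checks: under the global null (δ = 0) the raw-p DEG rate at
α = 0.05 stays within 3·√(α(1−α)/n_genes) of α; with δ = 3σ and 10 samples
per group, all planted DE genes pass BH FDR < 0.05.

## Problem sizes and determinism

Default experiment sizes — 60 genes, 40 samples, 12 planted DEGs, ≤ 200
selected rules, 10 replicates; 50 random matrices (≤ 12 items, ≤ 30
transactions) for the mining oracle; n ≤ 15 for the matrix oracles — keep
the whole suite and the acceptance script in seconds on one CPU while
exercising every code path.  Every stochastic component takes an explicit
seed (numpy `default_rng`); identical config + seed reproduces all outputs
byte for byte, which the pipeline tests assert.

## Known limitations

* The weighted support/confidence convention is one defensible reading of
  rank-weighted rule interestingness; the scoring functions isolate it.
* The dynamic hybrid tree cut is a re-implementation of the branch-detection
  idea with a simple clearance criterion, not a port of any particular
  reference implementation; its two knobs (`min_module_size`, `deep_split`)
  are exposed.
* GTOM for m ≥ 1 requires binarization of weighted networks; the τ = 0.5
  default is a choice, and results for GTOM on correlation data depend on it.
* Marker annotation against literature/pathway databases is out of scope;
  the `status` column is emitted as `unannotated`.
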
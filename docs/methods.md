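# Methods

## Model and objective

`shrinkclust` treats hard clustering as symmetric binary matrix
factorization. For N objects with pairwise similarities S (symmetric,
entries in [0, 1], unit diagonal), a partition into K clusters is encoded as
a binary assignment matrix A with unit row sums, and the partition-implied
similarity is AAᵀ (1 for co-clustered pairs, 0 otherwise). The fitted
partition minimizes ‖S − AAᵀ‖²_F. Expanding the square and dropping the
partition-independent constant Σ S²ᵢⱼ reduces this to

    f(A) = Σᵢ Σ_{j : Aᵢ = Aⱼ} (1 − 2 Sᵢⱼ),

a sum over co-clustered ordered pairs, self-pairs included. Intuitively each
co-clustered pair is rewarded when Sᵢⱼ > ½ and penalized when Sᵢⱼ < ½; the
value ½ is the implicit decision boundary of the objective, which matters
for similarity construction (below).

Moving one object i from cluster k to k′ changes the objective by

    Δfᵢ = 2 ( Σ_{j∈k′, j≠i} (1 − 2Sᵢⱼ) − Σ_{j∈k, j≠i} (1 − 2Sᵢⱼ) ).

Both sums exclude the self-pair: its contribution is identical in f(A′) and
f(A) and cancels; this is the only reading under which Δfᵢ equals the true
objective difference, and the unit tests verify the equality exactly against
brute-force evaluation.

## Algorithm

The solver initializes by assigning each object uniformly at random to one
of k₀ cluster ids and then iterates two steps:

1. **Removal sweep.** Empty clusters are deleted (f is unchanged). With a
   minimum cluster size ω in force, at most one undersized non-empty cluster
   is additionally dissolved (details below).
2. **Greedy permutation.** All N×(K−1) candidate single-object moves are
   scored through a cached matrix V[i, c] = Σ_{j∈c, j≠i}(1 − 2Sᵢⱼ), which
   makes each scan O(N·K) and each applied move an O(N) cache update. The
   move with the most negative Δf is applied; ties break to the lowest
   object index, then the lowest cluster id, so runs are reproducible given
   the seed.

Convergence is declared when no strictly improving move exists and the
removal sweep deleted nothing. Zero-cost moves are never taken: allowing
them could cycle, and forbidding them preserves the strict-decrease argument
that guarantees convergence (f is bounded below by −Σ S²ᵢⱼ). Clusters only
ever disappear, so the surviving count at convergence is the selected K; the
per-iteration record of (iteration, K, f) is exposed as the *shrinkage
path*.

Because K can only shrink, k₀ must exceed the number of clusters actually
present; the default k₀ = min(N, 20) suits data with up to roughly a dozen
clusters, and larger k₀ values cost iterations but not correctness. For the
same reason a greedy run from a degenerate initialization (for example all
objects in one cluster) is already at a local optimum and cannot split;
restarts make this harmless.

## Size-constrained removal

With ω > 0 the removal sweep must dissolve undersized clusters and decide
where their members go — a procedure with real freedom in it. The package's
policy, chosen after comparing alternatives on the simulated block matrices:

- at most one undersized cluster is dissolved per sweep (the smallest;
  ties to the lowest id), so the partition reorganizes between removals
  instead of collapsing wholesale while every early cluster is still tiny;
- a cluster is spared for the sweep when the current globally best move
  would move an object *into* it — such a cluster is actively assembling,
  and destroying it discards structure the optimization is building;
- orphaned members are reassigned one at a time in ascending object-index
  order, each to the surviving cluster with the smallest insertion cost
  Σ_{j∈c}(1 − 2Sᵢⱼ), i.e. by the same local criterion the move step uses.

Rejected alternatives: dissolving *all* undersized clusters at once
collapses the partition to a single cluster at the first sweep whenever
ω exceeds the typical initial cluster size N/k₀ (with N = 100, k₀ = 20 that
is any ω ≥ 6); a cascading within-sweep dissolution converges in fewer
iterations but merges blocks prematurely, degrading recovery for moderate ω.
The adopted policy reproduces the behaviors the simulations probe: exact
recovery for ω up to the smallest true cluster, clean forced merges beyond
it (ω = 20 → K = 4 in ~97% of runs, ω = 25 → K = 2 in all runs on the
15/17/20/24/24 blocks), and a mean iteration count that falls steeply with ω
before plateauing near ω ≈ 10. Dissolving a non-empty cluster can raise f;
monotonicity is a property of the move steps, and the path reflects that.
When ω > N the single remaining cluster is retained with a warning — the
constraint is infeasible.

## Similarity construction

Feature tables are converted with S = exp(−(D/(βσ))²), where D is the
Euclidean distance matrix, σ the standard deviation of the pairwise
distances and β = E(D²)/σ². Both moments are computed over the off-diagonal
entries of the full symmetric distance matrix — the zero diagonal is
structural, and including it would deflate both statistics — and population
(not sample) moments are used, matching the expectation notation. The kernel
has no free parameter, is strictly decreasing in distance, and maps zero
distance to exactly 1.

The kernel's length scale βσ = E(D²)/σ is deliberately large, so the
resulting similarities crowd the upper end of [0, 1]: on three
unit-covariance blobs with centers four to five apart, every off-diagonal
similarity lies in roughly [0.3, 1] with median ≈ 0.85. Since f rewards
co-clustering exactly when Sᵢⱼ > ½, a matrix whose entries all exceed ½ has
the one-cluster partition as its global optimum regardless of structure.
The remedy shipped (and used by the blob pipeline) is the skew
normalization `normalize_skewed_similarity`: shift all entries so the
off-diagonal median sits at 0.5, clip to [0, 1], reset the diagonal. This
recenters the similarity distribution on the objective's decision boundary,
and it is equally the right move for real similarity data skewed toward 1
(integrated multi-omic sample similarities typically are). The median is
computed off-diagonal only.

## Synthetic data

Three generators define the regimes the tests probe:

- **Block matrices.** A contiguous block assignment from given cluster
  sizes and its implied binary similarity S = AAᵀ — the noiseless ideal in
  which recovery should be perfect and f at the truth equals −Σ n²_k.
- **Folded-Gaussian noise.** Each off-diagonal entry of a binary S is
  replaced by |ε| (where it was 0) or 1 − |ε| (where it was 1), with an
  independent ε ~ N(0, σ²) per entry. The model is entrywise; because the
  objective sums Sᵢⱼ and Sⱼᵢ over every co-clustered pair, the solver
  effectively sees the symmetrized average of two independent draws, and
  `add_noise` returns that symmetric matrix by default (the raw entrywise
  matrix is available with `symmetrize=False`, and it is the matrix on
  which the marginal entry distribution should be studied: at σ = 0.5 about
  32% of raw entries cross ½, i.e. 2Φ(−1) of similarity relationships are
  effectively reversed). Mirroring a *single* draw across the diagonal
  instead doubles the effective pairwise noise variance; under that variant
  the planted partition stops being the objective's optimum in a few
  percent of σ = 0.4 matrices, so the observed recovery cliff between
  σ = 0.4 and σ = 0.5 identifies the averaged entrywise model as the one
  generating the reported behavior. Entries are clipped to [0, 1] (draws
  with |ε| > 1 are rare for σ ≤ 0.5 and invisible to the reversal
  statistic); the diagonal is exempt — self-similarity is structural.
- **2-D Gaussian blobs.** n points per center with identity covariance,
  plus ground-truth labels. The default experiment uses 50 points at each
  of (−2, 2), (−2, −2), (2, 0); at those separations a nearest-center
  classifier already misassigns ≈ 5 of 150 points in expectation, which
  bounds what any clustering of a single draw can achieve.

What these generators do *not* emulate: real similarity matrices are not
binary-plus-noise (their noise is structured and correlated), real
expression data is high-dimensional with non-spherical clusters, and block
sizes here are known exactly. Passing these tests shows the optimizer and
the pipelines behave as designed under the stated regimes, not that the
method will resolve subtypes in any particular dataset.

## Evaluation metrics

Partition agreement is scored from the truth × prediction contingency
table: normalized mutual information with arithmetic-mean normalization
I(T;P)/((H(T)+H(P))/2) (defined as 1 when both partitions are the trivial
single cluster, 0 when exactly one side is trivial), the plain unadjusted
Rand index (fraction of agreeing pairs), and the pair-counting F1 (harmonic
mean of pair precision and recall, 0 when there are no true-positive pairs;
a reference partition with no co-clustered pairs makes recall undefined and
returns 0 with a warning). *Exact recovery* means the contingency table is
a permuted diagonal — equality up to bijective relabeling. All metrics are
invariant to relabeling on either side; the tests cross-check NMI and Rand
against scikit-learn and the pair F1 against direct pair enumeration.

## Defaults and problem sizes

| parameter  | default      | meaning / rationale                                  |
|------------|--------------|------------------------------------------------------|
| `k0`       | min(N, 20)   | initial cluster count; must exceed the true K        |
| `omega`    | 0            | minimum cluster size; 0 = base algorithm             |
| `max_iter` | 10 000       | safety cap; runs at N = 100 converge in ~20–100 iterations |
| `restarts` | 1            | independent restarts, best final f kept; restart r uses seed + r |
| `seed`     | 0            | all randomness is confined to initialization         |

The simulation studies in the test suite use 50 solver runs per condition
for the recovery and size-constraint experiments and 100 noisy replicates
per σ for the noise sweep — sizes at which every run completes in
milliseconds and the binomial uncertainty on a perfect recovery rate is
already informative. The acceptance script uses the same sizes.

## Numerical choices and degenerate inputs

- Input validation symmetrizes by averaging (warning above 1e-8 maximal
  asymmetry), clips to [0, 1] with a warning, and forces the diagonal to 1.
- N = 1 returns a single cluster immediately; a constant all-ones S
  collapses to one cluster (every merge improves f).
- All-coincident points (or zero distance spread) make the kernel
  degenerate; the all-ones limit is returned with a warning.
- Cluster ids are compacted after removals preserving relative order;
  output files renumber clusters 1..K by first appearance.
- The final objective is recomputed from the labels at the end of a run, so
  reported values carry no accumulated float drift.

## Limitations

- The solver finds local optima; greedy single-object moves cannot split a
  cluster, so an under-provisioned k₀ (or an unlucky degenerate start) caps
  the discoverable K. Restarts mitigate but do not eliminate this.
- Only hard partitions are produced — no soft memberships, no must-link or
  cannot-link constraints, no handling of missing similarities.
- With similarities derived from Euclidean distance the objective favors
  roughly spherical clusters, like K-means and symmetric-NMF relatives.
- The ω-constrained removal policy is one defensible resolution of an
  underdetermined procedure; other reasonable policies yield the same
  feasible-size guarantees but can merge different clusters when ω exceeds
  the smallest natural cluster.
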
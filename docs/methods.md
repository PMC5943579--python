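# Methods

## The problem

Community-detection algorithms return a partition of a network into groups,
but they do so even on random graphs. The question this package answers is
not "is there community structure overall?" but "is *this particular*
community stronger than what the same detection pipeline produces on a
randomized version of the network?" — with the crucial complication that a
community's quality score is strongly, positively correlated with its size
under the null, so quality must be judged *conditional on size*.

## The (q, s)-test

Let q_c be a per-community quality and s_c a size measure (node count n_c or
degree sum vol_c). The null ensemble is built by generating R randomized
networks that preserve (expected) node degrees, running on each the same
detection algorithm used on the original network, and pooling the
(q̃, s̃) pairs of all C̄ detected communities. The joint null density is
estimated by a bivariate Gaussian KDE: per-coordinate scales h·σ_q̃ and
h·σ_s̃ (unbiased sample standard deviations), kernel correlation γ equal to
the Pearson correlation of the pooled pairs, and Scott's-rule bandwidth
h = C̄^(−1/6). The p-value of community c is the conditional tail
probability P(q̃ ≥ q_c | s_c), which for this kernel has a closed form: a
weighted average of normal CDF terms with Gaussian size weights
exp[−((s_c − s̃_k)/(√2 h σ_s̃))²] and Φ arguments
[(q_c − q̃_k)/(h σ_q̃) − γ(s_c − s̃_k)/(h σ_s̃)] / √(1−γ²). The closed form
is verified in the test suite against direct numerical quadrature of the
KDE integrals, and the partial-integral identity it rests on is verified
against adaptive quadrature at 1e-8.

Testing C communities inflates the family-wise error, so the per-community
level is Šidák-corrected: α = 1 − (1 − α′)^(1/C), with α′ = 0.05 by default.
A community is significant when p ≤ α (non-strict).

Numerical notes:

* Size weights are computed with a max-shift so a query deep in the tails
  does not underflow; if even the nearest null sample is farther than the
  underflow horizon the p-value would be pure extrapolation and a hard error
  is raised instead.
* γ is clipped to ±(1 − 1e−8) when the pooled pairs are (numerically)
  perfectly correlated; zero variance in either coordinate is an error
  advising a larger R.
* σ uses the C̄−1 denominator; for C = 1 the Šidák formula is returned as
  α′ exactly rather than through `1 − (1−α′)` round-trip rounding.
* p-values are clipped to [0, 1] after the weighted average.

## Quality functions

All four per-community scores are oriented so larger is better, which lets
one maximizer serve all of them: the modularity contribution
q^mod = (1/2M) Σ_{i,j∈c}(A_ij − d_i d_j/2M) (sums over *ordered* intra
pairs; summed over communities it is exactly Newman modularity, asserted
against networkx's implementation at 1e−12); the internal average degree
q^int = 2·(intra edges)/n_c; minus the expansion q^exp = −cut_c/n_c; and
minus the conductance q^cnd = −cut_c/vol_c. Cut edges are counted once. A
zero-volume community has conductance defined as 0 (with a warning); it has
no edges to cut. Reported scores are always recomputed from integer edge
counts, never from incremental caches.

## Detection

* **Modularity**: the Louvain heuristic via igraph's C implementation
  (`community_multilevel`), deterministic under a fixed seed. The contract
  used downstream is only "a seedable local maximizer of Σ q^mod".
* **int / exp / cnd**: a Kernighan–Lin-style relabelling search over a fixed
  label budget C, written for this package. Each pass greedily applies the
  single (node, new label) relabelling with the largest ΔQ — accepted even
  when negative — never moving a node twice in a pass, then rewinds to the
  best labeling seen; passes repeat until no improvement. ΔQ is computed
  incrementally from per-community aggregates (asserted against full
  recomputation at 1e−10 on 1000 random moves); the Q used for bookkeeping
  is re-summed from the aggregates each step so no float drift accumulates.

Two design points were genuinely open and resolved as follows:

* *Emptying communities.* A move that would empty its source community is
  inadmissible. Fixing C exists precisely to rule out trivial solutions: for
  the cut-based objectives the all-in-one labeling has zero cut and would
  otherwise always win (and would collapse the null ensemble to degenerate
  single-community partitions). Communities can be created into (an
  initially empty label can be filled) but never destroyed; the initial
  uniform-random assignment is made surjective so all C communities exist
  from the start. A consequence is that a pass may end before N relabelings
  when no admissible move remains.
* *Ties.* ΔQ ties are broken by lowest node index, then lowest label, for
  determinism under a fixed seed.

When no C is supplied for the int/exp/cnd objectives, C defaults to the
community count of a Louvain run on the same network.

## Null models

`chung_lu` (default): connect each pair independently with probability
min(1, d_i d_j/2M) — preserves expected degrees. `stub_matching`: pair
degree stubs uniformly, discarding self-loops and duplicate edges —
preserves degrees exactly up to the discarded stubs and, in particular,
leaves no node isolated. Randomized networks are not forced to be connected.
Per-network seeds are derived counter-style from the base seed
(`SeedSequence(base, spawn_key=(r,))`), so the pooled ensemble is
bit-identical for any worker count.

The choice of variant matters for calibration experiments: Chung–Lu
randomization isolates low-degree nodes, and detection then yields many
singleton communities all at exactly (q, s) = (0, 1). An atom in the null
makes the conditional p-value at that atom a point mass, so pooled null
p-values cannot be uniform. The calibration (uniformity) experiment
therefore uses stub matching, where the null (q, s) distribution is
continuous. Even then the p-value distribution carries a residual KDE
smoothing distortion (KS ≈ 0.06–0.09 at R = 100, decaying slowly with R);
the calibration check uses ~220 pooled communities, where the 1% KS critical
value (≈0.11) sits above that floor.

## Baselines

* **S-test** (extremal intra-edge count at fixed node count): for each
  distinct community size n and each randomized network, a greedy
  grow-and-swap local search finds a strong n-node subset; maxima are made
  non-decreasing in n by seeding each size with the grown best subset of the
  previous size. p = (1 + #{maxima ≥ observed})/(R + 1), so p is never 0.
  This test is very conservative by construction: the densest subsets of a
  degree-preserving randomization are hub clusters that often out-score
  planted communities even at zero mixing (on the benchmark below its TPR at
  μ = 0 is 0).
* **L-test criterion** (deterministic, node-level): a community is
  significant iff every member has more intra-community neighbors than its
  configuration-model expectation, taken as d_i(vol_c − d_i)/2M — a node's
  stubs cannot attach to themselves. This is the verbal criterion, not the
  B-score order statistics of the method it summarizes.

Both baselines use the same Šidák-corrected α as the (q, s)-test.

## Synthetic benchmark

The generator emulates LFR planted partitions: degrees follow a truncated
power law (exponent 2, max 100, lower cutoff calibrated by bisection so the
discretized mean is the target 10), community sizes follow a truncated power
law (exponent 2) on [20, 200] (the quality–size scatter uses [10, 100]),
each node keeps a fraction 1 − μ of its edges internal, intra-community
edges are realized exactly by edge-switching degree-sequence sampling
(igraph) and inter-community edges by cross-community stub matching with
conflicting stubs re-paired then dropped. μ = 0 yields strictly internal
edges; μ = 1 strictly external ones. Generation retries with fresh sub-seeds
(≤20) when placement fails, when the realized mean degree drifts more than
15% from target, or when a node ends up isolated. At μ > 0 a hub whose
internal degree exceeds every open community's size is placed in the largest
open community with its internal degree capped at size − 1 (the standard
LFR resolution); at μ = 0 capping is disabled so the all-edges-internal
guarantee is exact — which also means size ranges whose maximum is at or
below the maximum degree (e.g. [10, 100] with max degree 100) are infeasible
at μ = 0.

What the generator does *not* emulate: degree–degree correlations,
clustering beyond what the planted partition induces, overlapping
communities, and weighted or directed edges. Tests passing on these
networks show the pipeline behaves as designed under the stated null and
planted-partition alternatives; they do not certify behavior on empirical
networks with, e.g., core–periphery structure.

The true-positive-rate experiment applies each significance test to the
*planted* communities of fresh networks over a μ grid and averages the
per-network fraction judged significant. The null ensembles inside the
(q, s)-test still use communities *detected* in randomizations. The
agreement score between two tests is τ = (C₁₁ + C₀₀)/C.

## Problem sizes and defaults

Defaults follow the benchmark's standard setting: R = 500 randomized
networks for analyses (the p-values change little beyond that), scaled to
R = 100 and 10 replicates in the test suite and benchmark CLI defaults
(full-scale 30 replicates / R = 500 behind `--full`); the headline
reproduction script uses the full 30 networks at N = 1000. The KL search is
quadratic per pass and intended for networks up to a few thousand nodes;
Louvain handles larger ones.

## Known limitations

* The KDE conditional p-value inherits smoothing bias O(h²); with Scott's
  rule this decays only as C̄^(−1/3), so calibration is approximate at
  moderate R (see above).
* The S-test's extremal subset search is a heuristic; its maxima are lower
  bounds, which makes the S-test *less* conservative than with exact maxima.
  Best-found counts are logged for audit.
* Communities whose size lies far outside the null size support cannot be
  scored (hard error rather than silent extrapolation).
* Only undirected, unweighted, simple graphs are supported; directions and
  weights of input files are ignored by construction.
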
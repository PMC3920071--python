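# Methods

This note documents the statistical model behind `speechconn`, the choices
made where the procedure admitted more than one reasonable convention, and
what the synthetic-data tests do and do not establish about real data.

## Data model

The unit of analysis is a nonnegative weighted connectivity matrix per
subject over a fixed, ordered parcellation of speech-network ROIs (default
28 per hemisphere; hemisphere-major order, lobe-major and
anterior-to-posterior within hemisphere).  Edge weights are normalized tract
densities: mean probabilistic-streamline density in the target ROI divided
by the seed-mask voxel count, so a row is a seed and a column a target.

Raw seed × target matrices are asymmetric only because tract tracing is
directional; diffusion carries no direction information, so intra-hemispheric
matrices are symmetrized as M = (M₀ + M₀ᵀ)/2 and the diagonal
(self-connections) is fixed at zero and excluded from every statistic.  The
commissural matrix stays asymmetric for commissural-only analyses — all
28² = 784 cells are distinct connections — and is symmetrized the same way
only when embedded as the off-diagonal block of the 56 × 56 bilateral
matrix, which must be a valid undirected graph.  The default speech-network
label list is a best-effort reconstruction from ROI names common in the
speech-motor literature and is explicitly user-overridable; analyses depend
only on the node count and order, not on the names.

## Edge-wise statistics

Group comparisons use the Wilcoxon rank-sum test with midranks and the
tie-corrected normal approximation, without continuity correction.  When
both groups have ≤ 5 subjects the full permutation distribution of the case
rank sum is enumerated instead (C(n, n₁) assignments; tail probabilities
include ties with the observed sum), because the normal approximation is
poor at that size and enumeration is cheap.  The sign attached to each edge
is the sign of mean(case) − mean(control) — a deliberate mixture: the test
is rank-based but the reported direction follows the difference of means,
which is the convention the signed display value −log₁₀(p)·sign assumes.
Severity correlations are midrank Spearman ρ with the t-approximation for
p, computed over case subjects only by default (severity is a case-group
construct); a flag admits all scored subjects for sensitivity analyses.
Edges that are constant across subjects get p = 1 and sign 0 rather than an
error.  FDR control is Benjamini–Hochberg step-up (via statsmodels).

## Permutation inference

**NBS.**  Edge-wise one-tailed p's are thresholded (defaults: 0.01 for group
tests, 0.05 for correlations), supra-threshold edges are partitioned into
connected components, and each observed component's size is referred to the
permutation null distribution of the maximum component size.  Component
"size" is the edge count (the common NBS convention; an intensity variant is
out of scope).  The exchangeable unit is the subject's group label for group
tests and the severity vector across case subjects for correlations.
Corrected p-values use (1 + b)/(1 + m), so they are bounded below by
1/(m + 1), never zero, and monotone in component size.  Inside permutations
the rank-sum statistic always uses the normal approximation: ranks depend
only on the data, so each permutation reduces to one boolean-matrix product,
which is what makes 10⁴ iterations (the default) and replicate calibration
studies cheap.  Tails are fixed one-tailed, alpha 0.05: case < control for
group tests, negative for severity correlations, matching the directional
prior of white-matter deficit studies.

**Sign-bias ratio test.**  Within a scope of edges, the numbers of negative
and positive effect signs are counted and R = (n₋ + 1)/(n₊ + 1) (Laplacian
correction avoids division by zero) is referred to the permutation null of
the same quantity, one-tailed for an excess of negative signs.  Two scopes
are implemented because the procedure is described ambiguously in the field:
over *all* edges of the matrix, or over only the edges already significant
at uncorrected two-tailed p < 0.05.  The default is `significant_edges`;
neither is asserted to be canonical, and results should state the scope
used.  The binomial test is deliberately not a substitute: edges sharing a
seed or target ROI are dependent, and the test suite demonstrates on
cohorts with a shared per-subject factor that the permutation p and the
binomial p diverge grossly.

## Graph metrics

Strength is the row sum of weights.  Shortest-path measures convert weights
to lengths as ℓ = 1/w (the convention for connectivity-strength weights in
the brain-connectivity toolboxes this package interoperates with; stated
here prominently because results depend on it).  Betweenness centrality
counts full shortest-path multiplicities and is normalized to a fraction of
the (n−1)(n−2)/2 pairs by default, with raw counts available via a flag —
normalization does not affect group-difference directions.  Clustering is
the Onnela geometric-mean formula with weights rescaled by the graph
maximum, zero for nodes of binary degree < 2.  Weighted global efficiency
is the mean of 1/d(i,j) over ordered pairs with disconnected pairs
contributing 0; it equals 1 on a complete unit-weight graph.  Betweenness
and clustering are scale invariant; efficiency scales linearly with the
weights.  Implementation rests on networkx and scipy shortest paths; the
test suite checks all four measures against independent brute-force oracles
(triple-loop Floyd–Warshall, exhaustive simple-path enumeration, triple-loop
triangle sums) on 100 random graphs of ≤ 8 nodes.

Per-node metric group tests (two-tailed t-tests, Spearman severity
correlations) are reported uncorrected and flagged exploratory — with 28
nodes × 3 metrics, ~4 nominally significant nodes are expected under the
null.

## Regional aggregation

ROI means of scalar volumes (FA and other tensor-derived measures) are
arithmetic means over labeled voxels; with 63 labels per hemisphere this
yields 126 means per subject.  No value floor is applied inside ROIs by
default (skeleton-based thresholds belong to a different method family); a
threshold flag exists for sensitivity analyses.  Zero-voxel ROIs are
recorded as missing with a warning, not an error.  The module consumes label
volumes; constructing shallow-white-matter labels is upstream anatomy
tooling and out of scope.

## Synthetic cohorts

The generator emulates the statistical structure the inference assumes:
baseline weights decay exponentially with node-order distance
(strength · exp(−|i−j|/scale), defaults 1.0 and 3.0), mimicking the
dominance of short-range connections in real tract-density matrices;
per-subject noise is multiplicative log-normal (σ default 0.2) because
tract densities are nonnegative and right-skewed.  Group sizes default to
20 cases vs 17 controls.  Planted effects multiply case weights on a
connected component of target edges grown by random spanning-tree
construction (connectivity by construction, as NBS power tests require).
Severity scores are drawn from 13 + 33·Beta(2, 2.5), matching a clinical
severity instrument with observed range 13–43 and median ≈ 26; severity
edges shrink as exp(slope · (s − median(s))), centered on the sample median
so the slope changes the correlation, not the group mean.  An optional
per-subject global log-normal factor (default off) induces cross-edge
dependence for the permutation-vs-binomial demonstration.  A single master
seed drives everything through spawned child streams; identical seeds give
bit-identical cohorts.

What the generator does *not* emulate: spatial autocorrelation beyond the
shared subject factor, seed-size heterogeneity, tractography distance bias,
hemispheric asymmetries, or site/motion artifacts.  Passing calibration and
power tests on these cohorts therefore establishes the correctness and
calibration of the inference machinery under its stated assumptions — not
the power of the design against real tractography noise.

## Problem sizes and numerical choices

Calibration suites use 200 replicate null cohorts at 500 permutations
(null FWER of NBS within [0.01, 0.10]; sign-bias p uniform by KS test and
~5% one-sided rejection), and 50 replicates for power (8-edge component at
multiplier 0.4, σ = 0.15: detection with ≥ 80% edge recall in ≥ 90% of
replicates).  These sizes give the binomial confidence to distinguish a
calibrated test from a broken one while keeping the default suite fast.
Symmetry checks use an absolute tolerance of 1e-8; component ordering is
deterministic (size descending, ties by smallest node index); permutation
label assignments are drawn by argsort of uniform variates.  Pipeline
outputs contain no timestamps and use fixed float formatting, so a rerun
with an identical config and seed reproduces every file byte for byte.

## Known limitations

Exact rank-sum enumeration is limited to groups of ≤ 5 (factorial growth);
permutations always use the normal approximation, a documented
approximation at small n.  The NBS correlation permutes severity within
cases only, holding edge thresholds fixed per permutation.  Nuisance
covariates (age, sex) are not modeled at any level, matching the analysis
design this package supports.  The default parcellation label list is a
reconstruction, not an authoritative anatomy.
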
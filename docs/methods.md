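# Methods

## Problem setting

A compound library screened against m targets gives each compound a
binary activity profile y ∈ {0,1}^m. The screening goal is a *desired*
profile: active on a chosen set of main targets, inactive elsewhere.
`multirank` turns this into a graded ranking problem: profiles are
encoded as integer rank scores, a linear ranking function is trained on
all profiles at once, and rankings are evaluated with pair-based
metrics that weight confusions between distant score levels more
heavily than confusions between adjacent ones.

## Profile encoding

`build_scheme(m, main_targets, secondary_priority, main_priority,
nonselective_as_decoy)` produces a total map from all 2^m profiles to
scores 0..max with these guarantees: the all-inactive profile maps to
0; the exact desired profile is the unique maximum; scores are a
contiguous integer range.

Hard decoy rules (score 0) are applied first:

1. no main target active;
2. main targets incompletely met *and* any secondary target hit;
3. if `nonselective_as_decoy`: every secondary target hit.

Remaining profiles are ranked by a lexicographic severity key
(secondary-extra severity, main-miss severity): unwanted secondary
activity is penalized before missing main activity. Within each
component, an ordered priority list assigns power-of-two weights
(first listed = weight 2^L … last = 2, unlisted = 1), so the presence
of a higher-priority deviation always dominates any combination of
lower-priority ones; "equal" priority gives unit weights, and
equally-deviating profiles share one score. The four canonical
three-target schemes (single main; dual mains; single main with
ordered avoidance; dual mains with ordered main priority) are pinned
cell-by-cell by golden tests; for m > 3 the construction is this
package's documented extrapolation — in particular the choice that
extras outrank misses in the severity key is a design decision, chosen
because unwanted activity must be designed *out* of a lead while a
missing activity can be designed *in*.

The three-level selectivity labeling (`srank_encode`: selective 1,
decoy 0, non-selective −1) and the binary main-target labeling
(`binary_labels`: 1 iff active on all main targets) are provided for
the comparison protocols. An optional pre-filter (`drop_promiscuous`)
removes compounds active on all m targets, whose features would
otherwise act as noise for every scheme; it is off by default.

## Ranking model and metrics

For scores s and predictions f, the orderable pair set is
P = {(i,j) : s_i > s_j} with total weight W = Σ_P (s_i − s_j). The
pairwise loss is 1 for f_i < f_j, ½ for an exact floating-point tie
(the ranking-by-sorting interpretation of a tie), else 0. `rank_error`
is the unweighted mean over P (equal to 1 − AUC for binary scores,
ties included — asserted against scikit-learn's Mann–Whitney AUC);
`kpartite_error` weights each pair by s_i − s_j and normalizes by W.
A tolerance-based tie predicate (|f_i − f_j| < 1e−12) is available for
diagnostics only; the metrics use exact equality.

Training minimizes J(w) = ½‖w‖² + C·L(w) with, by default, the
margin-rescaled surrogate
L(w) = (1/W) Σ_P max(0, (s_i − s_j) − wᵀ(x_i − x_j)); the
slack-rescaled variant (1/W) Σ_P (s_i − s_j)·max(0, 1 − wᵀ(x_i − x_j))
is selectable. Both are convex upper bounds of the k-partite error
(scaled by W). There is no intercept: rankings are invariant to
additive constants. Dividing by W makes C comparable across data set
sizes; the consequence for grid values quoted in the unnormalized
pair-sum convention is discussed under "Evaluation protocol".

### Fast loss evaluation

L(w) and its subgradient are computed without materializing P: the l
predictions are grouped by score and sorted once per group; for each
of the R(R−1)/2 ordered score pairs a `searchsorted` sweep with prefix
sums yields the exact hinge sum and the per-instance subgradient
counts, giving O(d·l + R²·l + l·log l) per evaluation. The sweep is
asserted to equal the brute-force O(l²) pair expansion to 1e−9
relative over hundreds of random instances and both loss variants.

### Solver

The objective is minimized by a bundle (cutting-plane) method run in
the l-dimensional span of the training rows: with the Gram matrix
K = XXᵀ precomputed, every quantity (predictions, plane inner
products, ‖w‖²) lives in R^l, so the 2²⁰-dimensional weight vector is
only formed once at the end (w = Xᵀ·coef). Each iteration adds the
tangent plane of C·L at the current point, re-solves the regularized
bundle subproblem through its simplex-constrained dual (an in-house
FISTA with exact simplex projection; Lipschitz constant by power
iteration), and then improves the incumbent by a line search between
the incumbent and the QP iterate — the risk along the segment is
re-evaluated at four interior points, which is cheap because of the
fast sweep and closes the primal-dual gap far faster than the bundle
model alone. The dual value of the bundle model is a certified lower
bound on min J, so termination on

    gap ≤ tol · min(best objective, initial gap)

guarantees tol-optimality of the returned objective *and* forces real
progress in the small-C regime, where J is nearly flat around 0 and a
purely objective-relative test would stop after one step. Exceeding
`max_iter` returns the best iterate with `converged=False`. The bundle
is pruned to ≤ 100 planes (inactive, oldest first). The solver is
deterministic given (data, config); the `seed` field exists for
interface stability and does not affect the returned weights.
Optimality is verified on small instances against an independent
generic solver (L-BFGS-B on the smooth box-constrained dual of the
fully expanded pairwise QP, with a primal-dual-gap certificate).

Defaults: `tol=1e-5`, `max_iter=500`, margin rescaling. Typical fits
at l ≈ 500 converge in under a second.

## Baselines

Per-target SVCs and the Crammer–Singer multi-class SVM are delegated
to liblinear (via scikit-learn) with `fit_intercept=False`; the tests
pin the optimization contract instead of the implementation — hinge
and multi-class objectives must match independent QP references to
1e−4 / 1e−3 relative on small instances. The linear combination
`combine` sums weight vectors elementwise; prediction linearity
f_combined(x) = Σ cᵢ fᵢ(x) is exact and property-tested. Default
factors are +2 per desired target and −1 per undesired target;
alternatives (e.g. +3/−2/−1) are plain configuration. Per-target SVC
k uses activity on target k as its label, with all other training
compounds (including actives of other targets) as negatives — the
negative-class composition is not fully determined by the protocol
description, and this choice is documented rather than claimed
canonical. MC-SVM argmax ties go to the lowest class index.

## Molecular encoding

`ecfp` hashes circular atom environments: round-0 codes from (element,
heavy degree, attached H count, formal charge, ring membership), then
bond_diameter/2 rounds in which each atom's code becomes a hash of its
previous code and the sorted (bond order, neighbor code) pairs. All
codes from all rounds fold modulo the hash space (2²⁰ default; 2¹²
in tests so brute-force oracles stay fast). The hash is an in-house
deterministic 32-bit one (blake2b, 4-byte digest), so fingerprints are
bit-identical across runs and platforms; structural deduplication of
identical environments across rounds is deliberately not performed —
under binary folding, duplicate codes set the same bit anyway.
Fingerprints are binary by default (a count mode exists); collisions
from folding are accepted silently. `cosine_normalize` scales to unit
Euclidean length so dot products are cosine similarities in [0, 1].

Structure input (SMILES, V2000 SDF) is parsed with RDKit. The
normalization is deliberately minimal: largest fragment (ties: more
heavy atoms, then lexicographically smallest canonical SMILES,
logged), aromaticity perception, hydrogen counts folded into per-atom
fields, and canonical atom ordering (hence idempotent and input-order
independent). Neutralization and tautomer canonicalization are *not*
performed; this is a deliberate substitution for a full standardizer
pipeline and matters when comparing against externally prepared data.
pK_i activity tables are binarized with an **inclusive** cutoff
(value ≥ cutoff → active), the reading of "inactive below the cutoff".
Sparse fingerprints round-trip through a libsvm-style text dialect
with 0-based, strictly ascending indices and a header comment carrying
dimension and normalization flag.

## Evaluation protocol

One repetition: group active compounds by exact profile; from every
subset draw n = ⌊(smallest subset of the same single/dual/triple
category)/2⌋ compounds (floor for odd sizes); add decoys sampled
without replacement from the all-inactive pool (1000 by default; if
the pool is smaller, all of it with a warning); choose C by 2-fold
cross-validated grid search, stratified by rank score (stratification
is this package's choice — unstratified 2-fold splits degenerate when
score levels are rare; invalid splits are redrawn up to 10 times);
fit; score the held-out remainder under both the binary and the graded
labeling. Default 20 repetitions; all methods see the same splits for
a given seed, so comparisons are paired. Grid-search selection uses
the k-partite error for ranking-evaluated methods and the binary
miss-ranked-pair fraction for the plain SVC; ties prefer smaller C.
Summary dispersion is reported as both SD and IQR.

Default grids: {0.1, 1, 10, 100, 1000} for SVC and MC-SVM (liblinear's
unnormalized-sum convention, used as-is) and {1e−6 … 1e−2} for the
ranking methods. The ranking grid is quoted in the pair-sum convention
of the original ranking-SVM software; under this package's
W-normalized objective those raw values all fall in the regime where
every hinge is active and the whole grid collapses to a single
solution. The harness therefore multiplies ranking grid values by the
training set's total pair weight W before calling the solver, which
makes the searched model space match the quoted grid while the
reported C stays in the quoted convention.

The cutoff-sweep protocol for real-valued (pK_i) data re-binarizes at
each cutoff and uses stratified 50/50 train/test splits (identical
label distribution in both halves, per-level floor; a level with a
single compound stays in the test half with a warning) instead of
decoy injection.

## Synthetic benchmarks

`make_benchmark` plants, per target, a disjoint block of 30
"pharmacophore" features in a 2¹²-dimensional space (2²⁰ remains the
production fingerprint default; the smaller test dimension keeps the
brute-force oracles cheap). A compound active on target k carries each
feature of block k with probability `activation_prob`; uniform
background bits (Poisson, mean 20 per compound) and per-feature block
flips with probability `background_noise` add realism. Ground-truth
per-target weight vectors are the block indicators, so in the
noise-free limit a linear ranker separates the designed profiles
perfectly — which end-to-end tests exploit as an exact oracle
(k-partite error 0 on train and test). The default composition is
100/100/100 single-target, 60/60/60 dual, 40 triple actives and 280
decoys (n = 800), the overlap structure of a three-target
confirmatory screen; "moderate noise" in the tests means
activation_prob 0.75 and background_noise 0.005. These values were
fixed once as the package's standard study conditions.

What the generator does **not** emulate: real chemistry (fingerprints
are drawn directly, no molecule graphs), correlated targets (blocks
are disjoint by default; an explicit block layout can introduce
overlap), property-matched decoys, and heavy-tailed feature frequency
distributions. Passing tests therefore demonstrate correctness of the
machinery and the expected ordering of methods under planted linear
structure, not performance on any real screening library.

## Known limitations

- Kernelized/nonlinear ranking, top-of-list objectives and probability
  calibration are out of scope; the model is strictly linear.
- Real-valued (pK_i-graded) rank scores are not supported; profiles
  are binarized before encoding.
- The bundle solver precomputes the l×l Gram matrix; memory grows
  quadratically in the training set size (fine for the protocol sizes
  here, ~10⁴ instances at most).
- The m > 3 encoding extrapolation and the per-target SVC
  negative-class choice are documented decisions, not uniquely
  determined by the protocol they generalize.
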
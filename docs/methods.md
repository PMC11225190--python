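# Methods

## Overview

`phenobin` implements a quantitative integrative-taxonomy workflow for
groups — such as crustose lichens — in which most specimens cannot be
sequenced. A molecular reference tree anchors the taxonomy; specimens known
only from phenotype ("queries") are attached to it by evolutionary
placement with character weights calibrated on the reference taxa;
taxon-delimitation hypotheses are then compared with MRPP on phenotype
distances; and ordination summarizes how well phenotype alone separates the
resulting groups.

## Phenotype coding

Characters are binary, ordered multistate, or continuous morphometric.
Continuous measurements are gap-coded into ordered states before analysis:
with explicit thresholds, a value's state is the number of thresholds at or
below it (right-half-open intervals); with automatic coding, `n_states`
equal-width bins span the observed range and the maximum falls in the top
state. The mapping is monotone, deterministic and parameter-free; a
degenerate (constant) range codes everything as state 0. Missing cells
("?" or "-") carry a single missing flag; unknown and inapplicable are not
distinguished, which matches the common convention of coding characters of
absent structures (e.g. apothecia of sterile specimens) as unknown.

## Trees, edges and rooting

Trees are stored rooted for bookkeeping with a degree-2 root; every score
is invariant to the root position (tested). Each non-root node owns the
edge to its parent; edge ids are assigned in post-order and are stable
across re-reads, giving 2n − 2 edges for n terminals. The two root-adjacent
edges represent one unrooted edge, always carry equal placement scores, and
ties resolve to the lower edge id. Polytomies are rejected by default
(placement scores on polytomies are ambiguous) or resolved deterministically
with zero-length edges on request.

## Parsimony and likelihood engines

Parsimony uses Sankoff dynamic programming with unordered (0/1) or ordered
(|i − j|) step matrices. Likelihood uses the Mk model: a k-state chain with
equal exchange rates beta and uniform stationary frequencies,

    P_same(t) = 1/k + (k−1)/k · exp(−k·beta·t)
    P_diff(t) = 1/k −   1/k · exp(−k·beta·t),

with Felsenstein pruning and a uniform root prior; missing terminals carry
all-ones partials. For both criteria the package precomputes per-edge
*directional* tables — the cost (or partial likelihood) of each side of
every edge conditional on the state of a node inserted on that edge — so a
query can be scored on every edge in one vectorized pass. Both step
matrices are metrics and Markov transition matrices compose along an edge,
so subdividing an edge never changes the base score; this is asserted
internally and exploited by the tests' rebuild-and-rescore oracles.

Queries attach at the midpoint of the split edge with a pendant branch
whose default length is the reference tree's mean pendant branch length
(scale-consistent, configurable).

Per-character Mk rates are fitted on the intact reference tree by bounded
1-D maximization (bounds [1e-4, 100], tolerance 1e-6) and reused unchanged
during leave-one-out calibration and placement. Because a single discrete
character's rate likelihood is ridge-shaped — beyond some rate, saturation
changes the log-likelihood by almost nothing — the fit returns the smallest
rate within 0.01 log units of the optimum (the lower edge of the
profile-likelihood plateau) rather than an arbitrary point on the ridge.

## Weight calibration

Each character earns an integer weight in [0, 100]: every reference
terminal is pruned in turn and its state for that character is scored on
every edge of the pruned tree; the character *supports* the placement when
the true attachment edge attains the optimal insertion objective, and the
weight is 100 · supporting / informative placements, rounded. A placement
is informative only if the character still varies among the remaining
terminals and its per-edge objective actually discriminates among edges; a
flat objective (a saturated character, or an autapomorphic state that adds
the same cost everywhere) carries no signal and is excluded — otherwise
noise characters would trivially "support" every edge and inherit full
weight. Characters invariant across all reference taxa are conventionally
assigned weight 100 and flagged uninformative.

Tie handling differs by criterion in a way that mirrors the structure of
each objective. Parsimony scores are integers and boundary insertions tie
exactly, so any edge attaining the minimum counts. ML attachment
log-likelihoods within one same-state region of the tree differ only by
surface roughness of order beta times branch length (~1e-4 for slow
characters), while edges in the wrong state region are worse by O(1) log
units; the ML tie window is therefore 0.01 log units — between those two
scales — so that region-level quasi-ties count as support. With a strict
(machine-epsilon) window the ML argmax simply selects the shortest edge of
the region and the weights measure edge length rather than congruence.
A consequence of the ordered ML surface is that on very small trees a
clade-congruent character is graded (intermediate weight) under ML while
parsimony pins it at 100; on realistic matrices (tens of characters,
~24 taxa) diagnostic characters calibrate to the 70–100 range under both
criteria and fast noise characters fall near 0.

## Placement, bootstrap and classification

A query's per-edge objective is the weight-weighted sum of its
per-character edge scores (total steps under MP, total attachment
log-likelihood under ML); characters missing in the query contribute an
edge-constant term and hence nothing to the ranking, so missing data are
never imputed for placement. The optimum with lowest-edge-id tie-breaking
gives the best edge. Support comes from non-parametric bootstrapping over
characters (default 100 replicates): character columns are resampled with
replacement, weights travelling with them, and an edge's support is the
percentage of replicates in which it is optimal, converted to integers by
largest-remainder rounding so supports always sum to exactly 100. One named
generator is seeded per (query, criterion) from the master seed, making
supports independent of run order.

Clade-level support is the sum of edge supports over edges whose distal
subtree lies entirely inside the named clade (pendant and internal,
including the clade's stem edge). A query is assigned to the top clade when
that support reaches the threshold (default 70), otherwise reported
"unsupported"; secondary clades at or above 5% support are listed as
alternatives. Extended clades (molecular clade plus the queries binned into
it) are built per criterion separately. Placements serialize as jplace
version 3 with `like_weight_ratio` = support/100.

## MRPP

The test statistic is delta = Σ_g C_g · x̄_g, the weighted mean
within-group pairwise distance, with natural weights C_g = n_g/N by default
(equal weights 1/G optional). The chance-corrected within-group agreement
is A = 1 − delta_obs/delta_expected, where delta_expected is the overall
mean pairwise distance among the grouped specimens — which equals the exact
mean of delta over all relabelings under either weighting, because every
pair is equally likely to fall within a group. A = 1 when groups are
internally identical, ~0 at chance, negative when groups are more
heterogeneous than chance. The p-value is purely permutational, with the
observed assignment included: p = (1 + #{delta_perm ≤ delta_obs})/(1 +
n_perm) for sampled relabelings, or the exact proportion when the number of
distinct assignments is at most 10,000 and the null is enumerated. Moment
(Pearson type III) approximations are deliberately out of scope.

Distances default to euclidean on coded states with pairwise-complete
missing-value handling: each pair is compared on characters observed in
both and the summed squared difference is rescaled by the fraction
observed. Gower (range-normalized, for mixed scales) and Bray–Curtis are
available. MRPP never imputes; "without apothecia" analyses are expressed
as character subsets in the grouping scenarios.

## Ordination

PCA uses correlation to form the cross-products matrix, so eigenvalues sum
to the number of variables and results are invariant to affine rescaling of
any variable. Constant variables are dropped with a warning; axis signs
follow the convention that the largest-magnitude loading on each axis is
positive. Missing cells are first interpolated by the taxon mean —
conspecific specimens with the value observed, type specimens preferred as
donors when flagged — and specimens with unresolvable cells are dropped (or
rejected under strict mode), mirroring the exclusion of sterile specimens
from published ordinations. Axis significance uses a randomization test
(default 999 replicates): each replicate permutes values independently
within every column, and p_k = (1 + #{lambda*_k ≥ lambda_k})/(1 + n_rand).

## Synthetic data

The generator provides a no-download test bed with known truth. Trees are
ultrametric Yule trees (in-package simulator: exponential epoch waiting
times at rate k·lambda, uniform lineage choice, a final hanging epoch;
expected root-to-tip depth Σ_{k=2..n} 1/(k·lambda), Monte-Carlo checked).
Every depth-2 node with ≥2 terminals becomes a named clade. Discrete
characters evolve by Mk simulation root-to-tips; continuous characters by
unit-variance Brownian motion, then gap coding with the reference breaks.
Queries copy a uniformly chosen clade member and take one extra
evolutionary step along a pendant branch (Mk transition, or a Brownian
increment re-coded with the same breaks), preserving the placement
problem's structure: novel but clade-faithful phenotypes.

Default conditions: 24 reference taxa, birth rate 1.0 (total tree length
≈ (n−1)/lambda ≈ 23 expected substitutions, so a rate-0.05 character
changes ~1.2 times across the whole tree — genuinely diagnostic — while a
rate-1.0 character is saturated noise); 60 characters split 30 diagnostic
(rate 0.05) and 30 homoplastic (rate 1.0); state counts distributed
{2: 0.5, 3: 0.3, 4: 0.2}; 30% of characters form an "apothecia" block that
goes missing wholesale for a specimen with probability 0.3 (the sterile-
specimen pattern; empirical matrices of this kind have ~30% apothecial
characters and frequent sterility); two queries per clade with pendant
length defaulting to the tree's mean pendant. All randomness flows from one
master seed through named child generators, so tree, matrix and queries
are byte-reproducible.

What passing tests show — and what they do not: the generator's characters
are independent given the tree, missingness is independent of phenotype,
and queries are single-step derivatives of sampled tips. Real matrices
have correlated characters, missingness confounded with taxon identity,
and queries of uneven divergence; recovery rates measured here are
therefore an upper bound on what comparable real data would give.

## Problem sizes in the shipped checks

The end-to-end recovery check aggregates five seeded datasets of the
default condition (60 classifications across ML and MP); MRPP null
calibration uses 200 relabelings of a 40 × 20 matrix; exhaustive MRPP
checks run at n ≤ 8; placement oracles at ≤ 6 taxa; the PCA randomization
at 999 replicates. These sizes keep the full suite fast while leaving every
statistical assertion comfortably powered.

## Known limitations

- No gamma rate heterogeneity, asymmetric step matrices, or
  ascertainment-bias (Mkv) correction in the Mk model.
- ML calibration weights depend on the 0.01 tie window; the window is a
  scale choice, defensible but not unique, and on very small trees ML
  weights are conservative.
- The weight formula itself (leave-one-out support fraction) is one
  reasonable operationalization of "weight calibration"; placement tools
  embedded in phylogenetics packages may calibrate differently, so
  absolute weights are comparable within a run, not across tools.
- MRPP p-values are permutational only and bounded below by
  1/(n_perm + 1); published values from moment approximations
  (e.g. p ≈ 1e-7) cannot be matched by permutation at feasible sizes.
- The NEXUS reader accepts only the documented CHARACTERS-block dialect
  (SYMBOLS 0–9, MISSING ?), not the full grammar.
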
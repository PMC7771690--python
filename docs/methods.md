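# Methods

## The model

`metabotree` treats an organism as the set of metabolic reactions its genome
encodes (a draft genome-scale reconstruction) and builds organism trees from
two similarity measures over those sets.

**Binary fingerprint.** The Jaccard index J(A,B) = |A∩B|/|A∪B| over reaction
presence vectors. Reactions absent from both organisms of a pair carry no
information and cannot change the score; columns empty across the whole
loaded set are dropped before comparison but retained in the catalog. A pair
of all-empty fingerprints is an error rather than similarity 0: an organism
with no reactions cannot be placed by any downstream clustering.

**Enzyme-sequence similarity.** Per reaction shared by a pair, all enzyme
sequences on one side are aligned against all on the other with exact
Smith–Waterman local alignment (no heuristics) and the raw score is
normalized by the *query's* self-alignment score. This makes the directed
score a fraction of the query's maximal attainable score, and makes
S(A→B) ≠ S(B→A) when lengths differ. The reaction score is the maximum over
all enzyme pairs: isozymes and complex subunits are allowed to match on
their best representative, independent of how many sequences are present.
Organism-level similarity averages the reaction scores over n_R
contributing reactions:

- shared reaction → its alignment score;
- reaction in exactly one organism → the penalty value p (mode `value`), or
  excluded (mode `ignore`);
- reaction in neither → always excluded. This exclusion is forced by the
  worked example: with it, the ignore-mode average is the mean of the four
  shared scores (0.86) and the penalty averages equal (3.44 + 4p)/8.

Organism-level matrices are symmetrized as the mean of the two directed
scores because UPGMA needs symmetric input; both directed values are
available from the per-pair score tables, and the symmetrization is recorded
in the matrix metadata. Scores are not clamped: a negative penalty can drive
⟨S⟩ below zero, which the distance transform simply maps above 1.

## Alignment parameters

BLOSUM50 with gap opening and extension costs both 8 (a linear gap model),
matching the defaults of the classic local-alignment implementations this
mirrors; both costs and the matrix name are configurable. The implementation
is Biopython's `PairwiseAligner` in local mode; the test suite checks it
against an independent full-DP oracle, including the classic
HEAGAWGHEE/PAWHEAE pair whose BLOSUM50 linear-gap-8 score is 28.

## Trees

Distances are d = 1 − s, the simplest monotone map consistent with
similarities in [0, 1]; negative similarities give distances above 1, which
UPGMA handles unchanged. UPGMA is implemented directly so tie-breaking is
deterministic: among equally close cluster pairs, the pair with the
lexicographically smallest (min-label, min-label) key merges first, and
equal-distance merges resolve sequentially, so trees are binary and
bit-reproducible across platforms (cross-checked against SciPy average
linkage on matrices with distinct distances). Node height is half the merge
distance, so trees are ultrametric. Trees are kept canonical — children of
every node ordered by smallest contained leaf label — which gives each
topology a unique Newick form. Newick parsing is delegated to dendropy;
writing is a direct emitter.

## Tree similarity K

Binary mode: a leaf scores 1 iff its parent clade (the smallest clade
properly containing it) has the same leaf set in both trees; K is the mean
over leaves. Weighted mode enumerates all N−1 internal-node clades of the
first tree per leaf, ordered by increasing topological distance (edge count)
from the leaf with ties broken by clade size and then sorted leaf labels,
and scores the η-th clade with weight (N−η)/(N−1) when its leaf set occurs
anywhere in the second tree; the weights sum to N/2, so F(ξ) = (2/N)·Σ is 1
for identical trees. Two deliberate choices here:

- *Proximity ordering.* The enumeration walks outward from the leaf
  (nearest branch first), so local disagreement costs more than disagreement
  near the root. Under this ordering the antisymmetric four-leaf case
  ((A,B),(C,D)) vs ((A,C),(B,D)) scores K = 1/3: only the root clade
  matches, and it is the second-nearest node of every leaf.
- *Match-anywhere criterion.* A clade of tree A counts when its leaf set
  occurs as a clade anywhere in tree B, since node positions are not
  comparable across topologies. A consequence worth knowing: the η = 1 term
  is an upper bound on, not equal to, the binary statistic — a leaf's parent
  clade can occur in the other tree around a different neighborhood.

The weighted per-leaf sums are accumulated as integers before the final
division so K(T, T) is exactly 1.

## Noise model

At level ζ each organism swaps reactions for uniformly chosen absent ones,
conserving its reaction count. Default mode swaps exactly round(ζ·R_i)
reactions (the deterministic count makes small-fixture tests sharp; at
R_i = 1,743 and ζ = 0.01 this is exactly 17 swaps); a Bernoulli mode
(each present reaction swapped independently with probability ζ) is
retained. Removals and additions are drawn without replacement within a
replicate, so a removed reaction cannot return in the same instance. One
perturbed matrix instance feeds all pairwise comparisons of a replicate.
Each ζ gets an independent child RNG stream spawned from the seed, so
results for one ζ do not depend on which others are requested.

## Penetration

Class boundaries follow the strict wording "less than 10%" / "more than
90%": LP iff fraction < 0.10, HP iff fraction > 0.90, MP iff
0.35 ≤ fraction ≤ 0.65. Fractions in [0.10, 0.35) and (0.65, 0.90] belong to
no named class and are reported as a residual UNCLASSIFIED class, including
in per-organism composition tables (rows sum to 1). Reactions present in no
loaded organism are excluded from penetration statistics but stay in the
catalog, where the null model may draw them. The null model draws, per
replicate and organism, R_i reactions uniformly without replacement from the
catalog; the per-reaction expected count is Σ_i R_i/R_T with variance
Σ_i p_i(1−p_i), p_i = R_i/R_T, which the tests use as the analytic oracle.

## Synthetic fixtures

The clade generator plants three strata: `n_core` reactions in every
organism (fraction 1 → HP), `n_clade` reactions per internal grouping of
the clade tree (a 50%-of-organisms clade → MP), and `n_private` reactions
per organism (→ LP in sets of ≥ 11 organisms). Defaults (40/10/3) give each
organism a realistic mix dominated by shared reactions with a visible
private tail. The two-clade helper splits each clade by recursive halving
rather than as a deep caterpillar: with constant per-level reaction counts,
UPGMA's cluster-average distances do not recover caterpillars beyond depth
≈ 4, whereas balanced sister groups are recovered exactly — a property the
topology-recovery tests rely on.

Sequences start from a uniform random root sequence per reaction
(default length 120) and accumulate independent per-site substitutions
(probability 0.05 per edge, uniform over the 19 alternative residues) down
the clade tree, so within-clade pairs share more substitution history than
cross-clade pairs. This is deliberately minimal: no indels, no rate
heterogeneity, no substitution-matrix-weighted mutation. Passing tests on
these fixtures demonstrate that the pipeline's arithmetic and orderings are
right and that clade signal is recovered when it exists; they do not show
robustness to the gap structure, domain shuffling or annotation biases of
real enzyme data.

## Problem sizes and determinism

The test and acceptance runs use desk-scale sizes chosen to exercise every
code path: 16–20 organism fixtures, Monte-Carlo replicate counts of 200
(tree stability) and 1,000 (penetration null), 50 random alignment pairs up
to length 40, and 100 random trees of 4–32 leaves. All randomness flows
through seeded numpy generators; every report records its seed, and repeated
runs are bit-identical.

## Known limitations

- All-against-all alignment is exact DP and scales quadratically in both
  organism count and sequences per reaction; whole-proteome comparisons of
  hundreds of organisms call for batching or heuristics out of scope here.
- The 1 − s distance transform and the mean-of-directions symmetrization
  are conventions; alternatives (e.g. max/min of directions) would shift
  branch lengths but rarely topology.
- Multifurcations are never produced; equal-distance merges resolve into an
  arbitrary-but-deterministic binary order, so K between trees built from
  tie-heavy matrices reflects that convention.
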
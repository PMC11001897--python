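# Methods

## The prediction problem

A candidate 6mA site is represented by a fixed 41-nt window (2L+1 with
L = 20) with the putatively modified adenosine at position 21 (1-based).
The model assumes fixed-length windows over {A, C, G, U} — DNA-alphabet
input is coerced T→U at load time — and a binary label: 1 for a
methylated central A, 0 otherwise. Windows violating the contract
(wrong length, ambiguous bases, non-A center) are skipped with a logged
reason rather than aborting a load, because supplementary sequence
files are routinely messy. Duplicate removal is exact: first occurrence
of each (sequence, label) pair is kept, and sequences appearing under
both labels are retained but flagged, since they are evidence of
conflicting annotation rather than redundancy. No similarity-based
homology clustering is performed.

## Encoding

The 522-feature descriptor combines composition and position signals.

**Frequency vector (84).** Overlapping k-mer counts for k = 1, 2, 3 in
lexicographic (A, C, G, U) order. Conservation: the blocks sum to 41,
40, 39 for any window.

**AAPIV / RAAPIV (84 + 84).** For each k-mer, the sum of the 1-based
start positions of its occurrences; the mono block always sums to
861 = 41·42/2. RAAPIV is the same computed on the reversed sequence,
capturing 3'-anchored positional structure.

**PRIM / RPRIM (90 + 90).** The position-relative incidence matrix at
k = 1, 2, 3 (4×4, 16×16, 64×64). The entry convention is fixed as
entry(i→j) = Σ_q (q − f_i) over occurrences q of target k-mer j, with
f_i the first occurrence of source k-mer i; contributions from
occurrences preceding f_i enter with negative sign, and rows/columns of
absent k-mers are zero. This convention is one of several defensible
readings of "position-relative incidence"; it was chosen because it is
deterministic, O(4^k + n) to compute, and verifiable by brute force.
RPRIM is PRIM of the reversed sequence.

**2D sequence matrices (90).** The k-mer stream is integer-encoded
1..4^k and written row-major into the smallest enclosing square (7×7
for a 41-nt window at every k), zero-padded at the tail.

**Moment reduction.** Each of the nine matrices (3 PRIM, 3 RPRIM, 3
2D) is compressed to 30 scalars: raw moments E_jk = Σ_c Σ_d c^j d^k
β_cd and central moments about the mass centroid, both over 1-based
coordinates, plus discrete Hahn moments on the 0-based support, for
all orders j+k ≤ 3 in the fixed index order (0,0), (0,1), (1,0),
(1,1), (0,2), (2,0), (1,2), (2,1), (0,3), (3,0). Ten coefficients per
family is the unique reading consistent with a 90-feature block per
three-matrix family.

## Hahn moments: numerical choices

The Hahn polynomial evaluator follows the three-parameter 3F2 form
common in the discrete-orthogonal-moments literature, with Pochhammer
symbols read as rising factorials and shape parameters u = v = 0 by
default (uniform weight; configurable via `HahnParams`). Evaluated
term-by-term at face value, that family spans the polynomials of each
degree but is *not* numerically orthogonal — no positive diagonal
weight orthogonalizes it, which we established by exact linear algebra
at small N. Orthogonality is what gives Hahn moments their
reversibility, so the moment transform uses the orthonormal basis
obtained by weighted Gram–Schmidt of the family in degree order. That
basis coincides, up to sign, with the classical discrete orthonormal
Hahn functions (the test suite verifies this against an
exact-rational-arithmetic classical Hahn oracle), and it makes the
full-order transform exactly invertible: B = Qᵀ H Q. Rows are
sign-fixed (non-negative leading difference) so the basis is
deterministic. Rectangular matrices are zero-padded bottom/right to a
square before the transform. Basis matrices are cached per (N, u, v).

Degenerate inputs: a matrix with zero total mass has no centroid; its
central-moment block is substituted with zeros and a warning is logged
(signed PRIM entries can legitimately cancel), rather than failing the
whole encoding.

## Ensembles

All learners are scikit-learn estimators seeded from the config.
Stacking uses KNN (k = 5), a decision tree, an MLP (one hidden layer of
64 units), and an RBF-SVM as base learners; their out-of-fold outputs
(5-fold, stratified, seeded) train a gradient-boosting meta-learner, so
no base prediction used for meta-training comes from a model that saw
the row. KNN, SVM and MLP sit behind a standardization step fit on
training folds only; tree-based learners are left unscaled, as is
conventional. Features are emitted unscaled by the encoder so that it
stays a pure function of the sequence.

Hyperparameter tuning is off by default; when enabled it grid-searches
small documented grids (tree depth {3, 5, 10, none}; boosting learning
rate {0.05, 0.1, 0.2} and estimators {100, 300}; forest estimators
{100, 300}) by seeded 5-fold CV. The defaults are the library defaults
of each estimator. Gradient boosting is exposed as the headline
variant, being the strongest performer of the three families.

## Evaluation

Sn = TP/(TP+FN), Sp = TN/(TN+FP), ACC = (TP+TN)/n,
F1 = 2TP/(2TP+FP+FN), MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)),
and AUROC from continuous scores (equal to the Mann–Whitney pairwise
probability with ties counted ½). Ratios with zero denominators are
reported as explicitly undefined with a reason — never silently zero,
which would corrupt model comparisons. The decision threshold is 0.5.

The independent protocol is a stratified split (default 70/30, seeded).
The k-fold protocol (default k = 10, stratified, seeded) reports pooled
(micro-averaged) confusion counts as the headline, with per-fold
metrics retained for dispersion; pooling is our aggregation choice
since each sample is tested exactly once.

## Synthetic data

The generator emulates labeled benchmark windows: negatives are drawn
uniformly (¼ per base, center forced to A), positives from a
per-position probability profile. The planted profile phases a fixed
GGACU consensus — the DRACH-like sequence context associated with
adenosine methylation — so that the center falls on its A; at strength
s each non-center position gives the consensus base probability
(1−s)/4 + s. Strength 0 is indistinguishable background; strength 1 is
a deterministic, perfectly separable motif. The default strength is
0.9: strong planted signal, chosen so that even a single-feature
decision stump separates the classes on held-out data, which the tests
verify directly.

What the generator does not emulate: genomic k-mer composition bias,
shared flanking context between near-duplicate sites, species mixtures,
and label noise. Passing benchmarks on synthetic data therefore
demonstrate that the pipeline preserves and recovers planted positional
composition signal — not that real 6mA sites are predictable at these
accuracies; published benchmark performance depends on the curated
datasets, which ship separately.

## Problem sizes

The behavioral benchmarks use 1,000 windows per class (70/30 split) for
the strong-signal check, 100 per class for the no-signal 10-fold
control, and 100 per class across five seeds and four signal strengths
for the AUROC monotonicity sweep; these sizes give binomial standard
errors small enough for the stated bounds while keeping the full suite
fast on a single CPU.

## Known limitations

- The PRIM entry convention and the k-mer ordering are fixed choices
  among several defensible ones; absolute feature values are not
  comparable across tools that chose differently.
- Hahn moments at u = v = 0 weight the support uniformly; heavy-tailed
  weights (u, v > 0) are available but untested against real data.
- Exact-duplicate removal does not remove near-duplicates; reported
  cross-validation numbers on redundant real datasets will be
  optimistic.
- The stacking ensemble is markedly slower to train than the other
  families (nested out-of-fold fitting of four base learners).
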
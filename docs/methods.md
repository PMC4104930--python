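# Methods

## Models

All regressors are linear ε-insensitive support vector machines.  The
single-task primal is

    min_w  ½‖w‖² + C Σᵢ ℓ_ε(w·xᵢ, yᵢ),      ℓ_ε(ξ, y) = max(|ξ − y| − ε, 0)^p

with p = 2 by default (L2 loss models the mean squared error directly; L1 is
available).  Features are expected non-negative and unit-normalized, so the
linear kernel coincides with the cosine kernel and dot products live in
[0, 1].  No bias term is regularized: labels are centered before the solve
and the mean is carried as the model offset.  A regularized-bias switch
(constant-feature augmentation) exists for the graph method, where per-task
biases can matter when tasks differ in their average potency.

**Dual coordinate descent.**  The L2-loss dual
½βᵀQβ + Σᵢ(ε|βᵢ| − yᵢβᵢ + βᵢ²/4C) is minimized coordinate-wise with exact
one-dimensional soft-threshold updates; L1 loss replaces the quadratic term
with the box |βᵢ| ≤ C.  The coordinate order is re-permuted every epoch from
an explicit integer seed, making runs bit-reproducible.  Optional
per-instance linear terms pᵢ (the dual then carries −Σβᵢpᵢ, i.e. effective
labels yᵢ + pᵢ) support the top-down node problems.  The sign convention is
fixed by the primal: the node trainer passes pᵢ = −B·(w_p·xᵢ) and recovers
the full node weight w = u + B·w_p from the shifted-label solution u; the
equivalence is enforced by dense-oracle tests rather than assumed.

**Graph-regularized multi-task SVR.**  Task similarities form a symmetric
non-negative adjacency A (diagonal conventionally 1; it cancels in
L = D − A, which the tests assert).  The joint regularizer
¼ΣₛₜA_st‖wₛ−wₜ‖² = ½ΣₛₜL_st wₛ·wₜ yields, in the block-vector view, the
dual kernel Q_ij = M_{tᵢtⱼ} xᵢ·xⱼ with M = (I_T + L)⁻¹.  M is obtained once
per fit by a symmetric positive-definite (Cholesky) solve, never by explicit
inversion of anything ill-conditioned; I_T + L is positive definite for any
valid A.  The coordinate-descent loop maintains both the per-task dual
accumulations vₜ = Σ_{tᵢ=t} βᵢxᵢ and the model weights wₜ = Σₛ M_{ts} vₛ
incrementally (O(Tn) per update).  Labels are centered by the global mean
over all tasks — per-task centering would change the model class; datasets
whose tasks differ strongly in mean label should consider the
regularized-bias switch instead.

**Top-down multi-task SVR.**  Given a rooted taxonomy whose leaves are the
tasks, one model per node is trained breadth-first.  The root (B ignored,
zero parent) is exactly the pooled 1SVM; each descendant minimizes
(1−B)/2‖w‖² + B/2‖w−w_p‖² + C Σ_{i∈S}ℓ_ε on the instances of its subtree,
with labels centered per node.  Prediction for a task uses the leaf's full
weight plus the leaf offset — the convention consistent with the node
primal's loss argument ξᵢ = w·xᵢ and with the B = 0 ⇒ independent-model
property; the alternative convention of summing node and parent weights at
prediction time is inconsistent with that property but is exposed as a
compatibility switch (`literal_parent_sum`).  A node whose subtree has no
training instances (a held-out novel target) inherits its parent's model,
the limit of the node problem at B = 1 with no loss term.

**Pull strengths B.**  TDMTtax takes B from the taxonomy edge weights,
scaled into [0, 1] by the maximum weight (a no-op when weights are already
calibrated).  TDMTgs runs a local grid search per node: (B, C) by inner
cross-validation against the fixed parent, ties broken toward smaller B and
then smaller C (our convention — the smaller pull and the smoother model are
the conservative choices).  Negative-transfer prevention adds B = 0 to leaf
grids; it is off by default because on the benchmark it usually costs more
than it saves for the taxonomy-parameterized variant, and the grid-search
variant already contains B = 0.

## Task similarities and taxonomies

A weighted taxonomy converts to a similarity matrix via patristic (shortest
path) distances, normalization by the maximum off-diagonal distance (so the
most distant pair gets similarity exactly 0) and s = 1 − d, diagonal 1.  An
override list forces named "atypical" tasks to similarity 0 against
everyone, regardless of distances.  Newick parsing/writing delegates to
dendropy; strict mode rejects missing branch lengths, lenient mode defaults
them to 1.0 (the convention for attaching distant outlier tasks to the
root).  UPGMA construction from a correlation matrix runs average-linkage
agglomeration on 1 − r and emits an ultrametric tree (equal root-to-leaf
depths, asserted by tests).

## Simulation benchmark

The generator emulates a controlled multi-task regression world: D
categorical attributes with 6 levels, one-hot encoded (instances are binary
vectors of length 6D with exactly D ones, attribute levels drawn uniformly);
task models drawn attribute-wise from Gaussians with means
(−β, −2β/3, −β/3, β/3, 2β/3, β) and variance σ²; targets y = wₜ·x exactly,
with no label noise.  β = 3 throughout (low noise); σ² = 0.5β gives the
high-task-similarity regime and σ² = 3β the low one.  Under the high/low
settings with T = 10, D = 10 the mean pairwise cosine between task weights
concentrates near 0.76 / 0.34 and the mean pairwise Pearson correlation of
targets on common instances near 0.79 / 0.38 (the population value of the
latter is Σμ_k² / (Σμ_k² + 5σ²) per attribute, i.e. 0.862 and 0.384).
Similarities fed to the algorithms come from the generating weights:
pairwise cosines for the graph method (negative cosines clipped to 0, as the
adjacency must be non-negative; raw values retained for reporting), and a
star taxonomy whose root is the mean-of-Gaussians model with edge weights
cos(wₜ, w_mean) for the top-down method.  "anti" (1 − cos) and "random"
(uniform [0, 1], unit diagonal) variants probe robustness to wrong
similarity inputs.

What the generator does *not* emulate: sparse hashed fingerprints with
feature collisions, assay noise and inter-laboratory heterogeneity in the
labels, task-dependent label means, and non-uniform chemical-space coverage.
Passing benchmark tests therefore demonstrates correctness and the
qualitative transfer-learning behavior, not expected performance on real
bioactivity panels.

## Evaluation harness

Splits are generated once and shared by every algorithm, so per-(task,
split) MSEs are paired by construction.  Hyperparameters use the grids
log₂C ∈ {−5, −3, …, 7} (a coarser high-C grid {2, 4, 6, 8} is provided for
graph training with very many tasks) and B ∈ {0, 0.1, 0.25, 0.5, 0.75, 0.9,
1}; ε is fixed at 0.1 pIC50 units, the scale of a 25% relative IC50 assay
deviation (log₁₀ 1.25 ≈ 0.1).  Inner-CV folds are seeded and stratified by
task.  Model-selection ties go to the smallest C (and smallest B).

Leave-one-sequence-out holds out all training data of one task, keeps its
fixed test set, and redistributes its training budget uniformly over the
remaining tasks (remainder to the largest pools, ties to the lowest id) so
the total training size matches the standard protocol.  The graph method
drops the held-out task's ridge term — its identity contribution is removed
from block(I_T + L) while all coupling terms remain, so the held-out weight
is interpolated from its neighbors; the modified system must stay positive
definite (a task with no effective similarity edges is rejected, and the
harness skips the graph method for held-out tasks with all-zero similarity).
The top-down method predicts a held-out leaf through its parent.

Significance: two-sided Wilcoxon signed-rank per task on paired MSEs (exact
for ≤ 25 pairs without ties, continuity-corrected normal approximation
otherwise), corrected across the comparison family by Holm (family-wise) or
Benjamini–Hochberg (FDR 5%); tasks are labeled Better/NoChange/Worse for the
first algorithm by the sign of the median paired difference among
significant results.  All-zero difference vectors get p = 1 and a
degenerate flag.

## Numerical choices and defaults

- Solver tolerance 1e-3 on the maximum projected-gradient violation,
  *scaled by the label magnitude* (gradients are label-scaled, so an
  absolute threshold would be arbitrarily strict or loose); cap 1000 epochs.
  Non-convergence raises a warning and flags the result — at the largest
  grid C values on nearly noise-free data the dual is ill-conditioned and
  the cap can bind during cross-validation, which affects model selection
  only marginally.  Tests that assert oracle agreement run at tolerance
  1e-9 with a high epoch cap.
- Coordinate order is permuted per epoch from the run's seed; a global seed
  fans out to independent substreams for every sampling step (weights,
  per-task train draws, test draws), so each component is independently
  reproducible.
- Shrinking heuristics are deliberately omitted: correctness and
  readability over speed at desk scale.  The inner loops are JIT-compiled
  with numba when available, with a pure-Python fallback.
- Instances with identical features and conflicting labels are legal; the
  convex solver handles them.
- Fingerprint folding is id mod 2^bits with presence (binarized)
  semantics; the collision fraction is reported.  The frequent-feature
  filter removes features present in strictly more than the threshold
  fraction (default 90%) of compounds and stores the kept-column mapping
  for held-out data.
- Curation computes geometric means of repeated pIC50 values exactly as
  stated in the protocol it reproduces, although pIC50 is already a log
  quantity — a faithful-reproduction choice, not a statistical
  recommendation.
- k-medians chemotype clustering uses random distinct medoid
  initialization, 10 restarts keeping the best assignment cost; the elbow
  for k is the largest second difference of the within-cluster sum of
  squares over the candidate range.
- Problem sizes in the shipped experiments (e.g. 10 splits of T = 5, D =
  14, N = 45 for the similarity-robustness study; N up to 90 for learning
  curves) were chosen as the smallest settings at which the documented
  qualitative patterns are stable across seeds.

## Known limitations

- Linear models only; no nonlinear kernels and no classification SVMs.
- Task similarities are consumed, not learned; adjacency inputs must be
  symmetric and non-negative.
- The curation module operates on structured activity records; database
  retrieval, structure standardization and fingerprint generation belong to
  external tools (raw circular-fingerprint ids are accepted from any
  generator, with optional rdkit support).
- The grid-search top-down variant can overfit (B, C) on very small nodes —
  the taxonomy-parameterized variant, which only searches C, is the safer
  default on small panels.
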
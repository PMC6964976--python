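# Methods

## Problem and model

The package recovers a binary drug–target interaction (DTI) matrix from
partial observations. Rows are drugs, columns are targets; an observed 1
is an experimentally known interaction, an observed 0 a presumed
non-interaction, and unobserved entries are what the method ranks. The
working assumptions are

1. **Low rank** — interactions are driven by a small number of latent
   factors, so the complete matrix `X` is approximately low-rank. The
   nuclear norm `‖X‖_*` (sum of singular values) is the convex surrogate
   used in place of rank.
2. **Local invariance on two graphs** — drugs that are similar should
   have similar interaction profiles, and likewise for targets. This
   enters as trace penalties `Tr(Xᵀ L_d X)` and `Tr(X L_t Xᵀ)` with graph
   Laplacians over the drug and target similarity graphs.

The objective is

```
min_X ‖A ∘ (M − X)‖²_F + λ‖X‖_* + μ₁ Tr(Xᵀ L_d X) + μ₂ Tr(X L_t Xᵀ)
```

with `A` the binary observation mask. All terms are convex, so the
minimizer is global and independent of initialization.

## Similarity fusion

Each side contributes five similarity matrices: the *standard* similarity
(chemical structure for drugs, e.g. SIMCOMP; normalized Smith–Waterman
sequence similarity for targets), supplied as input and never computed
here, plus four similarities derived from the interaction profiles
themselves — cosine, Pearson correlation, Hamming (1 − fraction of
differing positions) and Jaccard (matching nonzero positions over union
support). Degenerate profiles (an all-zero row for a cold-start drug, a
constant vector for the correlation) are assigned similarity 0, deferring
entirely to the standard similarity.

The five matrices are combined by a weighted sum. Default weights are
`{standard: 1, cosine: 4, correlation: 4, hamming: 1, jaccard: 4}`:
cosine, correlation and Jaccard carry four times the weight of Hamming,
which contributes the least predictive signal of the four; the standard
similarity's weight is a free parameter defaulting to 1. Negative
combined entries (possible through correlation/cosine) are clipped to 0
so the combination is a valid set of graph weights.

The combined similarity is then sparsified to a p-nearest-neighbor graph:
entry (i, j) keeps factor 1 if i and j are mutually among each other's p
nearest neighbors, 0.5 if only one-sided, 0 otherwise; the diagonal is
kept. Ties in the neighbor ranking break by ascending index so the
operation is deterministic. Sparsification is applied once, to the
combined matrix, not per similarity. Finally `L = D − S` with
`D_ii = Σ_j S_ij`; by default the normalized form `D^{−1/2} L D^{−1/2}`
is used (eigenvalues in [0, 2]; zero-degree nodes get a zero scaling
entry). Summing Laplacians of individual similarities and taking the
Laplacian of the summed similarity are algebraically identical, which the
tests verify.

## Solver

Variable splitting introduces `Y ≈ X` and `Z ≈ Xᵀ`:

```
min ‖A∘(M−X)‖²_F + λ‖X‖_* + μ₁Tr(Z L_d Zᵀ) + μ₂Tr(Y L_t Yᵀ)
    + ν₁‖Zᵀ−X‖²_F + ν₂‖Y−X‖²_F
```

and the blocks are updated in alternation, starting from `Y = M`,
`Z = Mᵀ`, `X = M`:

* **X-update.** Minimizing over X is a nuclear-norm problem with the
  quadratic data term `‖A∘(M−X)‖² + ν₁‖Zᵀ−X‖² + ν₂‖Y−X‖²` (the
  column-stacked system). It is solved by proximal gradient (singular
  value shrinkage, SVS): a gradient half-step with inverse step size
  `a = 1 + ν₁ + ν₂` (which majorizes the quadratic, whose elementwise
  curvature is at most `2(1 + ν₁ + ν₂)`), then soft-thresholding of the
  singular values at `λ / (2a)`. The inner solve warm-starts from the
  current X and runs to its own tolerance (1e-8 relative by default).
* **Y/Z-updates.** Setting the Y-gradient to zero gives
  `ν₂Y + μ₂Y L_t = ν₂X`, a right-sided Sylvester equation whose left
  coefficient is scalar; the closed form `Y = ν₂X(ν₂I + μ₂L_t)^{-1}` is
  computed with one symmetric positive definite solve (the matrix is
  `νI + μL` with L PSD, hence nonsingular for ν > 0). The Z-update is the
  transposed analogue with `(ν₁, μ₁, L_d)`.

Each update minimizes its block exactly (the X-update monotonically), so
the splitting objective is non-increasing; the iteration halts when its
relative change falls below `tol` (default 1e-6) or after `max_iter`
(default 500) outer iterations.

**Nonnegative projection.** Scores are interaction propensities, so the
returned estimate is projected onto the nonnegative orthant. The
projection is applied once, to the converged estimate, not inside the
iteration: shrink-then-clip is not the proximal operator of the
nuclear norm plus a nonnegativity constraint, and applying it per
iterate both perturbs the fixed point away from the convex minimizer and
permits small objective upticks. Projecting only the final estimate keeps
every iteration an exact proximal step (objective provably monotone, the
μ = 0 case numerically identical to plain SVS) and cannot change the
ranking among retained scores. A `nonneg` flag disables it.

Plain nuclear-norm completion (`svs_solve`) is the same proximal loop
with no proxy terms (`a = 1`, threshold `λ/2`) and serves both as the
baseline and as the reference for the μ₁ = μ₂ = 0 reduction test.

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| λ | nuclear-norm weight | 1.0 | larger → lower-rank, smoother scores |
| μ₁ | drug-graph weight | 0.5 | best reported regime on the GPCR benchmark |
| μ₂ | target-graph weight | 0.1 | idem |
| ν₁, ν₂ | splitting penalties | 1.0 | affect the path, not the minimizer |
| p | nearest neighbors kept | 5 | graph sparsification |
| tol | outer stop tolerance | 1e-6 | relative objective change |

Grid search (`grid_search`) scans any subset of these, scoring each
point by mean cross-validated AUPR; to avoid optimistic bias it should be
run on the training portion only, with a separate held-out evaluation.

## Evaluation protocol

Three cross-validation settings, each as k-fold CV (default 10 folds,
5 runs): **CVS1** masks random drug–target pairs, **CVS2** masks whole
drug rows (novel drugs), **CVS3** masks whole target columns (novel
targets). Training zeros are treated as observed non-interactions
(mask 1); test entries are unobserved (mask 0). Within every fold the
four interaction-derived similarities are recomputed from the training
matrix only, so no test label reaches the graphs; a
`similarity_from_full` flag reproduces the variant computed once from the
full matrix. Metrics are AUPR (non-interpolated step-curve area,
equivalently mean precision at positive ranks) and AUC (Mann–Whitney,
ties counted ½), computed per fold and aggregated as mean ± sd across all
folds of all runs. A fold whose test labels are single-class is skipped
with a logged warning — on networks as small as the nuclear-receptor
benchmark (90 positives) this can occur. AUPR is preferred over AUC for
DTI because high-ranked false positives are the expensive errors.

## Synthetic data generator

The generator produces datasets with exactly the structure the method
exploits, so that the benefit of graph regularization is testable.
Drugs and targets are assigned to clusters (defaults: 4 drug, 3 target
clusters); nonnegative latent factors of dimension `latent_rank` are
drawn around gamma-distributed cluster centroids (shape 2, scale 1) with
Gaussian jitter (sd 0.25) clipped at zero. The propensity matrix is
`P = UVᵀ / max(UVᵀ)` — a positive monotone squashing that preserves
`rank ≤ latent_rank` — and the interaction matrix sets to 1 exactly the
`round(density·n·m)` largest entries of P, then flips each label
independently with `label_flip_rate`. Side similarities are latent-factor
cosine similarities (in [0, 1] since the factors are nonnegative, unit
diagonal), hence genuinely informative about the low-rank signal.

What the generator does *not* emulate: the extreme sparsity and
block-structured bias of curated interaction databases, similarity
matrices estimated from chemistry or sequence (here the graphs are
exactly consistent with the latent factors, an upper bound on how
informative real side information is), and drugs/targets absent from the
similarity universe. Tests that pass on this generator therefore
demonstrate correctness of the machinery and the direction of the
graph-regularization effect, not performance levels on real benchmark
data; real Yamanishi-format files can be supplied to the same API and
CLI.

Default study conditions used in tests and in `scripts/acceptance.py`:
60 drugs × 30 targets, rank 3, density 0.15, flip rate 0.05, 30% of
entries held out, 10 seeds — small enough to run a full sweep in seconds,
large enough that AUPR differences of ~0.01 are stable across seeds.

## Numerical choices and limitations

* Inverse step size `a = 1` for plain SVS (`a = 1 + ν₁ + ν₂` stacked) is
  the largest monotone step for the masked quadratic; `step < 1` is
  rejected.
* Soft-threshold level is `λ/(2a)`, consistent with the squared-loss
  convention.
* X is initialized to the observed matrix; since the objective is convex
  the converged solution does not depend on this.
* p-NN ties and fold partitions are deterministic given the seed;
  identical seeds reproduce reports bit-exactly.
* AUPR is undefined without positives and AUC without both classes; such
  inputs raise rather than returning a silent default.
* Dense SVD per inner iteration bounds practical problem sizes to a few
  thousand rows/columns; no randomized SVD path is provided.
* The solver returns continuous propensities, not calibrated
  probabilities; only the ranking is meaningful.
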
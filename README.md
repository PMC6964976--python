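# mgrnnm

Drug–target interaction (DTI) prediction by **multi-graph regularized
nuclear norm minimization**.

Experimentally validating drug–protein interactions is slow and expensive,
so computational screening is used to rank candidate pairs before wet-lab
work. This package treats the problem as matrix completion: the known
interactions form a partially observed binary matrix `M` (rows = drugs,
columns = targets) assumed to be low-rank, and the unobserved entries are
recovered as continuous interaction propensities. On top of the low-rank
prior, the recovery is regularized by graph Laplacians that pull similar
drugs (and similar targets) toward similar interaction profiles — using
not one but five similarity measures per side: the standard chemical
structure / genomic sequence similarities plus cosine, Pearson
correlation, Hamming and Jaccard similarities computed from the
interaction profiles themselves.

## Model

With sub-sampling mask `A`, combined drug Laplacian `L_d` and combined
target Laplacian `L_t`:

```
min_X  ‖A ∘ (M − X)‖²_F + λ‖X‖_* + μ₁ Tr(Xᵀ L_d X) + μ₂ Tr(X L_t Xᵀ)
```

where `‖X‖_*` is the nuclear norm (sum of singular values, the convex
surrogate for rank). `L_d` and `L_t` are built by summing the five
weighted similarity matrices per side, sparsifying the combined similarity
to a p-nearest-neighbor graph, and (by default) normalizing
`L = D − S` to `D^{−1/2} L D^{−1/2}`.

The problem is solved by variable splitting (ADMM): proxies `Y ≈ X` and
`Z ≈ Xᵀ` decouple the terms so that each block update is cheap —

* **X-update**: a stacked nuclear-norm problem solved by singular value
  shrinkage (a masked gradient step followed by soft-thresholding of the
  singular values);
* **Y/Z-updates**: Sylvester equations `νT + μTL = νC` whose left
  coefficient is scalar, solved exactly with one symmetric positive
  definite factorization.

Every block update decreases the convex splitting objective, so the
recorded objective history is monotone.

Plain nuclear-norm completion (`svs_solve`) is included as the baseline
and is exactly the `μ₁ = μ₂ = 0` special case.

## Worked example

```python
import numpy as np
from mgrnnm import (SyntheticSpec, generate_synthetic, MGRNNMParams,
                    mgrnnm_fit, predict, aupr)
from mgrnnm.evaluation import training_problem

# a 60x30 dataset whose similarity graphs reflect its rank-3 structure
ds = generate_synthetic(SyntheticSpec(
    n_drugs=60, n_targets=30, latent_rank=3,
    interaction_density=0.15, label_flip_rate=0.05, seed=0)).dataset

# hide 30% of the entries, fit, and rank the hidden ones
rng = np.random.default_rng(1)
A = (rng.random(ds.interactions.shape) >= 0.3).astype(float)
params = MGRNNMParams(lam=1.0, mu1=0.5, mu2=0.1, p=5)
problem, Ld, Lt = training_problem(ds, A, params)
state = mgrnnm_fit(problem, Ld, Lt, params)
test = A.ravel() == 0
print("converged:", state.converged, "iterations:", state.iterations_run)
print("held-out AUPR:", round(aupr(predict(state).ravel()[test],
                                   ds.interactions.ravel()[test]), 4))
```

prints

```
converged: True iterations: 38
held-out AUPR: 0.851
```

i.e. the solver converged in 38 alternating iterations and, ranking the
540 hidden drug–target pairs by predicted propensity, the area under the
precision–recall curve is 0.85 (a constant predictor would score near the
positive rate, 0.15). Setting `mu1=mu2=0` in the same run drops the AUPR
to 0.8281: the similarity graphs contribute real signal.

The same workflow is available from the shell:

```
mgrnnm simulate --n-drugs 60 --n-targets 30 --seed 0 --outdir sim/
mgrnnm cv --interactions sim/interactions.txt \
          --drug-sim sim/drug_similarity.txt \
          --target-sim sim/target_similarity.txt \
          --setting CVS1 --k-folds 10 --n-runs 5 --outdir cv/
```

`cv` supports the three standard DTI protocols: CVS1 holds out random
pairs, CVS2 whole drug rows (novel drugs), CVS3 whole target columns
(novel targets). Interaction-derived similarities are recomputed per fold
from training data only, so no test labels leak into the graphs.

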
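# mtqsar — multi-task support vector regression for multi-target QSAR

Inhibitors of one protein kinase are rarely silent on the rest of the
kinome: bioactivity data for related targets carry transferable signal.
`mtqsar` builds quantitative structure–activity (QSAR) regression models for
**many protein targets at once**, transferring knowledge between similar
targets instead of fitting every target in isolation.  It is aimed at
cheminformaticians modelling potency panels (pIC50 vs hashed circular
fingerprints) and at anyone who wants a compact, well-tested reference
implementation of multi-task ε-insensitive support vector regression.

## Methods

All models are linear SVRs with L2 ε-insensitive loss on unit-normalized
non-negative features (the linear kernel then equals the cosine kernel).
For a multi-task dataset of triples (xᵢ, yᵢ, tᵢ) with tasks 1…T:

- **tSVM** — T independent SVRs, one per task (the classical baseline).
- **1SVM** — one SVR pooling all tasks as if they were identical.
- **GRMT** — graph-regularized multi-task SVR.  Task similarity is a
  symmetric adjacency matrix A ≥ 0; the joint primal

  ```
  min  ½ Σₜ ‖wₜ‖² + ¼ Σₛₜ A_st ‖wₛ − wₜ‖² + C Σᵢ ℓ_ε(w_{tᵢ}·xᵢ, yᵢ)
  ```

  couples the task weight vectors through the graph Laplacian L = D − A.
  The dual uses the block kernel Q_ij = M_{tᵢtⱼ} xᵢ·xⱼ with M = (I_T+L)⁻¹
  and is solved by seeded dual coordinate descent.
- **TDMTtax / TDMTgs** — top-down multi-task SVR over a task taxonomy
  (e.g. the kinome tree).  One model per node, root first; each node solves

  ```
  min  (1−B)/2 ‖w‖² + B/2 ‖w − w_p‖² + C Σ_{i∈S} ℓ_ε(w·xᵢ, yᵢ)
  ```

  pulling toward the fixed parent weight w_p with strength B ∈ [0,1] —
  only a linear term added to the standard dual.  B comes from the scaled
  taxonomy branch weights (TDMTtax) or a local per-node grid search with
  inner cross-validation (TDMTgs); adding B = 0 at the leaves prevents
  negative transfer.

The package also ships the taxonomy machinery (Newick I/O, patristic
distances, s = 1 − d similarity conversion, UPGMA from correlations), a
controlled simulation benchmark (six-valued attributes, attribute-wise
Gaussian task models, noise-free targets), chemistry-side utilities
(activity-record curation cascade, fingerprint folding, Tanimoto k-medians
chemotype clustering) and an evaluation harness (shared splits, nested CV,
leave-one-sequence-out, paired Wilcoxon tests with Holm or
Benjamini–Hochberg correction).

## Worked example

```python
from mtqsar.evaluate import run_protocol, simulated_splits
from mtqsar.simulate import SimulationConfig

config = SimulationConfig(N=15, T=5, D=14, beta=3.0, sigma2=1.5, seed=0)
splits = simulated_splits(config, n_splits=5)
table = run_protocol(["tSVM", "1SVM", "GRMT", "TDMTtax", "TDMTgs"], splits,
                     C_grid=[0.125, 2.0, 32.0], inner_folds=3, seed=0)
print(table.groupby("algorithm").mse.mean().round(2))
```

prints

```
algorithm
1SVM       45.64
GRMT       45.54
TDMTgs     40.52
TDMTtax    41.66
tSVM       72.32
```

Five similar tasks with only 15 training instances each: the independent
tSVM (MSE 72.3) is clearly beaten by the multi-task methods (40.5–45.5),
which pool evidence across tasks.  With more data per task the ranking
shifts — the pooled 1SVM plateaus while everything else converges toward
zero error (`examples/simulated_benchmark.py` and friends walk through
this, novel-target prediction, taxonomy construction and curation).

A thin CLI mirrors the library: `mtqsar simulate|train|evaluate|loso|stats`.

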
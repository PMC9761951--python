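# mdjl — multi-omics joint learning for cancer survival

`mdjl` predicts per-patient survival risk from several omics data types
measured on the same cohort (e.g. DNA methylation, mRNA and miRNA
expression). It is aimed at computational biologists who have V ≥ 2
sample-aligned feature matrices plus right-censored survival outcomes and
want a single integrated hazard score per patient, together with the
standard survival read-outs (concordance index, Kaplan–Meier curves,
log-rank tests).

## The model

Three stages are trained jointly against one survival loss:

1. **Pairwise correlation representations.** Each view `x^v ∈ R^{d_v×N}`
   is embedded by a three-layer network `y^v = f_v(x^v) ∈ R^{d×N}`. For
   every pair of views (v, u) the per-sample outer product
   `χ_i = y_i^v ⊗ y_i^u` captures all d² cross-modality feature
   interactions; an affine projection maps its flattening back to
   `y^{v,u} ∈ R^{d×N}`. The M = V(V−1)/2 pair blocks are stacked into the
   fused representation `y ∈ R^{(M·d)×N}`.

2. **Similarity fusion by cross-diffusion.** For each pair representation
   a locally-scaled Gaussian affinity `W^m` is built over patients, then a
   row-stochastic matrix `P^m` (diagonal pinned at 1/2) and a sparse
   K-nearest-neighbour kernel `S^m`. Cross-diffusion iterates
   `P^m ← S^m · mean_{u≠m}(P^u) · S^mᵀ` (re-normalized each step) for T
   rounds, so the views converge to a consensus patient-similarity graph
   `P = mean_m P^m_T`.

3. **Graph-convolutional Cox head.** With `Â = D̃^{-1/2}(P+I)D̃^{-1/2}`,
   a three-layer GCN propagates `y` over the patient graph and a linear
   head scores the log hazard ratio `φ_i = z_i β`. The loss is the
   negative Cox partial log-likelihood
   `L = −Σ_{i: event} [φ_i − log Σ_{t_j ≥ t_i} e^{φ_j}]`,
   evaluated on training patients (transductively: the graph spans train
   and test patients, risk sets do not).

Evaluation follows the repeated-split protocol: 20 trials (configurable)
of stratified 70/30 re-splits with full re-fits, reporting the mean
held-out concordance index. Ablations: `variant="si"` removes the graph
(identity adjacency — a plain feed-forward net), `variant="os"` builds the
similarity graphs from the raw views instead of the learned
representations.

Because no deep-learning framework is a dependency, the package carries a
small numpy reverse-mode autodiff core (`mdjl.nn`) whose gradients are
pinned by central-finite-difference tests.

## Worked example

```python
from mdjl import SimConfig, simulate, TrainConfig, run_trials, oracle_cindex

# three views (200/150/100 features) of 200 patients, five shared latent
# factors driving both the views and a Weibull proportional-hazards time,
# ~30% independent censoring
dataset, truth = simulate(SimConfig(seed=1))
print(f"censored: {truth.censor_rate_realized:.0%}")
print(f"oracle C-index: {oracle_cindex(truth, dataset.survival):.3f}")

cfg = TrainConfig(epochs=100, embed_dim=16, hidden_sizes=(64, 32))
summary = run_trials(dataset, cfg, n_trials=3, master_seed=7)
print(f"MDJL test C-index: {summary.mean_c_index:.3f} ± {summary.sd_c_index:.3f}")
```

prints

```
censored: 30%
oracle C-index: 0.849
MDJL test C-index: 0.805 ± 0.020
```

The oracle C-index is the ceiling attainable from the true linear
predictor; the trained model recovers most of the latent survival signal
from the noisy views alone. On a matched null cohort (hazard coefficients
zeroed) the same protocol stays at chance level (≈ 0.5).

The same pipeline is scriptable from the shell:

```bash
mdjl simulate --out cohort --seed 1
mdjl preprocess --data cohort --out clean          # 20% filters, KNN impute, z-score
mdjl train --data clean --out fit --epochs 100 --embed-dim 16
mdjl evaluate --pred fit/phi.tsv --survival clean/survival.tsv --out report.json
```

`mdjl evaluate` reports the test C-index plus the median-hazard risk
grouping with its Kaplan–Meier log-rank p-value.

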
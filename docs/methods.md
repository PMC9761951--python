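# Methods

## Model and assumptions

`mdjl` integrates V ≥ 2 sample-aligned omics matrices with right-censored
survival outcomes under three assumptions:

- the data types share a common low-dimensional signal, and the
  *pairwise* interactions between modalities carry discriminative
  information beyond each modality alone;
- patients who are molecularly similar have similar hazards, so
  propagating representations over a patient-similarity graph
  regularizes the risk score;
- hazards are proportional: a single time-independent log hazard ratio
  φ_i per patient orders survival, which is exactly what the Cox partial
  likelihood estimates and what the concordance index measures.

The pipeline is: per-view three-layer embeddings f_v into a shared
d-dimensional space; per-sample outer products between every pair of
embeddings, projected back to d dimensions by one affine+ReLU layer per
pair (M = V(V−1)/2 pairs, computed once per unordered pair — the outer
product of the swapped pair is just the transpose); the M pair blocks
stacked into y ∈ R^{(M·d)×N}; a consensus patient graph built from the M
representations by cross-diffusion; and a three-layer GCN with a linear
Cox head on top of y and the graph.

Training is transductive and full-batch: one graph spans the train and
test patients, the forward pass scores everyone, but the partial
likelihood (and its risk sets) is restricted to the training mask. All
parameters — feature nets, pair projections, GCN, Cox head — take one
joint Adam step per epoch.

## Parameters that matter

| parameter | default | notes |
|---|---|---|
| embedding width d | 128 | pair projections cost d×d² weights; 16 is used at synthetic scale |
| feature-net hidden widths | (512, 512) | sized for 10³–10⁴-feature omics inputs; (64, 32) at synthetic scale |
| GCN hidden width | 32 | two ReLU graph layers + one linear graph layer |
| K (neighbourhood size) | 20 | clamped to N−2 with a warning on small cohorts |
| T (diffusion rounds) | 30 | disagreement between views plateaus well before 30 |
| Gaussian-kernel μ | 0.5 | locally scaled kernel, so no global bandwidth is needed |
| learning rate | 1e-4 | Adam, full batch |
| epochs | 200 | fixed budget; there is no convergence criterion, the loss trace is returned for inspection |
| trials / split | 20 × 70/30 | stratified on the event indicator to keep risk sets non-empty |

The Cox head has no bias: an intercept cancels in the partial likelihood
(the loss is invariant to adding a constant to every φ, which the tests
assert). Tied event times use the Breslow convention — the plain risk-set
sum — rather than Efron's correction.

## Preprocessing recipe

Samples with more than 20% missing entries in *any* view are removed
from every view and the survival table; features with more than 20%
missing entries are then dropped per view; remaining gaps are filled by
k-nearest-neighbour donor means (k = 10 by default; scikit-learn's
nan-Euclidean imputer); finally each feature is z-scored with the
population (ddof = 0) standard deviation. Z-scoring uses all samples,
which leaks test-set means/scales into training — the conventional
transductive choice for this protocol; `preprocess` operates before
splitting, so users who need strict train-only statistics should split
first and standardize with training moments themselves. Constant
features are set to zero with a warning.

## Similarity stage numerics

- Affinity: W(i,j) = exp(−dist²/(μ·ε_ij)) with
  ε_ij = (mean K-NN distance of i + mean K-NN distance of j + dist)/3,
  floored at 1e−12 so duplicate samples are well-defined; W is
  symmetrized and has unit diagonal.
- Normalization: P(i,j) = W(i,j)/(2·Σ_{k≠i}W(i,k)) off-diagonal, 1/2 on
  the diagonal; every row sums to 1 exactly. A row with no positive
  off-diagonal affinity is an error naming the sample.
- K-NN kernel: the K largest off-diagonal affinities per row, ties broken
  toward the smaller sample index for determinism; rows renormalized to 1.
- Diffusion: P^m ← S^m · mean_{u≠m}(P^u) · S^mᵀ, then re-normalized by
  the same rule — without re-normalization row-stochasticity (and the
  diagonal pin) would be lost after one step. The per-step maximum
  pairwise L1 disagreement between views is recorded; it drops steeply
  and then oscillates slightly around a plateau (the update is not an L1
  contraction), so only the overall decrease is a guaranteed property.
- With V = 2 there is a single pair representation and nothing to
  diffuse across; the fused graph is then its normalized weight matrix.
- The fused matrix is symmetrized, (P+Pᵀ)/2, before the GCN
  normalization D̃^{-1/2}(P+I)D̃^{-1/2}, which presumes an undirected
  graph.

The whole stage is detached: K-NN selection is non-differentiable, so no
gradient flows through W/P/S. Gradients reach the representation
networks only through the GCN's feature input. The graph is recomputed
from the current representations every epoch; `freeze_graph_after`
optionally pins it after a given epoch. Consequently the end-to-end
finite-difference gradient checks hold the graph fixed — that is the
function the analytic gradient differentiates.

## Autodiff core

No deep-learning framework is a dependency; `mdjl.nn` implements a
small float64 reverse-mode tape (matmul, broadcast add/mul, reshape,
transpose, concat, ReLU, exp/log, fancy indexing, a stable masked
log-sum-exp with a detached max shift) and Adam. Backward propagation
releases a node only after all of its consumers have contributed
(diamond-shaped graphs are common here: each view embedding feeds
several pair maps). Correctness is enforced by central finite
differences on the Cox loss (rel. 1e−5) and through the full
frozen-graph model (rel. 1e−3). ReLU makes the loss piecewise smooth, so
those checks run at a generic parameter point (zero-initialized biases
are nudged off the kink).

## Synthetic cohorts

The generator emulates the structure the model assumes: latent factors
h_i ~ N(0, I_q) shared by all views; view v is A_v h + N(0, noise_sd²)
with A_v entries N(0, loading_scale²); survival times follow a Weibull
proportional-hazards law via inverse transform,
T = (−log U / (scale·e^{risk}))^{1/shape} with risk = coefs·h; censoring
is independent exponential, its rate chosen by Brent root-finding so the
expected censored fraction on a 5 000-sample calibration draw matches
the target. Defaults: 200 patients, three views of 200/150/100 features,
q = 5, coefs (1, −1, 0.8, −0.6, 0.5), shape 2, ~30% censoring — sizes
and censoring chosen to mirror public multi-omics survival cohorts
(100–215 patients, roughly a quarter to a third censored).

What the generator does *not* emulate: real omics marginals (beta-valued
methylation, overdispersed counts), feature-feature correlation beyond
the shared factors, informative censoring, or batch effects. Passing
tests therefore demonstrate that the machinery recovers proportional-
hazards signal carried by shared latent structure in Gaussian views —
not performance on any real cancer cohort.

`oracle_cindex` scores the *true* linear predictor and is the ceiling
any model can reach on a given cohort (≈ 0.82–0.85 at the defaults);
the trained model typically reaches 0.75–0.81 held-out, and a
null-signal cohort (zero hazard coefficients) stays at chance.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run the synthetic protocol at
N = 200, d = 16, feature-net hiddens (64, 32), 100 epochs, and 3–5
repeated 70/30 trials per condition — small enough to iterate on a
laptop core while leaving the method, protocol and hyperparameters
(K = 20, T = 30, Adam 1e-4) exactly as defaulted. Exhaustive oracles
(quadruple-loop diffusion, risk-set enumeration, all-pairs concordance)
run at N ≤ 8–15 where enumeration is exact.

## Known limitations

- Quadratic in N (dense N×N graphs, full-batch training); not intended
  beyond a few thousand samples.
- The d×d² pair projection is dense by design; no low-rank factorization
  is offered because it would change the method.
- Transductive: adding a new patient requires re-running the forward
  pass (and in principle re-fitting); there is no inductive scoring path.
- Breslow ties only; no time-dependent effects, stratification,
  competing risks, or IPCW-adjusted metrics.
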
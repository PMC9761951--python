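"""Similarity-graph construction and cross-diffusion fusion.

Per representation m the stage builds a locally scaled Gaussian affinity
W^m, its row-stochastic normalization P^m (off-diagonal mass halved,
diagonal pinned at 1/2), and a sparse K-nearest-neighbour kernel S^m.
Cross-diffusion then repeatedly replaces each P^m by

    P^m  <-  S^m  x  mean_{u != m}(P^u)  x  S^m^T,

i.e. each view's similarity is propagated through its own local
neighbourhood structure against the consensus of the other views; after
each step P^m is re-normalized so row-stochasticity is preserved.  After
T iterations the fused similarity is the across-view mean, symmetrized
for use as an undirected graph.

This whole stage is deliberately non-differentiable (K-NN selection has
no useful gradient); the training loop treats the fused graph as a
constant of each forward pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

EPS_SCALE = 1e-12  # floor for the local kernel scale when samples coincide


@dataclass
class SimilarityStack:
    """Per-representation affinity/normalized/sparse matrices and hyperparameters."""

    affinities: list[np.ndarray]      # W^m, N x N symmetric nonnegative
    normalized: list[np.ndarray]      # P^m, row-stochastic with diag 1/2
    kernels: list[np.ndarray]         # S^m, rows sum to 1 over the K-neighbourhood
    neighborhoods: list[np.ndarray]   # N x K neighbour indices per representation
    K: int
    T: int

    @property
    def n_reps(self) -> int:
        return len(self.affinities)

    @property
    def n_samples(self) -> int:
        return self.affinities[0].shape[0]


@dataclass
class FusedGraph:
    """The cross-diffused, averaged similarity matrix and its symmetrization."""

    P: np.ndarray
    adjacency: np.ndarray                       # (P + P^T) / 2
    disagreement: list[float] = field(default_factory=list)  # per-iteration trace


def gaussian_affinity(rep: np.ndarray, K: int, mu: float = 0.5) -> np.ndarray:
    """Locally scaled Gaussian kernel on the columns (samples) of a d x N matrix.

    W(i,j) = exp(-dist^2(i,j) / (mu * eps_ij)) with the local scale
    eps_ij = (mean dist of i to its K nearest + same for j + dist(i,j)) / 3.
    Bandwidth-free: each pair is scaled by its own neighbourhood density.
    """
    x = np.asarray(rep, float).T  # samples as rows
    n = x.shape[0]
    if n < K + 1:
        raise ValueError(f"need N >= K+1 samples (N={n}, K={K})")
    dist = cdist(x, x)
    # mean distance of each sample to its K nearest others (exclude self at [:,0])
    knn_mean = np.sort(dist, axis=1)[:, 1:K + 1].mean(axis=1)
    scale = (knn_mean[:, None] + knn_mean[None, :] + dist) / 3.0
    scale = np.maximum(scale, EPS_SCALE)
    w = np.exp(-(dist ** 2) / (mu * scale))
    return (w + w.T) / 2.0


def normalize_weight(w: np.ndarray) -> np.ndarray:
    """Row-stochastic normalization with the diagonal pinned at 1/2.

    P(i,j) = W(i,j) / (2 * sum_{k != i} W(i,k)) off the diagonal and 1/2 on
    it, so every row sums to exactly 1 and half of each row's mass stays
    on the sample itself.
    """
    w = np.asarray(w, float)
    off = w - np.diag(np.diag(w))
    row = off.sum(axis=1)
    dead = np.flatnonzero(row <= 0)
    if dead.size:
        raise ValueError(f"sample(s) {dead.tolist()} have no positive off-diagonal affinity")
    p = off / (2.0 * row[:, None])
    np.fill_diagonal(p, 0.5)
    return p


def knn_kernel(w: np.ndarray, K: int) -> tuple[np.ndarray, np.ndarray]:
    """Sparse local kernel: keep each sample's K strongest neighbours, renormalize.

    Neighbourhoods are the K largest off-diagonal affinities per row,
    ties broken by ascending sample index.  Returns (S, neighbourhoods).
    """
    w = np.asarray(w, float)
    n = w.shape[0]
    if not K < n:
        raise ValueError(f"need K < N (K={K}, N={n})")
    masked = w.copy()
    np.fill_diagonal(masked, -np.inf)
    # stable sort on (-affinity, index): K largest, ties to the smaller index
    order = np.argsort(-masked, axis=1, kind="stable")
    nbrs = np.sort(order[:, :K], axis=1)  # store each neighbourhood sorted by index
    s = np.zeros_like(w)
    rows = np.repeat(np.arange(n), K)
    s[rows, nbrs.ravel()] = w[rows, nbrs.ravel()]
    row_sum = s.sum(axis=1, keepdims=True)
    row_sum[row_sum == 0] = 1.0
    return s / row_sum, nbrs


def build_similarity_stack(reps: list[np.ndarray], K: int = 20, T: int = 30,
                           mu: float = 0.5) -> SimilarityStack:
    """Affinity, normalized and sparse matrices for every representation."""
    n = np.asarray(reps[0]).shape[1]
    k_eff = K
    if k_eff > n - 2:
        k_eff = max(1, n - 2)
        warnings.warn(f"K={K} clamped to {k_eff} for N={n} samples", stacklevel=2)
    affinities, normalized, kernels, neighborhoods = [], [], [], []
    for rep in reps:
        w = gaussian_affinity(rep, k_eff, mu)
        s, nbrs = knn_kernel(w, k_eff)
        affinities.append(w)
        normalized.append(normalize_weight(w))
        kernels.append(s)
        neighborhoods.append(nbrs)
    return SimilarityStack(affinities, normalized, kernels, neighborhoods, k_eff, T)


def _max_disagreement(ps: list[np.ndarray]) -> float:
    m = len(ps)
    worst = 0.0
    for a in range(m):
        for b in range(a + 1, m):
            worst = max(worst, float(np.abs(ps[a] - ps[b]).sum()))
    return worst


def cross_diffuse(stack: SimilarityStack, T: int | None = None) -> tuple[SimilarityStack, list[float]]:
    """Run T cross-diffusion iterations; returns the updated stack and trace.

    Each step maps P^m to S^m (mean of other views' P) S^m^T and then
    re-applies the row-stochastic normalization, recording the maximum
    pairwise L1 disagreement between views per iteration.
    """
    m = stack.n_reps
    if m < 2:
        raise ValueError("cross-diffusion needs at least two representations")
    t_iters = stack.T if T is None else T
    if t_iters < 1:
        raise ValueError("need T >= 1")
    ps = [p.copy() for p in stack.normalized]
    trace = []
    for _ in range(t_iters):
        total = np.sum(ps, axis=0)
        new_ps = []
        for i in range(m):
            others = (total - ps[i]) / (m - 1)
            s = stack.kernels[i]
            new_ps.append(normalize_weight(s @ others @ s.T))
        ps = new_ps
        trace.append(_max_disagreement(ps))
    out = SimilarityStack(stack.affinities, ps, stack.kernels,
                          stack.neighborhoods, stack.K, stack.T)
    return out, trace


def fuse(stack: SimilarityStack, trace: list[float] | None = None) -> FusedGraph:
    """Average the diffused P^m and symmetrize for the undirected graph."""
    p = np.mean(stack.normalized, axis=0)
    return FusedGraph(p, (p + p.T) / 2.0, list(trace or []))


def fuse_representations(reps: list[np.ndarray], K: int = 20, T: int = 30,
                         mu: float = 0.5) -> FusedGraph:
    """End-to-end: representations -> affinities -> cross-diffusion -> fused graph.

    With a single representation (two views yield one pair) there is
    nothing to diffuse across, so the fused graph is its normalized
    weight matrix directly.
    """
    stack = build_similarity_stack(reps, K, T, mu)
    if stack.n_reps == 1:
        return fuse(stack, [])
    diffused, trace = cross_diffuse(stack)
    return fuse(diffused, trace)
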
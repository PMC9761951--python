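"""Pairwise cross-modality correlation representations.

Each view v is first embedded by a three-layer fully connected network
f_v into a shared d-dimensional space, y^v = f_v(x^v).  For every
unordered pair of views (v, u), v < u, the per-sample outer product
chi_i = y_i^v (x) y_i^u (the "interactive map") encodes all d*d pairwise
feature interactions between the two modalities; a single affine layer
psi_{v,u} with nonlinearity projects its row-major flattening back to d
dimensions, giving the correlation representation y^{v,u}.  The M =
V(V-1)/2 pair representations, stacked in lexicographic pair order,
form the fused representation y of shape (M*d) x N.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Tensor, concat_rows, glorot, relu


def pair_order(n_views: int) -> list[tuple[int, int]]:
    """Lexicographic unordered pairs (0-based): (0,1), (0,2), ..., (V-2,V-1)."""
    return [(v, u) for v in range(n_views) for u in range(v + 1, n_views)]


@dataclass
class FeatureNet:
    """Three-layer fully connected embedding f_v: R^{d_v} -> R^d, applied column-wise."""

    weights: list[Tensor]
    biases: list[Tensor]

    @staticmethod
    def init(rng: np.random.Generator, d_in: int, hidden_sizes: tuple[int, ...],
             embed_dim: int) -> "FeatureNet":
        sizes = [d_in, *hidden_sizes, embed_dim]
        weights = [Tensor.param(glorot(rng, sizes[l + 1], sizes[l]))
                   for l in range(len(sizes) - 1)]
        biases = [Tensor.param(np.zeros((sizes[l + 1], 1))) for l in range(len(sizes) - 1)]
        return FeatureNet(weights, biases)

    def forward(self, x: Tensor | np.ndarray) -> Tensor:
        """y^v = sigma(w^L ... sigma(w^1 x + b^1) ... + b^L) on a d_v x N matrix."""
        h = x if isinstance(x, Tensor) else Tensor(x)
        if h.shape[0] != self.weights[0].shape[1]:
            raise ValueError(
                f"input has {h.shape[0]} features, net expects {self.weights[0].shape[1]}")
        for w, b in zip(self.weights, self.biases):
            h = relu(w @ h + b)
        return h

    @property
    def params(self) -> list[Tensor]:
        return [*self.weights, *self.biases]


def interactive_map(y_v: np.ndarray, y_u: np.ndarray) -> np.ndarray:
    """Outer product of two length-d embedding vectors: entry (a, b) = y_v[a] * y_u[b]."""
    y_v = np.asarray(y_v, float)
    y_u = np.asarray(y_u, float)
    if y_v.ndim != 1 or y_u.ndim != 1 or y_v.shape != y_u.shape:
        raise ValueError(f"expected two equal-length vectors, got {y_v.shape} and {y_u.shape}")
    return np.outer(y_v, y_u)


def interactive_maps_batch(y_v: Tensor, y_u: Tensor) -> Tensor:
    """Row-major flattened outer products for all N samples: (d*d) x N.

    Column i holds vec(y_i^v (x) y_i^u) with vec in row-major order, so
    entry a*d+b is y_i^v[a] * y_i^u[b].
    """
    d, n = y_v.shape
    if y_u.shape != (d, n):
        raise ValueError("embeddings must share shape d x N")
    # (d,1,N) * (1,d,N) broadcast, then flatten the leading d*d block row-major
    a = y_v.reshape(d, 1, n)
    b = y_u.reshape(1, d, n)
    return (a * b).reshape(d * d, n)


@dataclass
class CorrelationProjection:
    """Affine map psi_{v,u}: vec(chi) in R^{d^2} -> R^d, plus nonlinearity."""

    weight: Tensor  # d x d^2
    bias: Tensor    # d x 1

    @staticmethod
    def init(rng: np.random.Generator, embed_dim: int) -> "CorrelationProjection":
        return CorrelationProjection(
            Tensor.param(glorot(rng, embed_dim, embed_dim * embed_dim)),
            Tensor.param(np.zeros((embed_dim, 1))),
        )

    def forward(self, flat_maps: Tensor) -> Tensor:
        """y^{v,u} = sigma(w_psi vec(chi) + b_psi), column-wise over samples."""
        return relu(self.weight @ flat_maps + self.bias)

    @property
    def params(self) -> list[Tensor]:
        return [self.weight, self.bias]


@dataclass
class CorrelationExtractor:
    """The full correlation-representation stage: V feature nets + M projections."""

    feature_nets: list[FeatureNet]
    projections: dict[tuple[int, int], CorrelationProjection]
    embed_dim: int

    @staticmethod
    def init(rng: np.random.Generator, view_dims: list[int],
             hidden_sizes: tuple[int, ...] = (512, 512),
             embed_dim: int = 128) -> "CorrelationExtractor":
        nets = [FeatureNet.init(rng, d_v, hidden_sizes, embed_dim) for d_v in view_dims]
        projections = {pair: CorrelationProjection.init(rng, embed_dim)
                       for pair in pair_order(len(view_dims))}
        return CorrelationExtractor(nets, projections, embed_dim)

    @property
    def n_views(self) -> int:
        return len(self.feature_nets)

    @property
    def n_pairs(self) -> int:
        return len(self.projections)

    def pair_representations(self, xs: list[np.ndarray]) -> dict[tuple[int, int], Tensor]:
        if len(xs) != self.n_views:
            raise ValueError(f"expected {self.n_views} views, got {len(xs)}")
        embeddings = [net.forward(x) for net, x in zip(self.feature_nets, xs)]
        reps = {}
        for pair in pair_order(self.n_views):
            v, u = pair
            flat = interactive_maps_batch(embeddings[v], embeddings[u])
            reps[pair] = self.projections[pair].forward(flat)
        return reps

    def forward(self, xs: list[np.ndarray]) -> tuple[Tensor, dict[tuple[int, int], Tensor]]:
        """Return the stacked (M*d) x N representation and the per-pair blocks."""
        reps = self.pair_representations(xs)
        fused = concat_representations(reps)
        return fused, reps

    @property
    def params(self) -> list[Tensor]:
        out = []
        for net in self.feature_nets:
            out.extend(net.params)
        for pair in pair_order(self.n_views):
            out.extend(self.projections[pair].params)
        return out


def concat_representations(reps: dict[tuple[int, int], Tensor]) -> Tensor:
    """Stack pair blocks in lexicographic order (0,1), (0,2), ..., (V-2,V-1)."""
    n_views = max(u for _, u in reps) + 1
    order = pair_order(n_views)
    missing = [p for p in order if p not in reps]
    if missing:
        raise ValueError(f"missing pair representation(s): {missing}")
    return concat_rows([reps[p] for p in order])
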
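"""Graph-convolutional Cox survival network and the joint training loop.

The fused similarity matrix P (symmetrized) becomes a graph over the
patients; a three-layer graph convolutional network propagates the fused
correlation representation y over A_hat = D^{-1/2}(P+I)D^{-1/2}, and a
linear Cox head phi_i = z_i beta scores each patient's log hazard ratio.
Training is transductive and full-batch: the graph and forward pass cover
train and test patients together, but the negative Cox partial
log-likelihood is evaluated on training patients only (risk sets are
restricted to the training mask).  All stages — per-view feature nets,
correlation projections, GCN and Cox head — are updated jointly by Adam;
the similarity/diffusion stage is recomputed each epoch from the current
representations but carries no gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .correlation import CorrelationExtractor, pair_order
from .fusion import FusedGraph, fuse_representations
from .io import OmicsDataset
from .nn import Adam, Tensor, glorot, logsumexp_rows, relu


@dataclass
class TrainConfig:
    """Hyperparameters of one training run.

    ``variant`` selects the full model ("mdjl"), similarity built from the
    raw views instead of the learned correlation representations ("os"),
    or no graph at all — the GCN degenerates to a per-sample fully
    connected network ("si").
    """

    epochs: int = 200
    lr: float = 1e-4
    K: int = 20
    T: int = 30
    mu: float = 0.5
    hidden_sizes: tuple[int, ...] = (512, 512)
    embed_dim: int = 128
    gcn_hidden: int = 32
    seed: int = 0
    variant: str = "mdjl"  # mdjl | os | si
    freeze_graph_after: int | None = None

    def __post_init__(self) -> None:
        if self.variant not in ("mdjl", "os", "si"):
            raise ValueError(f"unknown variant {self.variant!r}")


@dataclass
class HazardPrediction:
    """Per-sample log hazard ratios with the trial's split masks."""

    phi: np.ndarray
    train_mask: np.ndarray
    test_mask: np.ndarray
    trial_id: int = 0

    def __post_init__(self) -> None:
        if (self.train_mask & self.test_mask).any():
            raise ValueError("train and test masks overlap")
        if not np.isfinite(self.phi).all():
            raise ValueError("non-finite hazard predictions")


def normalize_adjacency(p: np.ndarray) -> np.ndarray:
    """Symmetric GCN normalization: D^{-1/2} (P + I) D^{-1/2}."""
    p = np.asarray(p, float)
    p_tilde = p + np.eye(p.shape[0])
    d = p_tilde.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return p_tilde * inv_sqrt[:, None] * inv_sqrt[None, :]


@dataclass
class GCNCox:
    """Three GCN layers (two with nonlinearity, last linear) and a Cox head.

    The Cox head carries no bias: an intercept is unidentifiable in the
    partial likelihood.
    """

    weights: list[Tensor]  # W_g^l, input -> hidden -> hidden -> hidden
    beta: Tensor           # hidden -> 1

    @staticmethod
    def init(rng: np.random.Generator, d_in: int, hidden: int = 32) -> "GCNCox":
        sizes = [d_in, hidden, hidden, hidden]
        weights = [Tensor.param(glorot(rng, sizes[l + 1], sizes[l]).T)
                   for l in range(3)]
        beta = Tensor.param(glorot(rng, hidden, 1).ravel())
        return GCNCox(weights, beta)

    def forward(self, features: Tensor, a_hat: np.ndarray) -> tuple[Tensor, Tensor]:
        """features: N x (M*d) sample-major; returns (z: N x hidden, phi: N)."""
        if features.shape[1] != self.weights[0].shape[0]:
            raise ValueError(
                f"feature width {features.shape[1]} != GCN input {self.weights[0].shape[0]}")
        a = Tensor(a_hat)
        h = relu(a @ (features @ self.weights[0]))
        h = relu(a @ (h @ self.weights[1]))
        z = a @ (h @ self.weights[2])  # final layer linear
        if not np.isfinite(z.data).all():
            raise FloatingPointError("non-finite activations in GCN output layer")
        phi = z @ self.beta.reshape(-1, 1)
        return z, phi.reshape(-1)

    @property
    def params(self) -> list[Tensor]:
        return [*self.weights, self.beta]


def cox_loss(phi: Tensor | np.ndarray, time: np.ndarray, event: np.ndarray,
             mask: np.ndarray | None = None) -> Tensor:
    """Negative Cox partial log-likelihood, Breslow convention for ties.

    L = -sum_{i in mask, event_i=1} [ phi_i - log sum_{j in mask, t_j >= t_i} e^{phi_j} ].
    Risk sets are taken within the mask only; the log-sum-exp is computed
    with max-shift for stability.
    """
    phi = phi if isinstance(phi, Tensor) else Tensor(phi)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    n = phi.shape[0]
    mask = np.ones(n, bool) if mask is None else np.asarray(mask, bool)
    idx = np.flatnonzero(mask)
    ev_idx = idx[event[idx] == 1]
    if ev_idx.size == 0:
        raise ValueError("no uncensored sample in the training mask")
    # risk-set indicator: R[i, j] = 1 iff t_j >= t_i, both within the mask
    riskmat = (time[idx][None, :] >= time[ev_idx][:, None]).astype(float)
    phi_mask = phi.take(idx)
    lse = logsumexp_rows(riskmat, phi_mask)
    return (lse - phi.take(ev_idx)).sum()


@dataclass
class MDJLModel:
    """The assembled joint model for one dataset."""

    extractor: CorrelationExtractor
    gcn: GCNCox
    config: TrainConfig
    fused_graph: FusedGraph | None = None

    @staticmethod
    def init(view_dims: list[int], config: TrainConfig) -> "MDJLModel":
        rng = np.random.default_rng(config.seed)
        extractor = CorrelationExtractor.init(
            rng, view_dims, config.hidden_sizes, config.embed_dim)
        d_in = extractor.n_pairs * config.embed_dim
        gcn = GCNCox.init(rng, d_in, config.gcn_hidden)
        return MDJLModel(extractor, gcn, config)

    @property
    def params(self) -> list[Tensor]:
        return [*self.extractor.params, *self.gcn.params]

    def _graph_from(self, xs: list[np.ndarray],
                    reps: dict[tuple[int, int], Tensor]) -> FusedGraph:
        cfg = self.config
        if cfg.variant == "si":  # no graph: identity adjacency
            n = xs[0].shape[1]
            return FusedGraph(np.zeros((n, n)), np.zeros((n, n)), [])
        if cfg.variant == "os":  # similarity from the raw views
            mats = [np.asarray(x, float) for x in xs]
        else:
            mats = [reps[p].data for p in pair_order(self.extractor.n_views)]
        return fuse_representations(mats, cfg.K, cfg.T, cfg.mu)

    def forward(self, xs: list[np.ndarray],
                graph: FusedGraph | None = None) -> tuple[Tensor, FusedGraph]:
        """One full forward pass; returns (phi over all samples, fused graph used)."""
        fused_y, reps = self.extractor.forward(xs)
        if graph is None:
            graph = self._graph_from(xs, reps)
        a_hat = normalize_adjacency(graph.adjacency)
        _, phi = self.gcn.forward(fused_y.T, a_hat)
        return phi, graph


@dataclass
class TrainResult:
    model: MDJLModel
    prediction: HazardPrediction
    loss_trace: list[float] = field(default_factory=list)
    disagreement_trace: list[float] = field(default_factory=list)


def train_mdjl(dataset: OmicsDataset, train_mask: np.ndarray, config: TrainConfig,
               trial_id: int = 0) -> TrainResult:
    """Full-batch joint training of feature nets, projections, GCN and Cox head.

    Per epoch: embed views, build pair representations, recompute the
    fused similarity graph (unless frozen), run the GCN, evaluate the
    Cox loss on the training mask, and take one Adam step on every
    parameter.  Returns transductive hazards for all samples.
    """
    train_mask = np.asarray(train_mask, bool)
    xs = [v.values for v in dataset.views]
    time, event = dataset.survival.time, dataset.survival.event
    model = MDJLModel.init([v.n_features for v in dataset.views], config)
    opt = Adam(model.params, lr=config.lr)
    loss_trace: list[float] = []
    graph: FusedGraph | None = None
    for epoch in range(config.epochs):
        frozen = (config.freeze_graph_after is not None
                  and epoch >= config.freeze_graph_after)
        phi, g = model.forward(xs, graph=graph if frozen else None)
        if not frozen:
            graph = g
        loss = cox_loss(phi, time, event, train_mask)
        if not np.isfinite(loss.data):
            raise FloatingPointError(f"training loss diverged at epoch {epoch}")
        loss_trace.append(float(loss.data))
        opt.zero_grad()
        loss.backward()
        opt.step()
    # final evaluation pass with the trained parameters
    phi, graph = model.forward(xs, graph=graph if config.freeze_graph_after is not None else None)
    model.fused_graph = graph
    pred = HazardPrediction(phi.data.copy(), train_mask, ~train_mask, trial_id)
    return TrainResult(model, pred, loss_trace, list(graph.disagreement))


def predict_hazard(model: MDJLModel, dataset: OmicsDataset,
                   train_mask: np.ndarray, trial_id: int = 0) -> HazardPrediction:
    """Hazards for all samples from the transductive forward pass of a trained model."""
    xs = [v.values for v in dataset.views]
    phi, _ = model.forward(xs, graph=model.fused_graph)
    train_mask = np.asarray(train_mask, bool)
    return HazardPrediction(phi.data.copy(), train_mask, ~train_mask, trial_id)
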
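"""Contrastive pretraining of node embeddings on the heterogeneous graph.

Two stochastically augmented views of the graph (independent edge removal,
shared-mask feature-dimension zeroing) are encoded by one weight-shared
GCN whose propagation depth is jittered per step between the views (model
augmentation). A symmetric normalized-temperature contrastive loss with
cosine similarity aligns each node across views against all other nodes
in both views.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Adam, Tensor, spmm
from .errors import ParameterError, RunError
from .graph_io import (
    FeatureMatrix,
    HeterogeneousGraph,
    NormalizedAdjacency,
    build_normalized_adjacency,
)

_EPS = 1e-12


@dataclass(frozen=True)
class GraphView:
    """One augmented copy of the graph."""

    adjacency: NormalizedAdjacency
    features: FeatureMatrix
    kept_edge_fraction: float
    masked_dims: frozenset


@dataclass
class EncoderParams:
    """Shared GCN weights; ``weights[0]`` maps n_feat -> dim."""

    weights: list  # list of np.ndarray
    base_depth: int
    activation: str = "relu"

    @property
    def max_depth(self) -> int:
        return len(self.weights)


@dataclass(frozen=True)
class EmbeddingMatrix:
    """Embedding rows aligned with ``node_order``."""

    node_order: tuple
    vectors: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "node_order", tuple(self.node_order))
        object.__setattr__(
            self, "vectors", np.asarray(self.vectors, dtype=np.float64)
        )
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.node_order):
            raise ParameterError("embedding shape does not match node order")

    @property
    def dim(self) -> int:
        return self.vectors.shape[1]

    @property
    def index(self) -> dict:
        return {n: i for i, n in enumerate(self.node_order)}


@dataclass
class PretrainConfig:
    p_edge: float = 0.2
    p_feat: float = 0.2
    tau: float = 0.5
    depth: int = 2
    depth_jitter: int = 1
    epochs: int = 200
    lr: float = 1e-3
    dim: int = 48
    projection: bool = True
    seed: int = 0


def augment(
    graph: HeterogeneousGraph,
    features: FeatureMatrix,
    p_edge: float,
    p_feat: float,
    seed: int,
) -> GraphView:
    """Drop edges and zero whole feature dimensions, both Bernoulli."""
    if not (0.0 <= p_edge < 1.0 and 0.0 <= p_feat < 1.0):
        raise ParameterError("p_edge and p_feat must lie in [0, 1)")
    rng = np.random.default_rng(seed)

    def keep(edge_set):
        ordered = sorted(edge_set)
        mask = rng.random(len(ordered)) >= p_edge
        return frozenset(e for e, m in zip(ordered, mask) if m)

    kept_dd = keep(graph.edges_dd)
    kept_ss = keep(graph.edges_ss)
    kept_ds = keep(graph.edges_ds)
    total = len(graph.edges_dd) + len(graph.edges_ss) + len(graph.edges_ds)
    kept = len(kept_dd) + len(kept_ss) + len(kept_ds)
    sub = HeterogeneousGraph(graph.drugs, graph.diseases, kept_dd, kept_ss, kept_ds)
    adjacency = build_normalized_adjacency(sub)

    dim_mask = rng.random(features.n_feat) < p_feat
    masked_dims = frozenset(np.flatnonzero(dim_mask).tolist())
    values = features.values.copy()
    values[:, dim_mask] = 0.0
    return GraphView(
        adjacency=adjacency,
        features=FeatureMatrix(features.node_order, values),
        kept_edge_fraction=kept / total if total else 1.0,
        masked_dims=masked_dims,
    )


def _encode_t(adjacency, h: Tensor, weights, depth: int) -> Tensor:
    for layer in range(depth):
        h = spmm(adjacency.matrix, h @ weights[layer]).relu()
    return h


def encode(view: GraphView, params: EncoderParams, depth: int) -> EmbeddingMatrix:
    """H^(l) = relu(Â H^(l-1) W^(l)), starting from the view's features."""
    if depth > params.max_depth:
        raise ParameterError(f"depth {depth} exceeds available {params.max_depth} layers")
    weights = [Tensor(w) for w in params.weights]
    h = _encode_t(view.adjacency, Tensor(view.features.values), weights, depth)
    return EmbeddingMatrix(view.features.node_order, h.data)


def _contrastive_loss_t(z1: Tensor, z2: Tensor, tau: float) -> Tensor:
    n = z1.shape[0]
    eye = np.eye(n)

    def normalize(z):
        norms = (z * z).sum(axis=1, keepdims=True).sqrt() + _EPS
        return z / norms

    n1, n2 = normalize(z1), normalize(z2)
    e12 = ((n1 @ n2.T) * (1.0 / tau)).exp()
    e11 = ((n1 @ n1.T) * (1.0 / tau)).exp()
    e22 = ((n2 @ n2.T) * (1.0 / tau)).exp()
    pos = (e12 * eye).sum(axis=1)
    denom1 = e12.sum(axis=1) + e11.sum(axis=1) - (e11 * eye).sum(axis=1)
    denom2 = e12.T.sum(axis=1) + e22.sum(axis=1) - (e22 * eye).sum(axis=1)
    l1 = denom1.log() - pos.log()
    l2 = denom2.log() - pos.log()
    return (l1.mean() + l2.mean()) * 0.5


def contrastive_loss(z1: EmbeddingMatrix, z2: EmbeddingMatrix, tau: float) -> float:
    """Symmetric InfoNCE over cosine similarities; 0 when no negatives exist."""
    if tau <= 0:
        raise ParameterError("tau must be positive")
    if z1.node_order != z2.node_order:
        raise ParameterError("views must share one node order")
    return float(_contrastive_loss_t(Tensor(z1.vectors), Tensor(z2.vectors), tau).data)


def _glorot(rng, fan_in, fan_out):
    scale = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-scale, scale, size=(fan_in, fan_out))


def init_encoder(
    n_feat: int, config: PretrainConfig, rng: np.random.Generator
) -> EncoderParams:
    l_max = config.depth + config.depth_jitter
    dims = [n_feat] + [config.dim] * l_max
    weights = [_glorot(rng, dims[i], dims[i + 1]) for i in range(l_max)]
    return EncoderParams(weights=weights, base_depth=config.depth)


def pretrain(
    graph: HeterogeneousGraph,
    features: FeatureMatrix,
    config: PretrainConfig,
    log: list | None = None,
) -> EmbeddingMatrix:
    """Train the shared encoder and return depth-L embeddings of the clean graph."""
    rng = np.random.default_rng(config.seed)
    params = init_encoder(features.n_feat, config, rng)
    weights = [Tensor(w, requires_grad=True) for w in params.weights]
    proj = []
    if config.projection:
        proj = [
            Tensor(_glorot(rng, config.dim, config.dim), requires_grad=True),
            Tensor(_glorot(rng, config.dim, config.dim), requires_grad=True),
        ]
    opt = Adam(weights + proj, lr=config.lr)
    lo = max(1, config.depth - config.depth_jitter)
    hi = config.depth + config.depth_jitter

    def project(z: Tensor) -> Tensor:
        if not proj:
            return z
        return (z @ proj[0]).relu() @ proj[1]

    for epoch in range(config.epochs):
        d1 = int(rng.integers(lo, hi + 1))
        d2 = int(rng.integers(lo, hi + 1))
        s1 = int(rng.integers(0, 2**31 - 1))
        s2 = int(rng.integers(0, 2**31 - 1))
        v1 = augment(graph, features, config.p_edge, config.p_feat, s1)
        v2 = augment(graph, features, config.p_edge, config.p_feat, s2)
        h1 = project(_encode_t(v1.adjacency, Tensor(v1.features.values), weights, d1))
        h2 = project(_encode_t(v2.adjacency, Tensor(v2.features.values), weights, d2))
        loss = _contrastive_loss_t(h1, h2, config.tau)
        if not np.isfinite(loss.data):
            raise RunError(f"contrastive loss became non-finite at epoch {epoch}")
        if log is not None:
            log.append(float(loss.data))
        opt.zero_grad()
        loss.backward()
        opt.step()

    params.weights = [w.data for w in weights]
    full_view = GraphView(
        adjacency=build_normalized_adjacency(graph),
        features=features,
        kept_edge_fraction=1.0,
        masked_dims=frozenset(),
    )
    return encode(full_view, params, config.depth)
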
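"""Residual graph-convolution fine-tuning with a two-part ranking objective.

Scores are inner products of final node embeddings produced by
``H^(l) = relu(Â H^(l-1) W^(l)) + H^(l-1)`` over the bipartite treat graph.
Supervision combines a binary treat-relationship pairwise loss and an
effectiveness-comparison pairwise loss, balanced per step by weights
``w_I = L_IET/(L_IET+β)``, ``w_E = β/(L_IET+β)`` computed from detached
loss values (L_IET = L_I + L_E).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from ._autodiff import Adam, Tensor, spmm
from .errors import InputError, ParameterError, RunError
from .graph_io import BipartiteGraph, NormalizedAdjacency, build_normalized_adjacency
from .pretrain import EmbeddingMatrix


class BinaryTriple(NamedTuple):
    u: str  # disease
    i: str  # positive drug (treats u)
    j: str  # negative drug (no known treat edge)


class ECRTriple(NamedTuple):
    u: str  # disease
    i: str  # more effective drug
    k: str  # less effective drug


@dataclass(frozen=True)
class LossWeights:
    w_i: float
    w_e: float
    beta: float
    l_iet: float


@dataclass
class FineTuneModel:
    """Trained residual-convolution weights plus the frozen input embeddings."""

    weights: list  # list of (d, d) arrays
    z0: EmbeddingMatrix
    adjacency: NormalizedAdjacency
    lambda_: float

    def final_embeddings(self) -> EmbeddingMatrix:
        return residual_forward(self.adjacency, self.z0, self)

    def score_function(self) -> "ScoreFunction":
        return ScoreFunction(self.final_embeddings())


class ScoreFunction:
    """r̂(u, i) = <e_u, e_i> over a fixed embedding matrix."""

    def __init__(self, embeddings: EmbeddingMatrix):
        self.embeddings = embeddings
        self._index = embeddings.index

    def __call__(self, u, i) -> float:
        vec = self.embeddings.vectors
        return float(vec[self._index[u]] @ vec[self._index[i]])

    def scores_for(self, u, candidates) -> np.ndarray:
        vec = self.embeddings.vectors
        rows = [self._index[c] for c in candidates]
        return vec[rows] @ vec[self._index[u]]


@dataclass
class FineTuneConfig:
    layers: int = 2
    epochs: int = 200
    lr: float = 1e-2
    beta: float = 1000.0
    lambda_: float = 1e-4
    negatives_per_positive: int = 1
    init_scale: float = 1.0
    weight_override: tuple | None = None  # (w_I, w_E) for ablations
    seed: int = 0


def _align(z0: EmbeddingMatrix, order) -> np.ndarray:
    index = z0.index
    try:
        rows = [index[n] for n in order]
    except KeyError as exc:
        raise InputError(f"node {exc.args[0]!r} missing from input embeddings")
    return z0.vectors[rows]


def _residual_t(adjacency, h: Tensor, weights) -> Tensor:
    for w in weights:
        h = spmm(adjacency.matrix, h @ w).relu() + h
    return h


def residual_forward(
    adjacency: NormalizedAdjacency, z0: EmbeddingMatrix, model: FineTuneModel
) -> EmbeddingMatrix:
    """Apply all residual layers; rows follow the adjacency node order."""
    h0 = _align(z0, adjacency.node_order)
    for w in model.weights:
        if w.shape != (h0.shape[1], h0.shape[1]):
            raise ParameterError(
                f"layer weight shape {w.shape} incompatible with dim {h0.shape[1]}"
            )
    h = _residual_t(adjacency, Tensor(h0), [Tensor(w) for w in model.weights])
    return EmbeddingMatrix(adjacency.node_order, h.data)


def sample_binary_triples(
    train: BipartiteGraph, negatives_per_positive: int, seed: int
) -> list:
    """One block of uniform negatives per training edge, resampled per call."""
    if negatives_per_positive < 1:
        raise ParameterError("negatives_per_positive must be >= 1")
    rng = np.random.default_rng(seed)
    positives = {}
    for s, d in train.edges:
        positives.setdefault(s, set()).add(d)
    all_drugs = list(train.drugs)
    triples = []
    for u, i in sorted(train.edges):
        pool = [d for d in all_drugs if d not in positives[u]]
        if not pool:
            raise InputError(f"disease {u!r} is positive to every drug; cannot sample")
        picks = rng.choice(len(pool), size=negatives_per_positive, replace=True)
        triples.extend(BinaryTriple(u, i, pool[p]) for p in picks)
    return triples


def _pairwise_loss(triples, scores) -> float:
    # -ln sigmoid(x) == softplus(-x), overflow-safe
    diffs = np.array([scores(t.u, t[1]) - scores(t.u, t[2]) for t in triples])
    return float(np.sum(np.maximum(-diffs, 0.0) + np.log1p(np.exp(-np.abs(diffs)))))


def loss_LI(triples, scores) -> float:
    """Binary treat-relationship pairwise loss, summed over all triples."""
    if not triples:
        raise InputError("loss requires at least one binary triple")
    return _pairwise_loss(triples, scores)


def loss_LE(triples, scores) -> float:
    """Effectiveness-comparison pairwise loss; 0 for an empty triple list."""
    if not triples:
        return 0.0
    return _pairwise_loss(triples, scores)


def bayesian_total_loss(
    l_i: float, l_e: float, beta: float, lambda_: float, theta_sq_norm: float
) -> tuple:
    """total = w_I·L_I + w_E·L_E + λ‖Θ‖², with w_I = L_IET/(L_IET+β)."""
    if beta < 0 or lambda_ < 0:
        raise ParameterError("beta and lambda must be nonnegative")
    l_iet = l_i + l_e
    if l_iet + beta == 0:
        w_i, w_e = 0.5, 0.5
    else:
        w_i = l_iet / (l_iet + beta)
        w_e = beta / (l_iet + beta)
    total = w_i * l_i + w_e * l_e + lambda_ * theta_sq_norm
    return total, LossWeights(w_i=w_i, w_e=w_e, beta=beta, l_iet=l_iet)


def finetune(
    train: BipartiteGraph,
    ecr: list,
    z0: EmbeddingMatrix,
    config: FineTuneConfig,
    log: list | None = None,
) -> FineTuneModel:
    """Gradient training of the residual layers on both ranking losses.

    The per-epoch loss weights are recomputed from the detached loss values
    (or taken from ``config.weight_override`` in ablation runs); no gradient
    flows through them.
    """
    adjacency = build_normalized_adjacency(train)
    order = adjacency.node_order
    index = {n: i for i, n in enumerate(order)}
    h0 = _align(z0, order)
    d = h0.shape[1]
    rng = np.random.default_rng(config.seed)
    scale = np.sqrt(6.0 / (2 * d)) * config.init_scale
    weights = [
        Tensor(rng.uniform(-scale, scale, size=(d, d)), requires_grad=True)
        for _ in range(config.layers)
    ]
    opt = Adam(weights, lr=config.lr)
    h0_t = Tensor(h0)

    node_set = set(order)
    ecr_usable = [t for t in ecr if t.u in node_set and t.i in node_set and t.k in node_set]
    ecr_u = np.array([index[t.u] for t in ecr_usable], dtype=np.intp)
    ecr_i = np.array([index[t.i] for t in ecr_usable], dtype=np.intp)
    ecr_k = np.array([index[t.k] for t in ecr_usable], dtype=np.intp)

    for epoch in range(config.epochs):
        triples = sample_binary_triples(
            train, config.negatives_per_positive, seed=int(rng.integers(0, 2**31 - 1))
        )
        bu = np.array([index[t.u] for t in triples], dtype=np.intp)
        bi = np.array([index[t.i] for t in triples], dtype=np.intp)
        bj = np.array([index[t.j] for t in triples], dtype=np.intp)

        h = _residual_t(adjacency, h0_t, weights)
        diff_b = (h.gather_rows(bu) * (h.gather_rows(bi) - h.gather_rows(bj))).sum(
            axis=1
        )
        l_i_t = (-diff_b).softplus().sum()
        if len(ecr_usable):
            diff_e = (
                h.gather_rows(ecr_u) * (h.gather_rows(ecr_i) - h.gather_rows(ecr_k))
            ).sum(axis=1)
            l_e_t = (-diff_e).softplus().sum()
            l_e_val = float(l_e_t.data)
        else:
            l_e_t = None
            l_e_val = 0.0
        l_i_val = float(l_i_t.data)

        _, w = bayesian_total_loss(l_i_val, l_e_val, config.beta, 0.0, 0.0)
        w_i, w_e = (w.w_i, w.w_e)
        if config.weight_override is not None:
            w_i, w_e = config.weight_override

        reg = None
        for wt in weights:
            term = (wt * wt).sum()
            reg = term if reg is None else reg + term
        total = l_i_t * w_i + config.lambda_ * reg
        if l_e_t is not None and w_e != 0.0:
            total = total + l_e_t * w_e
        total_val = float(total.data)
        if not np.isfinite(total_val):
            raise RunError(f"fine-tuning loss became non-finite at epoch {epoch}")
        if log is not None:
            log.append(
                {
                    "epoch": epoch,
                    "L_I": l_i_val,
                    "L_E": l_e_val,
                    "w_I": w_i,
                    "w_E": w_e,
                    "total": total_val,
                }
            )
        opt.zero_grad()
        total.backward()
        opt.step()

    return FineTuneModel(
        weights=[w.data for w in weights],
        z0=EmbeddingMatrix(tuple(order), h0),
        adjacency=adjacency,
        lambda_=config.lambda_,
    )
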
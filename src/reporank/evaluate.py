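"""Ranking metrics (MRR, Hit@K), improvement rates, and embedding silhouette."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from sklearn.metrics import silhouette_score as _sk_silhouette

from .errors import InputError, LogicError, ParameterError
from .pretrain import EmbeddingMatrix


@dataclass(frozen=True)
class RankingRecord:
    disease: str
    target_drug: str
    rank: int
    n_candidates: int

    def __post_init__(self):
        if not 1 <= self.rank <= self.n_candidates:
            raise LogicError(
                f"rank {self.rank} outside [1, {self.n_candidates}] "
                f"for ({self.disease}, {self.target_drug})"
            )


@dataclass(frozen=True)
class MetricReport:
    mrr: float
    hit_at: dict
    n_queries: int
    per_query: tuple

    def to_dict(self) -> dict:
        return {
            "mrr": self.mrr,
            "hit_at": {str(k): v for k, v in self.hit_at.items()},
            "n_queries": self.n_queries,
        }


def rank_candidates(
    scores, disease, test_drug, all_drugs, train_positives_of_disease
) -> RankingRecord:
    """Filtered rank of the held-out drug with pessimistic tie handling.

    Candidates are all drugs minus the disease's training positives; ties
    count against the model (equal-scoring candidates rank ahead).
    """
    candidates = sorted(set(all_drugs) - set(train_positives_of_disease))
    if test_drug not in candidates:
        raise LogicError(f"test drug {test_drug!r} was filtered out of the candidates")
    vals = np.asarray([scores(disease, c) for c in candidates], dtype=np.float64)
    target = vals[candidates.index(test_drug)]
    greater = int(np.sum(vals > target))
    equal_others = int(np.sum(vals == target)) - 1
    return RankingRecord(
        disease=disease,
        target_drug=test_drug,
        rank=1 + greater + equal_others,
        n_candidates=len(candidates),
    )


def compute_metrics(records, ks=(1, 3, 10)) -> MetricReport:
    """MRR = mean 1/rank; Hit@K = fraction with rank <= K."""
    records = list(records)
    if not records:
        raise InputError("cannot compute metrics over zero ranking records")
    # plain left-to-right accumulation so results match a scalar loop exactly
    n = len(records)
    mrr = 0.0
    hits = {int(k): 0 for k in ks}
    for r in records:
        mrr += 1.0 / r.rank
        for k in hits:
            hits[k] += int(r.rank <= k)
    return MetricReport(
        mrr=mrr / n,
        hit_at={k: v / n for k, v in hits.items()},
        n_queries=n,
        per_query=tuple(records),
    )


def relative_improvement(new: float, baseline: float) -> float:
    """100·(new − baseline)/baseline, rounded half-up to 2 decimals."""
    if baseline <= 0:
        raise ParameterError(f"baseline must be positive, got {baseline}")
    pct = Decimal(100) * (Decimal(str(new)) - Decimal(str(baseline))) / Decimal(
        str(baseline)
    )
    return float(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def silhouette_score(embeddings: EmbeddingMatrix, labels) -> float:
    """Mean Euclidean silhouette of the rows grouped by label."""
    labels = list(labels)
    if len(labels) != len(embeddings.node_order):
        raise InputError("one label required per embedding row")
    if len(set(labels)) < 2:
        raise InputError("silhouette requires at least 2 distinct labels")
    if len(labels) < 3:
        raise InputError("silhouette requires at least 3 points")
    return float(_sk_silhouette(embeddings.vectors, labels, metric="euclidean"))


def ecr_ordering_accuracy(ecr_triples, scores) -> float:
    """Fraction of comparison triples ranked consistently by the scores."""
    if not ecr_triples:
        raise InputError("no comparison triples to evaluate")
    hits = sum(1 for t in ecr_triples if scores(t.u, t.i) > scores(t.u, t.k))
    return hits / len(ecr_triples)


def evaluate_split(score_fn, train, test, all_drugs, ks=(1, 3, 10)) -> MetricReport:
    """One filtered ranking query per held-out (disease, drug) pair."""
    train_pos = {}
    for s, d in train.edges:
        train_pos.setdefault(s, set()).add(d)
    records = [
        rank_candidates(score_fn, s, d, all_drugs, train_pos.get(s, set()))
        for s, d in sorted(test.edges)
    ]
    return compute_metrics(records, ks=ks)
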
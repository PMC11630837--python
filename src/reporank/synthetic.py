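"""Synthetic studies with planted latent structure.

Drugs and diseases get standard-normal latent factors; the planted
affinity is their inner product. Treat edges are each disease's
top-affinity drugs, drug signatures are a noisy linear image of drug
factors, similarity edges connect factor-nearest neighbors plus
Erdős–Rényi noise, and effectiveness comparisons order pairs of a
disease's treaters by true affinity. Everything is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ParameterError
from .features import SignatureTable
from .finetune import ECRTriple
from .graph_io import (
    BipartiteGraph,
    HeterogeneousGraph,
    save_bipartite,
    save_ecr,
    save_heterograph,
)


@dataclass(frozen=True)
class SyntheticConfig:
    n_drugs: int = 150
    n_diseases: int = 30
    latent_dim: int = 8
    n_feat: int = 64
    noise_sd: float = 0.5
    treat_density: float = 0.05
    dd_edge_prob: float = 0.01
    ss_edge_prob: float = 0.02
    recorded_fraction: float = 0.7
    ecr_per_disease: int = 10
    knn: int = 2
    signature_offset: float = 0.0  # shared assay-baseline shift, in per-dim SDs
    seed: int = 0

    def validate(self):
        if self.n_drugs < 2 or self.n_diseases < 1:
            raise ParameterError("need at least 2 drugs and 1 disease")
        if not 0 < self.treat_density < 1:
            raise ParameterError("treat_density must be in (0,1)")
        if not 0 < self.recorded_fraction <= 1:
            raise ParameterError("recorded_fraction must be in (0,1]")
        if not (0 <= self.dd_edge_prob < 1 and 0 <= self.ss_edge_prob < 1):
            raise ParameterError("edge probabilities must be in [0,1)")
        if self.noise_sd < 0 or self.ecr_per_disease < 0:
            raise ParameterError("noise_sd and ecr_per_disease must be nonnegative")


@dataclass
class SyntheticStudy:
    graph: HeterogeneousGraph
    signatures: SignatureTable
    treat: BipartiteGraph
    ecr: list
    drug_factors: np.ndarray
    disease_factors: np.ndarray
    effectiveness: np.ndarray  # (n_diseases, n_drugs) = planted affinity

    def truth_affinity(self, disease, drug) -> float:
        u = list(self.graph.diseases).index(disease)
        i = list(self.graph.drugs).index(drug)
        return float(self.effectiveness[u, i])


def _knn_edges(ids, factors, k, rng, noise_prob):
    """Symmetric kNN-by-cosine edges plus Erdős–Rényi noise edges."""
    n = len(ids)
    norms = np.linalg.norm(factors, axis=1, keepdims=True) + 1e-12
    sim = (factors / norms) @ (factors / norms).T
    np.fill_diagonal(sim, -np.inf)
    edges = set()
    for a in range(n):
        for b in np.argsort(-sim[a])[:k]:
            edges.add(tuple(sorted((ids[a], ids[int(b)]))))
    if noise_prob > 0:
        mask = rng.random((n, n)) < noise_prob
        for a in range(n):
            for b in range(a + 1, n):
                if mask[a, b]:
                    edges.add(tuple(sorted((ids[a], ids[b]))))
    return frozenset(edges)


def generate_study(config: SyntheticConfig) -> SyntheticStudy:
    config.validate()
    rng = np.random.default_rng(config.seed)
    drugs = tuple(f"d{i:04d}" for i in range(config.n_drugs))
    diseases = tuple(f"s{i:04d}" for i in range(config.n_diseases))

    drug_factors = rng.standard_normal((config.n_drugs, config.latent_dim))
    disease_factors = rng.standard_normal((config.n_diseases, config.latent_dim))
    affinity = disease_factors @ drug_factors.T

    per_disease = max(1, int(np.floor(config.treat_density * config.n_drugs + 0.5)))
    treat_edges = set()
    for u in range(config.n_diseases):
        top = np.argsort(-affinity[u])[:per_disease]
        for i in top:
            treat_edges.add((diseases[u], drugs[int(i)]))
    treat = BipartiteGraph(diseases, drugs, frozenset(treat_edges))

    loading = rng.standard_normal((config.latent_dim, config.n_feat))
    signatures_full = drug_factors @ loading + config.noise_sd * rng.standard_normal(
        (config.n_drugs, config.n_feat)
    )
    if config.signature_offset:
        mu = rng.standard_normal(config.n_feat)
        mu *= config.signature_offset * np.sqrt(config.n_feat) / np.linalg.norm(mu)
        signatures_full = signatures_full + mu
    n_recorded = max(1, int(np.floor(config.recorded_fraction * config.n_drugs + 0.5)))
    recorded_idx = np.sort(
        rng.choice(config.n_drugs, size=n_recorded, replace=False)
    )
    signatures = SignatureTable(
        tuple(drugs[i] for i in recorded_idx), signatures_full[recorded_idx]
    )

    edges_dd = _knn_edges(drugs, drug_factors, config.knn, rng, config.dd_edge_prob)
    edges_ss = _knn_edges(
        diseases, disease_factors, config.knn, rng, config.ss_edge_prob
    )
    graph = HeterogeneousGraph(
        drugs, diseases, edges_dd, edges_ss, frozenset(treat_edges)
    )

    ecr = []
    for u in range(config.n_diseases):
        treaters = sorted(treat.drugs_of(diseases[u]))
        if len(treaters) < 2:
            continue
        for _ in range(config.ecr_per_disease):
            a, b = rng.choice(len(treaters), size=2, replace=False)
            da, db = treaters[int(a)], treaters[int(b)]
            ia, ib = drugs.index(da), drugs.index(db)
            if affinity[u, ia] == affinity[u, ib]:
                continue
            if affinity[u, ia] > affinity[u, ib]:
                ecr.append(ECRTriple(diseases[u], da, db))
            else:
                ecr.append(ECRTriple(diseases[u], db, da))

    return SyntheticStudy(
        graph=graph,
        signatures=signatures,
        treat=treat,
        ecr=ecr,
        drug_factors=drug_factors,
        disease_factors=disease_factors,
        effectiveness=affinity,
    )


def ecr_consistency_check(ecr) -> bool:
    """True iff every disease's better-than relation is acyclic."""
    by_disease = {}
    for t in ecr:
        by_disease.setdefault(t.u, []).append((t.i, t.k))
    for pairs in by_disease.values():
        g = nx.DiGraph(pairs)
        if not nx.is_directed_acyclic_graph(g):
            return False
    return True


def save_study(study: SyntheticStudy, out_dir) -> dict:
    """Write the five standard TSVs plus truth.tsv; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / f"{name}.tsv" for name in
             ("nodes", "edges", "treat", "ecr", "features", "truth")}
    save_heterograph(study.graph, paths["nodes"], paths["edges"])
    save_bipartite(study.treat, paths["treat"])
    save_ecr(study.ecr, paths["ecr"])
    sig = pd.DataFrame(
        study.signatures.signatures,
        columns=[f"f{i}" for i in range(study.signatures.n_feat)],
    )
    sig.insert(0, "node_id", list(study.signatures.recorded_drugs))
    sig.to_csv(paths["features"], sep="\t", index=False)
    rows = []
    for u, s in enumerate(study.graph.diseases):
        for i, d in enumerate(study.graph.drugs):
            rows.append((s, d, study.effectiveness[u, i]))
    pd.DataFrame(rows, columns=["disease_id", "drug_id", "effectiveness"]).to_csv(
        paths["truth"], sep="\t", index=False
    )
    return {k: str(v) for k, v in paths.items()}
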
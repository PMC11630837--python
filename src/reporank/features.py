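"""Initial node features from expression-perturbation signatures.

Drugs with a recorded signature use it directly. Unrecorded drugs borrow
the mean signature of recorded drugs among their drug–drug neighbors
(1-hop, then 2-hop, then the global mean). Disease rows are the mean of
their treating drugs' rows, optionally sign-flipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .graph_io import BipartiteGraph, FeatureMatrix, HeterogeneousGraph


@dataclass(frozen=True)
class SignatureTable:
    """Signatures for the subset of drugs with recorded perturbations."""

    recorded_drugs: tuple
    signatures: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "recorded_drugs", tuple(self.recorded_drugs))
        object.__setattr__(
            self, "signatures", np.asarray(self.signatures, dtype=np.float64)
        )
        if len(set(self.recorded_drugs)) != len(self.recorded_drugs):
            raise InputError("duplicate drug ids in signature table")
        if self.signatures.ndim != 2 or self.signatures.shape[0] != len(
            self.recorded_drugs
        ):
            raise InputError("signature matrix shape does not match drug list")
        if not np.all(np.isfinite(self.signatures)):
            raise InputError("non-finite signature values")

    @property
    def n_feat(self) -> int:
        return self.signatures.shape[1]

    @property
    def index(self) -> dict:
        return {d: i for i, d in enumerate(self.recorded_drugs)}


def impute_drug_signature(
    drug, graph: HeterogeneousGraph, table: SignatureTable
) -> np.ndarray:
    """Signature for an unrecorded drug via its drug–drug neighborhood.

    Unweighted mean of recorded 1-hop neighbors; falling back to 2-hop
    recorded neighbors, then to the global mean of all recorded signatures.
    """
    if len(table.recorded_drugs) == 0:
        raise InputError("cannot impute from an empty signature table")
    idx = table.index
    hop1 = graph.drug_neighbors(drug)
    recorded1 = sorted(d for d in hop1 if d in idx)
    if recorded1:
        return table.signatures[[idx[d] for d in recorded1]].mean(axis=0)
    hop2 = set()
    for nb in hop1:
        hop2 |= graph.drug_neighbors(nb)
    hop2.discard(drug)
    hop2 -= hop1
    recorded2 = sorted(d for d in hop2 if d in idx)
    if recorded2:
        return table.signatures[[idx[d] for d in recorded2]].mean(axis=0)
    return table.signatures.mean(axis=0)


def derive_disease_signature(
    disease,
    treat_edges: BipartiteGraph,
    drug_features: FeatureMatrix,
    sign_flag: int = 1,
) -> np.ndarray:
    """sign_flag · mean of treating drugs' feature rows.

    A disease with no treating drug gets the global mean over all drug rows.
    """
    if sign_flag not in (1, -1):
        raise InputError(f"sign_flag must be +1 or -1, got {sign_flag}")
    index = {n: i for i, n in enumerate(drug_features.node_order)}
    treaters = sorted(treat_edges.drugs_of(disease))
    if treaters:
        try:
            rows = [index[d] for d in treaters]
        except KeyError as exc:
            raise InputError(f"drug {exc.args[0]!r} missing from drug features")
        return sign_flag * drug_features.values[rows].mean(axis=0)
    return sign_flag * drug_features.values.mean(axis=0)


def assemble_features(
    graph: HeterogeneousGraph,
    table: SignatureTable,
    treat_edges: BipartiteGraph,
    sign_flag: int = 1,
) -> FeatureMatrix:
    """One feature row per node, in the graph's canonical node order."""
    if len(table.recorded_drugs) == 0:
        raise InputError("empty signature table")
    extra = set(table.recorded_drugs) - set(graph.drugs)
    if extra:
        raise InputError(f"signature table has drugs not in graph: {sorted(extra)[:5]}")
    idx = table.index
    n_feat = table.n_feat
    drug_rows = np.empty((len(graph.drugs), n_feat))
    for r, drug in enumerate(graph.drugs):
        if drug in idx:
            drug_rows[r] = table.signatures[idx[drug]]
        else:
            drug_rows[r] = impute_drug_signature(drug, graph, table)
    drug_fm = FeatureMatrix(tuple(graph.drugs), drug_rows)
    disease_rows = np.empty((len(graph.diseases), n_feat))
    for r, disease in enumerate(graph.diseases):
        disease_rows[r] = derive_disease_signature(
            disease, treat_edges, drug_fm, sign_flag
        )
    return FeatureMatrix(
        tuple(graph.node_order), np.vstack([drug_rows, disease_rows])
    )
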
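"""Graph and table I/O, normalized adjacencies, and train/test splits.

All files are UTF-8 tab-separated with a header row; lines starting with
``#`` are comments. Five table kinds are supported:

* ``nodes.tsv`` — columns ``node_id``, ``node_type`` (``drug``/``disease``)
* ``edges.tsv`` — ``source_id``, ``target_id``, ``relation``
  (``drug-drug``, ``disease-disease``, ``disease-drug``)
* ``treat.tsv`` — ``disease_id``, ``drug_id``
* ``ecr.tsv`` — ``disease_id``, ``better_drug_id``, ``worse_drug_id``
* ``features.tsv`` — ``node_id`` followed by numeric feature columns
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import InputError, ParameterError

RELATION_DD = "drug-drug"
RELATION_SS = "disease-disease"
RELATION_DS = "disease-drug"
_RELATIONS = {RELATION_DD, RELATION_SS, RELATION_DS}


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HeterogeneousGraph:
    """Typed drug/disease graph with three undirected relation kinds.

    ``edges_dd`` and ``edges_ss`` store unordered pairs as sorted 2-tuples;
    ``edges_ds`` stores ``(disease, drug)`` pairs.
    """

    drugs: tuple
    diseases: tuple
    edges_dd: frozenset
    edges_ss: frozenset
    edges_ds: frozenset

    def __post_init__(self):
        drug_set, disease_set = set(self.drugs), set(self.diseases)
        if len(drug_set) != len(self.drugs) or len(disease_set) != len(self.diseases):
            raise InputError("duplicate node ids")
        if drug_set & disease_set:
            raise InputError(
                f"ids appear as both drug and disease: {sorted(drug_set & disease_set)[:5]}"
            )
        for a, b in self.edges_dd:
            if a == b:
                raise InputError(f"self-loop on drug {a!r}")
            if a not in drug_set or b not in drug_set:
                raise InputError(f"drug-drug edge ({a!r},{b!r}) references unknown drug")
        for a, b in self.edges_ss:
            if a == b:
                raise InputError(f"self-loop on disease {a!r}")
            if a not in disease_set or b not in disease_set:
                raise InputError(
                    f"disease-disease edge ({a!r},{b!r}) references unknown disease"
                )
        for s, d in self.edges_ds:
            if s not in disease_set:
                raise InputError(f"disease-drug edge references unknown disease {s!r}")
            if d not in drug_set:
                raise InputError(f"disease-drug edge references unknown drug {d!r}")

    @property
    def node_order(self) -> list:
        """Canonical node order: drugs first, then diseases."""
        return list(self.drugs) + list(self.diseases)

    def all_edges(self) -> list:
        """Every edge as a pair of node ids (relation-agnostic)."""
        return (
            [tuple(e) for e in sorted(self.edges_dd)]
            + [tuple(e) for e in sorted(self.edges_ss)]
            + [tuple(e) for e in sorted(self.edges_ds)]
        )

    def drug_neighbors(self, drug) -> set:
        """1-hop drug neighbors via drug-drug edges."""
        out = set()
        for a, b in self.edges_dd:
            if a == drug:
                out.add(b)
            elif b == drug:
                out.add(a)
        return out


@dataclass(frozen=True)
class FeatureMatrix:
    """Per-node feature rows aligned with ``node_order``."""

    node_order: tuple
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "node_order", tuple(self.node_order))
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=np.float64)
        )
        if len(set(self.node_order)) != len(self.node_order):
            raise InputError("duplicate ids in feature node order")
        if self.values.ndim != 2 or self.values.shape[0] != len(self.node_order):
            raise InputError(
                f"feature matrix shape {self.values.shape} does not match "
                f"{len(self.node_order)} nodes"
            )
        if not np.all(np.isfinite(self.values)):
            raise InputError("non-finite feature values")

    @property
    def n_feat(self) -> int:
        return self.values.shape[1]

    def row(self, node_id) -> np.ndarray:
        return self.values[self.node_order.index(node_id)]

    def reorder(self, order: Iterable) -> "FeatureMatrix":
        index = {n: i for i, n in enumerate(self.node_order)}
        try:
            rows = [index[n] for n in order]
        except KeyError as exc:
            raise InputError(f"node {exc.args[0]!r} missing from feature matrix")
        return FeatureMatrix(tuple(order), self.values[rows])


@dataclass(frozen=True)
class BipartiteGraph:
    """Disease–drug treat graph; ``edges`` holds ``(disease, drug)`` pairs."""

    diseases: tuple
    drugs: tuple
    edges: frozenset

    def __post_init__(self):
        object.__setattr__(self, "diseases", tuple(self.diseases))
        object.__setattr__(self, "drugs", tuple(self.drugs))
        object.__setattr__(self, "edges", frozenset(self.edges))
        dis, dr = set(self.diseases), set(self.drugs)
        if len(dis) != len(self.diseases) or len(dr) != len(self.drugs):
            raise InputError("duplicate node ids in bipartite graph")
        for s, d in self.edges:
            if s not in dis or d not in dr:
                raise InputError(f"edge ({s!r},{d!r}) has endpoint outside node sets")

    @property
    def node_order(self) -> list:
        """Canonical order: diseases first, then drugs."""
        return list(self.diseases) + list(self.drugs)

    def drugs_of(self, disease) -> set:
        return {d for s, d in self.edges if s == disease}

    def diseases_of(self, drug) -> set:
        return {s for s, d in self.edges if d == drug}


@dataclass(frozen=True)
class NormalizedAdjacency:
    """Symmetric propagation operator D̃^{-1/2}(A+I)D̃^{-1/2}."""

    node_order: tuple
    matrix: sp.csr_matrix

    @property
    def index(self) -> dict:
        return {n: i for i, n in enumerate(self.node_order)}


@dataclass(frozen=True)
class SplitResult:
    train: BipartiteGraph
    test: BipartiteGraph
    mode: str
    seed: int


# ---------------------------------------------------------------------------
# loading / saving
# ---------------------------------------------------------------------------


def load_heterograph(node_table_path, edge_table_path) -> HeterogeneousGraph:
    """Read nodes.tsv + edges.tsv into a validated graph.

    Duplicate edges are collapsed; self-loops and unknown ids are rejected
    with the offending row named.
    """
    nodes = _read_tsv(node_table_path)
    if not {"node_id", "node_type"} <= set(nodes.columns):
        raise InputError("node table must have columns node_id, node_type")
    if len(nodes) == 0:
        raise InputError("empty node table")
    drugs, diseases = [], []
    for row in nodes.itertuples(index=False):
        if row.node_type == "drug":
            drugs.append(row.node_id)
        elif row.node_type == "disease":
            diseases.append(row.node_id)
        else:
            raise InputError(f"unknown node_type {row.node_type!r} for {row.node_id!r}")

    edges = _read_tsv(edge_table_path)
    if not {"source_id", "target_id", "relation"} <= set(edges.columns):
        raise InputError("edge table must have columns source_id, target_id, relation")
    known = set(drugs) | set(diseases)
    e_dd, e_ss, e_ds = set(), set(), set()
    for i, row in enumerate(edges.itertuples(index=False)):
        s, t, rel = row.source_id, row.target_id, row.relation
        for endpoint in (s, t):
            if endpoint not in known:
                raise InputError(f"edge row {i}: unknown node id {endpoint!r}")
        if rel == RELATION_DD:
            e_dd.add(tuple(sorted((s, t))))
        elif rel == RELATION_SS:
            e_ss.add(tuple(sorted((s, t))))
        elif rel == RELATION_DS:
            e_ds.add((s, t))
        else:
            raise InputError(f"edge row {i}: unknown relation {rel!r}")
    return HeterogeneousGraph(
        tuple(drugs), tuple(diseases), frozenset(e_dd), frozenset(e_ss), frozenset(e_ds)
    )


def save_heterograph(graph: HeterogeneousGraph, node_table_path, edge_table_path):
    nodes = pd.DataFrame(
        {
            "node_id": list(graph.drugs) + list(graph.diseases),
            "node_type": ["drug"] * len(graph.drugs)
            + ["disease"] * len(graph.diseases),
        }
    )
    nodes.to_csv(node_table_path, sep="\t", index=False)
    rows = (
        [(a, b, RELATION_DD) for a, b in sorted(graph.edges_dd)]
        + [(a, b, RELATION_SS) for a, b in sorted(graph.edges_ss)]
        + [(s, d, RELATION_DS) for s, d in sorted(graph.edges_ds)]
    )
    pd.DataFrame(rows, columns=["source_id", "target_id", "relation"]).to_csv(
        edge_table_path, sep="\t", index=False
    )


def load_bipartite(treat_path, diseases=None, drugs=None) -> BipartiteGraph:
    """Read treat.tsv; node sets default to the ids present in the edges."""
    df = _read_tsv(treat_path)
    if not {"disease_id", "drug_id"} <= set(df.columns):
        raise InputError("treat table must have columns disease_id, drug_id")
    edges = {(r.disease_id, r.drug_id) for r in df.itertuples(index=False)}
    if diseases is None:
        diseases = tuple(sorted({s for s, _ in edges}))
    if drugs is None:
        drugs = tuple(sorted({d for _, d in edges}))
    return BipartiteGraph(tuple(diseases), tuple(drugs), frozenset(edges))


def save_bipartite(bipartite: BipartiteGraph, treat_path):
    pd.DataFrame(sorted(bipartite.edges), columns=["disease_id", "drug_id"]).to_csv(
        treat_path, sep="\t", index=False
    )


def load_ecr(ecr_path) -> list:
    """Read ecr.tsv into a list of ECRTriple."""
    from .finetune import ECRTriple

    df = _read_tsv(ecr_path)
    required = {"disease_id", "better_drug_id", "worse_drug_id"}
    if not required <= set(df.columns):
        raise InputError(f"ecr table must have columns {sorted(required)}")
    return [
        ECRTriple(r.disease_id, r.better_drug_id, r.worse_drug_id)
        for r in df.itertuples(index=False)
    ]


def save_ecr(triples, ecr_path):
    pd.DataFrame(
        [(t.u, t.i, t.k) for t in triples],
        columns=["disease_id", "better_drug_id", "worse_drug_id"],
    ).to_csv(ecr_path, sep="\t", index=False)


def load_features(features_path) -> FeatureMatrix:
    df = pd.read_csv(features_path, sep="\t", comment="#")
    if df.columns[0] != "node_id":
        raise InputError("features table must start with a node_id column")
    values = df.iloc[:, 1:].to_numpy(dtype=np.float64)
    return FeatureMatrix(tuple(df["node_id"].astype(str)), values)


def save_features(features: FeatureMatrix, features_path):
    df = pd.DataFrame(
        features.values, columns=[f"f{i}" for i in range(features.n_feat)]
    )
    df.insert(0, "node_id", list(features.node_order))
    df.to_csv(features_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# adjacency & splits
# ---------------------------------------------------------------------------


def build_normalized_adjacency(graph) -> NormalizedAdjacency:
    """Â = D̃^{-1/2}(A+I)D̃^{-1/2} over the graph's canonical node order.

    Works for both :class:`HeterogeneousGraph` (all three relation kinds
    flattened) and :class:`BipartiteGraph` (treat edges only).
    """
    order = graph.node_order
    index = {n: i for i, n in enumerate(order)}
    if isinstance(graph, HeterogeneousGraph):
        pairs = graph.all_edges()
    else:
        pairs = sorted(graph.edges)
    n = len(order)
    rows, cols = [], []
    for a, b in pairs:
        i, j = index[a], index[b]
        rows += [i, j]
        cols += [j, i]
    a_mat = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n, n), dtype=np.float64
    )
    a_mat.data[:] = 1.0  # collapse any accidental duplicates
    a_tilde = a_mat + sp.identity(n, format="csr")
    deg = np.asarray(a_tilde.sum(axis=1)).ravel()
    d_inv_sqrt = sp.diags(1.0 / np.sqrt(deg))
    return NormalizedAdjacency(tuple(order), (d_inv_sqrt @ a_tilde @ d_inv_sqrt).tocsr())


def split_warm(
    bipartite: BipartiteGraph, test_fraction: float, seed: int
) -> SplitResult:
    """Uniformly random edge partition; node sets are kept on both sides."""
    if not 0.0 < test_fraction < 1.0:
        raise ParameterError(f"test_fraction must be in (0,1), got {test_fraction}")
    edges = sorted(bipartite.edges)
    if len(edges) < 2:
        raise InputError("need at least 2 edges to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(edges))
    n_test = max(1, _round_half_up(test_fraction * len(edges)))
    n_test = min(n_test, len(edges) - 1)
    test_idx = set(perm[:n_test].tolist())
    train_edges = frozenset(e for i, e in enumerate(edges) if i not in test_idx)
    test_edges = frozenset(e for i, e in enumerate(edges) if i in test_idx)
    return SplitResult(
        train=BipartiteGraph(bipartite.diseases, bipartite.drugs, train_edges),
        test=BipartiteGraph(bipartite.diseases, bipartite.drugs, test_edges),
        mode="warm_edge",
        seed=seed,
    )


def split_cold_disease(
    bipartite: BipartiteGraph, test_fraction: float, seed: int
) -> SplitResult:
    """Partition diseases; each edge follows its disease's side.

    Test diseases never appear in the train graph (new-disease setting).
    Diseases without any edge stay on the train side.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ParameterError(f"test_fraction must be in (0,1), got {test_fraction}")
    eligible = sorted({s for s, _ in bipartite.edges})
    if len(eligible) < 2:
        raise InputError("need at least 2 diseases with edges for a cold split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(eligible))
    n_test = max(1, _round_half_up(test_fraction * len(eligible)))
    n_test = min(n_test, len(eligible) - 1)
    test_dis = {eligible[i] for i in perm[:n_test]}
    train_dis = tuple(s for s in bipartite.diseases if s not in test_dis)
    test_dis_ordered = tuple(s for s in bipartite.diseases if s in test_dis)
    train_edges = frozenset((s, d) for s, d in bipartite.edges if s not in test_dis)
    test_edges = frozenset((s, d) for s, d in bipartite.edges if s in test_dis)
    return SplitResult(
        train=BipartiteGraph(train_dis, bipartite.drugs, train_edges),
        test=BipartiteGraph(test_dis_ordered, bipartite.drugs, test_edges),
        mode="cold_disease",
        seed=seed,
    )
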
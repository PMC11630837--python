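import numpy as np
import pytest

from reporank.features import SignatureTable
from reporank.graph_io import BipartiteGraph, FeatureMatrix, HeterogeneousGraph
from reporank.synthetic import SyntheticConfig, generate_study


@pytest.fixture
def tiny_graph():
    """2 drugs, 1 disease; one drug-drug edge and one treat edge."""
    return HeterogeneousGraph(
        drugs=("d1", "d2"),
        diseases=("s1",),
        edges_dd=frozenset({("d1", "d2")}),
        edges_ss=frozenset(),
        edges_ds=frozenset({("s1", "d1")}),
    )


@pytest.fixture
def path_graph():
    """3-drug path d1 - d2 - d3, no diseases involved in edges."""
    return HeterogeneousGraph(
        drugs=("d1", "d2", "d3"),
        diseases=(),
        edges_dd=frozenset({("d1", "d2"), ("d2", "d3")}),
        edges_ss=frozenset(),
        edges_ds=frozenset(),
    )


@pytest.fixture
def small_bipartite():
    diseases = tuple(f"s{i}" for i in range(4))
    drugs = tuple(f"d{i}" for i in range(6))
    edges = frozenset(
        {
            ("s0", "d0"),
            ("s0", "d1"),
            ("s1", "d1"),
            ("s1", "d2"),
            ("s2", "d3"),
            ("s2", "d4"),
            ("s3", "d0"),
            ("s3", "d5"),
            ("s3", "d2"),
            ("s1", "d5"),
        }
    )
    return BipartiteGraph(diseases, drugs, edges)


@pytest.fixture(scope="session")
def small_study():
    """A 40-drug / 10-disease study shared across training-behavior tests."""
    return generate_study(
        SyntheticConfig(n_drugs=40, n_diseases=10, latent_dim=4, n_feat=16, seed=11)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(123)


@pytest.fixture
def mixed_signature_fixture():
    """5 drugs (3 recorded), 2 diseases, for feature-assembly oracles."""
    graph = HeterogeneousGraph(
        drugs=("a", "b", "c", "d", "e"),
        diseases=("x", "y"),
        edges_dd=frozenset({("a", "b"), ("b", "c"), ("c", "d")}),
        edges_ss=frozenset(),
        edges_ds=frozenset({("x", "a"), ("x", "c"), ("y", "b")}),
    )
    rng = np.random.default_rng(5)
    table = SignatureTable(("a", "b", "d"), rng.standard_normal((3, 4)))
    treat = BipartiteGraph(
        ("x", "y"), ("a", "b", "c", "d", "e"),
        frozenset({("x", "a"), ("x", "c"), ("y", "b")}),
    )
    return graph, table, treat
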
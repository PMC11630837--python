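import math

import numpy as np
import pytest

from reporank.errors import ParameterError, RunError
from reporank.features import assemble_features
from reporank.graph_io import FeatureMatrix, HeterogeneousGraph, build_normalized_adjacency
from reporank.pretrain import (
    EmbeddingMatrix,
    EncoderParams,
    GraphView,
    PretrainConfig,
    augment,
    contrastive_loss,
    encode,
    init_encoder,
    pretrain,
)


def full_view(graph, features):
    return GraphView(
        adjacency=build_normalized_adjacency(graph),
        features=features,
        kept_edge_fraction=1.0,
        masked_dims=frozenset(),
    )


class TestAugment:
    def test_no_op(self, tiny_graph, rng):
        feats = FeatureMatrix(tuple(tiny_graph.node_order), rng.standard_normal((3, 4)))
        view = augment(tiny_graph, feats, p_edge=0.0, p_feat=0.0, seed=0)
        assert view.kept_edge_fraction == 1.0
        assert view.masked_dims == frozenset()
        np.testing.assert_allclose(view.features.values, feats.values)

    def test_full_mask_gives_zero_features(self, tiny_graph, rng):
        feats = FeatureMatrix(tuple(tiny_graph.node_order), rng.standard_normal((3, 4)))
        view = augment(tiny_graph, feats, p_edge=0.0, p_feat=0.999999, seed=0)
        assert view.masked_dims == frozenset(range(4))
        np.testing.assert_allclose(view.features.values, 0.0)

    def test_masked_dims_zero_across_all_nodes(self, small_study):
        g = small_study.graph
        feats = FeatureMatrix(
            tuple(g.node_order), np.ones((len(g.node_order), 16))
        )
        view = augment(g, feats, p_edge=0.0, p_feat=0.5, seed=3)
        for dim in view.masked_dims:
            assert np.all(view.features.values[:, dim] == 0.0)
        kept = sorted(set(range(16)) - view.masked_dims)
        assert np.all(view.features.values[:, kept] == 1.0)

    def test_edge_removal_binomial(self):
        # 1000-edge drug chain/clique mixture, p_edge=0.2 => kept ~ B(1000, .8)
        n = 1001
        drugs = tuple(f"d{i}" for i in range(n))
        edges = frozenset((f"d{i}", f"d{i+1}") for i in range(n - 1))
        g = HeterogeneousGraph(drugs, (), edges, frozenset(), frozenset())
        feats = FeatureMatrix(drugs, np.zeros((n, 2)))
        kept = []
        for seed in range(200):
            view = augment(g, feats, p_edge=0.2, p_feat=0.0, seed=seed)
            kept.append(view.kept_edge_fraction * 1000)
        mean_kept = np.mean(kept)
        sd = math.sqrt(1000 * 0.2 * 0.8) / math.sqrt(200)
        assert abs(mean_kept - 800) < 3 * sd * math.sqrt(200)  # 3 binomial SDs

    def test_deterministic(self, small_study, rng):
        g = small_study.graph
        feats = FeatureMatrix(
            tuple(g.node_order), rng.standard_normal((len(g.node_order), 8))
        )
        v1 = augment(g, feats, 0.3, 0.3, seed=5)
        v2 = augment(g, feats, 0.3, 0.3, seed=5)
        assert v1.masked_dims == v2.masked_dims
        np.testing.assert_array_equal(
            v1.adjacency.matrix.toarray(), v2.adjacency.matrix.toarray()
        )

    def test_param_range(self, tiny_graph, rng):
        feats = FeatureMatrix(tuple(tiny_graph.node_order), np.zeros((3, 2)))
        with pytest.raises(ParameterError):
            augment(tiny_graph, feats, p_edge=1.0, p_feat=0.0, seed=0)
        with pytest.raises(ParameterError):
            augment(tiny_graph, feats, p_edge=0.0, p_feat=-0.1, seed=0)


class TestEncode:
    def test_identity_propagation_single_node(self):
        g = HeterogeneousGraph(("d1",), (), frozenset(), frozenset(), frozenset())
        feats = FeatureMatrix(("d1",), np.array([[1.0, 2.0]]))
        params = EncoderParams(weights=[np.eye(2)], base_depth=1)
        out = encode(full_view(g, feats), params, depth=1)
        np.testing.assert_allclose(out.vectors, [[1.0, 2.0]])

    def test_depth1_matches_dense_oracle(self, path_graph, rng):
        feats = FeatureMatrix(tuple(path_graph.node_order), rng.standard_normal((3, 4)))
        w = rng.standard_normal((4, 5))
        params = EncoderParams(weights=[w], base_depth=1)
        out = encode(full_view(path_graph, feats), params, depth=1)
        a_hat = build_normalized_adjacency(path_graph).matrix.toarray()
        oracle = np.maximum(a_hat @ feats.values @ w, 0.0)
        np.testing.assert_allclose(out.vectors, oracle, atol=1e-6)

    @pytest.mark.parametrize("depth", [1, 2, 3])
    def test_deeper_matches_dense_oracle(self, small_study, rng, depth):
        g = small_study.graph
        n = len(g.node_order)
        feats = FeatureMatrix(tuple(g.node_order), rng.standard_normal((n, 6)))
        ws = [rng.standard_normal((6, 8))] + [
            rng.standard_normal((8, 8)) for _ in range(depth - 1)
        ]
        params = EncoderParams(weights=ws, base_depth=depth)
        out = encode(full_view(g, feats), params, depth=depth)
        a_hat = build_normalized_adjacency(g).matrix.toarray()
        h = feats.values
        for w in ws:
            h = np.maximum(a_hat @ h @ w, 0.0)
        np.testing.assert_allclose(out.vectors, h, atol=1e-5)

    def test_zero_features_give_zero_embedding(self, path_graph, rng):
        feats = FeatureMatrix(tuple(path_graph.node_order), np.zeros((3, 4)))
        params = EncoderParams(weights=[rng.standard_normal((4, 4))], base_depth=1)
        out = encode(full_view(path_graph, feats), params, depth=1)
        np.testing.assert_allclose(out.vectors, 0.0)

    def test_depth_validated(self, path_graph, rng):
        feats = FeatureMatrix(tuple(path_graph.node_order), np.zeros((3, 4)))
        params = EncoderParams(weights=[np.eye(4)], base_depth=1)
        with pytest.raises(ParameterError):
            encode(full_view(path_graph, feats), params, depth=2)

    def test_permutation_equivariance(self, rng):
        drugs = ("a", "b", "c", "d")
        edges = frozenset({("a", "b"), ("b", "c"), ("c", "d")})
        g1 = HeterogeneousGraph(drugs, (), edges, frozenset(), frozenset())
        g2 = HeterogeneousGraph(tuple(reversed(drugs)), (), edges, frozenset(), frozenset())
        vals = rng.standard_normal((4, 3))
        f1 = FeatureMatrix(drugs, vals)
        f2 = FeatureMatrix(tuple(reversed(drugs)), vals[::-1])
        w = rng.standard_normal((3, 3))
        params = EncoderParams(weights=[w], base_depth=1)
        o1 = encode(full_view(g1, f1), params, 1)
        o2 = encode(full_view(g2, f2), params, 1)
        for i, node in enumerate(drugs):
            np.testing.assert_allclose(
                o1.vectors[i], o2.vectors[o2.node_order.index(node)], atol=1e-10
            )


def brute_force_contrastive(z1, z2, tau):
    """Literal double-summation of the symmetric InfoNCE formula."""

    def cos(a, b):
        return float(a @ b / ((np.linalg.norm(a) + 1e-12) * (np.linalg.norm(b) + 1e-12)))

    n = z1.shape[0]
    total = 0.0
    for first, second in ((z1, z2), (z2, z1)):
        for i in range(n):
            pos = math.exp(cos(first[i], second[i]) / tau)
            denom = 0.0
            for j in range(n):
                denom += math.exp(cos(first[i], second[j]) / tau)
                if j != i:
                    denom += math.exp(cos(first[i], first[j]) / tau)
            total += -math.log(pos / denom) / n
    return total / 2.0


class TestContrastiveLoss:
    def test_single_node_zero(self):
        z = EmbeddingMatrix(("a",), np.array([[1.0, 2.0]]))
        assert contrastive_loss(z, z, tau=0.5) == pytest.approx(0.0, abs=1e-12)

    def test_two_orthogonal_onehots_match_scalar_oracle(self):
        vecs = np.eye(2)
        z = EmbeddingMatrix(("a", "b"), vecs)
        expected = brute_force_contrastive(vecs, vecs, 1.0)
        assert contrastive_loss(z, z, tau=1.0) == pytest.approx(expected, abs=1e-8)

    @pytest.mark.parametrize("n,seed", [(5, 0), (8, 1), (10, 2)])
    def test_matches_brute_force(self, n, seed):
        rng = np.random.default_rng(seed)
        v1, v2 = rng.standard_normal((2, n, 4))
        names = tuple(f"x{i}" for i in range(n))
        got = contrastive_loss(
            EmbeddingMatrix(names, v1), EmbeddingMatrix(names, v2), tau=0.7
        )
        assert got == pytest.approx(brute_force_contrastive(v1, v2, 0.7), abs=1e-8)

    def test_nonnegative(self, rng):
        v1, v2 = rng.standard_normal((2, 6, 3))
        names = tuple(f"x{i}" for i in range(6))
        assert (
            contrastive_loss(EmbeddingMatrix(names, v1), EmbeddingMatrix(names, v2), 0.5)
            >= 0.0
        )

    def test_shuffling_views_increases_loss(self):
        rng = np.random.default_rng(4)
        base = np.eye(6) * 5.0 + 0.01 * rng.standard_normal((6, 6))
        names = tuple(f"x{i}" for i in range(6))
        aligned = contrastive_loss(
            EmbeddingMatrix(names, base), EmbeddingMatrix(names, base), 0.5
        )
        shuffled = contrastive_loss(
            EmbeddingMatrix(names, base),
            EmbeddingMatrix(names, np.roll(base, 1, axis=0)),
            0.5,
        )
        assert shuffled > aligned

    def test_tau_validated(self):
        z = EmbeddingMatrix(("a", "b"), np.eye(2))
        with pytest.raises(ParameterError):
            contrastive_loss(z, z, tau=0.0)


class TestPretrain:
    def test_epochs_zero_is_untrained_encode(self, small_study):
        g = small_study.graph
        feats = assemble_features(g, small_study.signatures, small_study.treat)
        cfg = PretrainConfig(epochs=0, seed=9)
        emb = pretrain(g, feats, cfg)
        params = init_encoder(feats.n_feat, cfg, np.random.default_rng(9))
        view = full_view(g, feats)
        expected = encode(view, params, cfg.depth)
        np.testing.assert_allclose(emb.vectors, expected.vectors)

    def test_deterministic(self, small_study):
        g = small_study.graph
        feats = assemble_features(g, small_study.signatures, small_study.treat)
        cfg = PretrainConfig(epochs=5, seed=3)
        e1 = pretrain(g, feats, cfg)
        e2 = pretrain(g, feats, cfg)
        np.testing.assert_array_equal(e1.vectors, e2.vectors)

    def test_loss_decreases_on_fixture(self, small_study):
        g = small_study.graph
        feats = assemble_features(g, small_study.signatures, small_study.treat)
        log = []
        pretrain(g, feats, PretrainConfig(epochs=60, seed=1), log=log)
        # per-epoch values are noisy (stochastic views/depths); compare means
        assert np.mean(log[-10:]) < np.mean(log[:10])
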
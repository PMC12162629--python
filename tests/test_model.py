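import numpy as np
import pytest

from dvamda import (
    AssociationMatrix,
    LatentGaussian,
    build_graph,
    fuse,
    gvae_encode,
    reparameterize,
    sage_encode,
    score_pairs,
    vae_encode,
)
from dvamda.autodiff import Tensor
from dvamda.io import MDAGraph
from dvamda.model import (
    DVAMDA,
    ModelState,
    gcn_propagation_matrix,
    init_state,
    neighbor_mean_matrix,
)


def _random_bipartite(rng, max_nodes=8):
    m = int(rng.integers(1, max_nodes - 1))
    n = int(rng.integers(1, max_nodes - m + 1))
    A = AssociationMatrix(rng.integers(0, 2, size=(m, n)))
    d = int(rng.integers(1, 5))
    X = rng.standard_normal((m + n, d))
    return build_graph(A, X)


def _brute_force_sage(G, state):
    """Per-node, per-layer loop implementation of mean-aggregation SAGE."""
    n_layers = state.config["sage_layers"]
    h = G.features.copy()
    adjacency = G.adjacency()
    for layer in range(n_layers):
        wa = state[f"sage{layer}_Wagg"].data
        ws = state[f"sage{layer}_Wself"].data
        b = state[f"sage{layer}_b"].data
        nxt = []
        for v in range(G.node_count):
            neighbors = np.flatnonzero(adjacency[v])
            agg = h[neighbors].mean(axis=0) if len(neighbors) else np.zeros(h.shape[1])
            pre = agg @ wa + h[v] @ ws + b.ravel()
            nxt.append(np.maximum(pre, 0.0) if layer < n_layers - 1 else pre)
        h = np.array(nxt)
    return h


class TestSageEncoder:
    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            G = _random_bipartite(rng)
            state = init_state(
                G.features.shape[1], hidden_dim=3, sage_layers=2, seed=int(rng.integers(2**31))
            )
            np.testing.assert_allclose(
                sage_encode(G, state), _brute_force_sage(G, state), atol=1e-10
            )

    def test_isolated_node_with_identity_weights_passes_through(self):
        A = AssociationMatrix(np.zeros((1, 1), dtype=int))
        X = np.array([[0.7, -1.2], [3.0, 0.5]])
        G = build_graph(A, X)
        state = init_state(2, hidden_dim=2, sage_layers=1, seed=0)
        state["sage0_Wself"].data[:] = np.eye(2)
        state["sage0_Wagg"].data[:] = 0.0
        state["sage0_b"].data[:] = 0.0
        np.testing.assert_allclose(sage_encode(G, state), X)

    def test_star_center_aggregates_neighbor_mean(self):
        # microbe 0 linked to both diseases, with disease features (2,0), (0,2)
        A = AssociationMatrix(np.array([[1, 1]]))
        X = np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 2.0]])
        G = build_graph(A, X)
        state = init_state(2, hidden_dim=2, sage_layers=1, seed=0)
        state["sage0_Wself"].data[:] = 0.0
        state["sage0_Wagg"].data[:] = np.eye(2)
        state["sage0_b"].data[:] = 0.0
        np.testing.assert_allclose(sage_encode(G, state)[0], [1.0, 1.0])

    def test_permutation_equivariance_within_partitions(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            G = _random_bipartite(rng)
            state = init_state(G.features.shape[1], hidden_dim=4, seed=3)
            out = sage_encode(G, state)
            perm_m = rng.permutation(G.m)
            perm_d = rng.permutation(G.n)
            node_perm = np.concatenate([perm_m, G.m + perm_d])
            inv = np.argsort(node_perm)
            edges = frozenset((int(inv[u]), int(inv[v])) for u, v in G.edges)
            G_perm = MDAGraph(G.m, G.n, edges, G.features[node_perm])
            np.testing.assert_allclose(sage_encode(G_perm, state), out[node_perm], atol=1e-10)

    def test_feature_width_mismatch_raises(self, toy_assoc):
        G = build_graph(toy_assoc, np.zeros((7, 3)))
        state = init_state(5, seed=0)
        with pytest.raises(ValueError, match="width"):
            sage_encode(G, state)


class TestGCNPropagation:
    def test_matches_dense_oracle_on_random_graphs(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            m, n = 3, 3  # 6-node bipartite graphs
            G = build_graph(
                AssociationMatrix(rng.integers(0, 2, size=(m, n))),
                rng.standard_normal((6, 2)),
            )
            prop = gcn_propagation_matrix(G)
            a_hat = G.adjacency() + np.eye(6)
            expected = np.zeros((6, 6))
            deg = a_hat.sum(axis=1)
            for i in range(6):
                for j in range(6):
                    expected[i, j] = a_hat[i, j] / np.sqrt(deg[i] * deg[j])
            np.testing.assert_allclose(prop, expected, atol=1e-12)

    def test_edgeless_graph_reduces_to_identity_propagation(self):
        A = AssociationMatrix(np.zeros((2, 2), dtype=int))
        G = build_graph(A, np.random.default_rng(0).standard_normal((4, 3)))
        np.testing.assert_allclose(gcn_propagation_matrix(G), np.eye(4))


class TestVAEEncoders:
    def test_identity_mean_path_reproduces_input(self):
        X = np.random.default_rng(0).standard_normal((5, 4))
        state = init_state(4, latent_dim=4, seed=0)
        state["vae_Wmu"].data[:] = np.eye(4)
        state["vae_bmu"].data[:] = 0.0
        q = vae_encode(X, state)
        np.testing.assert_allclose(q.mean, X)

    def test_variance_strictly_positive_for_any_weights(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((6, 3))
        state = init_state(3, latent_dim=5, seed=1)
        state["vae_Wvar"].data[:] = rng.standard_normal((3, 5)) * 10
        q = vae_encode(X, state)
        assert (q.var > 0).all()
        assert q.mean.shape == q.var.shape == (6, 5)

    def test_gvae_edgeless_graph_is_affine(self):
        # with no edges the propagation is the identity, so the mean path is
        # exactly the affine map X @ W + b
        A = AssociationMatrix(np.zeros((3, 2), dtype=int))
        X = np.random.default_rng(2).standard_normal((5, 4))
        G = build_graph(A, X)
        state = init_state(4, variant="gva_only", latent_dim=3, seed=2)
        q = gvae_encode(G, state)
        expected = X @ state["gvae_Wmu"].data + state["gvae_bmu"].data
        np.testing.assert_allclose(q.mean, expected, atol=1e-12)

    def test_gvae_symmetric_nodes_get_equal_means(self):
        # two microbes with identical features both linked to the one disease
        A = AssociationMatrix(np.array([[1], [1]]))
        X = np.array([[1.0, 2.0], [1.0, 2.0], [0.5, 0.5]])
        G = build_graph(A, X)
        state = init_state(2, variant="gva_only", latent_dim=3, seed=3)
        q = gvae_encode(G, state)
        np.testing.assert_allclose(q.mean[0], q.mean[1], atol=1e-12)

    def test_width_mismatch_raises(self):
        state = init_state(4, latent_dim=3, seed=0)
        with pytest.raises(ValueError, match="width"):
            vae_encode(np.zeros((2, 7)), state)


class TestReparameterize:
    def test_eval_mode_returns_mean_bitwise(self):
        q = LatentGaussian(np.array([[1.5, -2.0]]), np.array([[0.3, 4.0]]))
        np.testing.assert_array_equal(reparameterize(q, mode="eval"), q.mean)

    def test_vanishing_variance_returns_mean_in_train_mode(self):
        q = LatentGaussian(np.array([[1.0, 2.0]]), np.full((1, 2), 1e-300))
        z = reparameterize(q, rng=np.random.default_rng(0), mode="train")
        np.testing.assert_allclose(z, q.mean, atol=1e-140)

    def test_sample_mean_matches_posterior_mean(self):
        mean = np.array([[0.7, -1.3]])
        var = np.array([[0.5, 2.0]])
        q = LatentGaussian(mean, var)
        rng = np.random.default_rng(42)
        draws = np.stack([reparameterize(q, rng, "train") for _ in range(10_000)])
        se = np.sqrt(var / 10_000)
        assert (np.abs(draws.mean(axis=0) - mean) < 4 * se).all()

    def test_invalid_mode_raises(self):
        q = LatentGaussian(np.zeros((1, 1)), np.ones((1, 1)))
        with pytest.raises(ValueError, match="mode"):
            reparameterize(q, mode="test")


class TestFuse:
    def test_concatenation_order_and_width(self):
        rng = np.random.default_rng(0)
        Z, Zt, Xt = (rng.standard_normal((4, w)) for w in (3, 2, 5))
        fused = fuse(Z, Zt, Xt)
        assert fused.shape == (4, 10)
        np.testing.assert_array_equal(fused[:, :3], Z)
        np.testing.assert_array_equal(fused[:, 3:5], Zt)
        np.testing.assert_array_equal(fused[:, 5:], Xt)

    def test_zero_width_block_is_skipped(self):
        Z = np.ones((3, 2))
        Xt = np.full((3, 4), 2.0)
        fused = fuse(Z, np.zeros((3, 0)), Xt)
        np.testing.assert_array_equal(fused, np.hstack([Z, Xt]))

    def test_row_mismatch_raises(self):
        with pytest.raises(ValueError, match="row"):
            fuse(np.ones((3, 2)), np.ones((4, 2)), None)


class TestScorePairs:
    @pytest.fixture()
    def scorer(self):
        state = init_state(4, variant="sage_only", hidden_dim=4, predictor_hidden=6, seed=5)
        fused = np.random.default_rng(5).standard_normal((6, 4))
        return state, fused

    def test_scores_strictly_inside_unit_interval(self, scorer):
        state, fused = scorer
        pairs = [(0, 4), (1, 5), (2, 4)]
        s = score_pairs(fused, pairs, state, m=3)
        assert ((s > 0) & (s < 1)).all()

    def test_zero_microbe_embedding_collapses_to_bias_path(self, scorer):
        state, fused = scorer
        fused = fused.copy()
        fused[0] = 0.0
        fused[2] = 0.0
        s = score_pairs(fused, [(0, 4), (2, 5)], state, m=3)
        assert s[0] == pytest.approx(s[1], abs=1e-12)

    def test_hadamard_symmetry_between_pair_roles(self, scorer):
        # the elementwise product commutes, so swapping which embedding plays
        # the microbe role cannot change the score
        state, fused = scorer
        swapped = fused.copy()
        swapped[[0, 4]] = swapped[[4, 0]]
        s1 = score_pairs(fused, [(0, 4)], state, m=3)
        s2 = score_pairs(swapped, [(0, 4)], state, m=3)
        assert s1[0] == pytest.approx(s2[0], abs=1e-12)

    def test_out_of_range_pair_raises(self, scorer):
        state, fused = scorer
        with pytest.raises(IndexError):
            score_pairs(fused, [(4, 5)], state, m=3)


class TestModelStateSerialization:
    def test_checkpoint_round_trip_is_lossless(self, small_assoc, fast_params, tmp_path):
        model = DVAMDA(**{**fast_params, "epochs": 5}, random_state=0).fit(small_assoc)
        path = tmp_path / "model.json"
        model.state_.save(path)
        restored = ModelState.load(path)
        assert restored.config == model.state_.config
        for name, tensor in model.state_.params.items():
            np.testing.assert_array_equal(restored[name].data, tensor.data)

    def test_tied_sage_checkpoint_restores_aliasing(self, small_assoc, tmp_path):
        model = DVAMDA(
            hidden_dim=8, latent_dim=8, predictor_hidden=8, epochs=3,
            tied_sage=True, random_state=0,
        ).fit(small_assoc)
        assert model.state_["sage0_Wagg"] is model.state_["sage0_Wself"]
        path = tmp_path / "tied.json"
        model.state_.save(path)
        restored = ModelState.load(path)
        assert restored["sage0_Wagg"] is restored["sage0_Wself"]

    def test_unknown_version_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"version": 99, "config": {}, "params": {}}')
        with pytest.raises(ValueError, match="version"):
            ModelState.load(path)


class TestEstimator:
    def test_eval_forward_is_deterministic(self, small_assoc, fast_params):
        model = DVAMDA(**fast_params, random_state=1).fit(small_assoc)
        pairs = [(0, 0), (5, 3), (10, 7)]
        s1 = model.predict_proba(pairs)
        s2 = model.predict_proba(pairs)
        np.testing.assert_array_equal(s1, s2)

    def test_get_set_params_round_trip(self):
        model = DVAMDA(latent_dim=32)
        params = model.get_params()
        assert params["latent_dim"] == 32
        clone = DVAMDA().set_params(**params)
        assert clone.get_params() == params

    @pytest.mark.parametrize("variant", ["full", "sage_only", "dva_only", "gva_only"])
    def test_all_variants_fit_and_score(self, small_assoc, fast_params, variant):
        model = DVAMDA(**{**fast_params, "epochs": 10}, variant=variant, random_state=0)
        model.fit(small_assoc)
        s = model.predict_proba([(0, 0), (1, 1)])
        assert ((s > 0) & (s < 1)).all()

    def test_unfitted_predict_raises(self):
        with pytest.raises(RuntimeError, match="not fitted"):
            DVAMDA().predict_proba([(0, 0)])
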
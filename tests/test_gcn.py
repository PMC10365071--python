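"""GCN model: attention contract, layers, training, CV, grid search, ranking."""

import numpy as np
import pytest
from dataclasses import replace

from unbgcn import (
    ModelConfig,
    attention_forward,
    cross_validate,
    forward,
    gcn_layer,
    grid_search,
    masked_cross_entropy,
    planted_feature_graph,
    predict,
    train,
)
from unbgcn.gcn import (
    TrainedModel,
    model_from_dict,
    model_to_dict,
    propagation_operator,
    rank_roi_attention,
)
from unbgcn.popgraph import PopulationGraph


def trained_acc(graph, config):
    model = train(graph, config)
    pred, _ = predict(graph, model, graph.test_mask)
    return (pred == graph.labels[graph.test_mask]).mean()


class TestAttentionForward:
    def test_rows_sum_to_one(self, rng):
        X = rng.standard_normal((15, 6))
        Wa = rng.standard_normal((15, 6))
        Z, A = attention_forward(X, Wa, rng.standard_normal(6))
        assert np.allclose(A.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(A >= 0)
        assert Z.shape == X.shape

    def test_zero_init_uniform(self, rng):
        X = rng.standard_normal((8, 5))
        Z, A = attention_forward(X, np.zeros((8, 5)), np.zeros(5))
        assert np.allclose(A, 1 / 5)
        assert np.allclose(Z, X / 5)

    def test_single_node_direct(self):
        Z, A = attention_forward(np.array([[1.0, 1.0]]), np.zeros((1, 2)), np.zeros(2))
        assert np.allclose(Z, [[0.5, 0.5]])

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            attention_forward(np.array([[np.inf, 0.0]]), np.zeros((1, 2)), np.zeros(2))


class TestGCNLayer:
    def test_identity(self, rng):
        H = rng.standard_normal((4, 3))
        out = gcn_layer(np.eye(4), H, np.eye(3), activation="none")
        assert np.array_equal(out, H)

    def test_relu_clamps(self):
        H = -np.ones((3, 2))
        out = gcn_layer(np.eye(3), H, np.eye(2), activation="relu")
        assert np.all(out == 0.0)

    def test_against_triple_loop(self, rng):
        S = rng.standard_normal((10, 10))
        H = rng.standard_normal((10, 4))
        Th = rng.standard_normal((4, 3))
        out = gcn_layer(S, H, Th, activation="none")
        expected = np.zeros((10, 3))
        for i in range(10):
            for j in range(3):
                for a in range(10):
                    for b in range(4):
                        expected[i, j] += S[i, a] * H[a, b] * Th[b, j]
        assert np.abs(out - expected).max() < 1e-10

    def test_shape_mismatch(self, rng):
        with pytest.raises(ValueError):
            gcn_layer(np.eye(3), rng.standard_normal((4, 2)), np.eye(2))


class TestMaskedCrossEntropy:
    def test_perfect_predictions(self):
        probs = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert masked_cross_entropy(probs, [0, 1], [True, True]) == pytest.approx(0.0)

    def test_uniform_two_class(self):
        probs = np.full((5, 2), 0.5)
        loss = masked_cross_entropy(probs, [0, 1, 0, 1, 0], np.ones(5, bool))
        assert loss == pytest.approx(np.log(2))

    def test_hand_summed(self, rng):
        probs = rng.dirichlet(np.ones(3), size=6)
        labels = rng.integers(0, 3, 6)
        mask = np.array([1, 0, 1, 1, 0, 1], bool)
        expected = np.mean([-np.log(probs[i, labels[i]]) for i in range(6) if mask[i]])
        assert masked_cross_entropy(probs, labels, mask) == pytest.approx(expected)

    def test_empty_mask(self):
        with pytest.raises(ValueError):
            masked_cross_entropy(np.full((2, 2), 0.5), [0, 1], [False, False])


class TestForward:
    def test_rows_sum_to_one(self):
        g = planted_feature_graph(10, 1.0, seed=0, n_features=6)
        model = train(g, ModelConfig(epochs=5, seed=0))
        probs = forward(g, model)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_two_node_hand_computation(self):
        # one hidden layer, no attention, hand-set weights, L = [[1,-1],[-1,1]]
        X = np.array([[1.0, 2.0], [0.5, -1.0]])
        W = np.array([[0.0, 1.0], [1.0, 0.0]])
        th0 = np.array([[1.0, 0.0], [0.0, 1.0]])
        th1 = np.array([[1.0, -1.0], [2.0, 0.5]])
        model = TrainedModel(
            thetas=[th0, th1], attn_w=None, attn_b=None, history=[],
            config=ModelConfig(hidden_layers=1, attention_enabled=False),
            classes=np.array([0, 1]),
        )
        g = PopulationGraph(X=X, W=W, labels=np.array([0, 1]),
                            train_mask=np.ones(2, bool), test_mask=np.zeros(2, bool))
        probs = forward(g, model)
        # hand computation
        L = np.array([[1.0, -1.0], [-1.0, 1.0]])
        H = np.maximum(L @ X @ th0, 0.0)
        logits = L @ H @ th1
        expected = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        assert np.allclose(probs, expected, atol=1e-12)


class TestTraining:
    def test_recovers_planted_structure(self):
        g = planted_feature_graph(50, 5.0, seed=4)
        assert trained_acc(g, ModelConfig(seed=4)) >= 0.9

    def test_loss_decreases_early(self):
        g = planted_feature_graph(50, 5.0, seed=0)
        model = train(g, ModelConfig(seed=0, epochs=15))
        h = model.history
        assert np.mean(h[10:15]) < np.mean(h[0:5])

    def test_same_seed_identical_history(self):
        g = planted_feature_graph(20, 2.0, seed=1, n_features=8)
        cfg = ModelConfig(epochs=30, seed=5)
        m1, m2 = train(g, cfg), train(g, cfg)
        assert m1.history == m2.history
        for a, b in zip(m1.thetas, m2.thetas):
            assert np.array_equal(a, b)

    def test_single_class_mask_rejected(self):
        g = planted_feature_graph(10, 1.0, seed=0, n_features=4)
        g.labels[:] = 0
        with pytest.raises(ValueError):
            train(g, ModelConfig(epochs=2))

    def test_transductive_labels_never_leak(self):
        g = planted_feature_graph(20, 3.0, seed=2, n_features=8)
        cfg = ModelConfig(epochs=40, seed=9)
        m1 = train(g, cfg)
        g2 = planted_feature_graph(20, 3.0, seed=2, n_features=8)
        g2.labels[g2.test_mask] = 1 - g2.labels[g2.test_mask]  # corrupt held-out labels
        m2 = train(g2, cfg)
        for a, b in zip(m1.thetas, m2.thetas):
            assert np.array_equal(a, b)
        assert np.array_equal(m1.attn_w, m2.attn_w)

    def test_permutation_equivariance_without_dropout(self):
        g = planted_feature_graph(15, 3.0, seed=3, n_features=6)
        cfg = ModelConfig(epochs=30, seed=7, dropout=0.0)
        probs = forward(g, train(g, cfg))
        rng = np.random.default_rng(0)
        perm = rng.permutation(g.n_nodes)
        gp = PopulationGraph(
            X=g.X[perm], W=g.W[np.ix_(perm, perm)], labels=g.labels[perm],
            train_mask=g.train_mask[perm], test_mask=g.test_mask[perm],
        )
        probs_p = forward(gp, train(gp, cfg))
        assert np.allclose(probs_p, probs[perm], atol=1e-10)


class TestPredict:
    def test_argmax_and_tiebreak(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0]])
        W = np.zeros((2, 2))
        zero_model = TrainedModel(
            thetas=[np.zeros((2, 4)), np.zeros((4, 2))], attn_w=None, attn_b=None,
            history=[], config=ModelConfig(hidden_layers=1, attention_enabled=False),
            classes=np.array([3, 7]),
        )
        g = PopulationGraph(X=X, W=W, labels=np.array([3, 7]),
                            train_mask=np.ones(2, bool), test_mask=np.zeros(2, bool))
        labels, probs = predict(g, zero_model)
        assert np.allclose(probs, 0.5)  # exact tie
        assert np.all(labels == 3)  # lowest class index wins

    def test_memorizes_training_set(self):
        g = planted_feature_graph(30, 5.0, seed=6, n_features=10)
        model = train(g, ModelConfig(seed=6))
        pred, _ = predict(g, model, g.train_mask)
        assert (pred == g.labels[g.train_mask]).mean() >= 0.95


class TestCrossValidate:
    def test_separable_fixture_high_accuracy(self):
        g = planted_feature_graph(50, 10.0, seed=0)
        res = cross_validate(g.X, g.phenotypes, g.labels, ModelConfig(seed=0),
                             n_repeats=5)
        assert res["mean"]["acc"] >= 0.95

    def test_deterministic_splits(self):
        g = planted_feature_graph(30, 2.0, seed=1, n_features=8)
        cfg = ModelConfig(seed=3, epochs=20)
        r1 = cross_validate(g.X, g.phenotypes, g.labels, cfg, n_repeats=3)
        r2 = cross_validate(g.X, g.phenotypes, g.labels, cfg, n_repeats=3)
        assert r1["per_split"].equals(r2["per_split"])

    def test_shuffled_labels_chance_level(self):
        g = planted_feature_graph(40, 5.0, seed=2, n_features=10)
        rng = np.random.default_rng(0)
        shuffled = rng.permutation(g.labels)
        res = cross_validate(g.X, g.phenotypes, shuffled, ModelConfig(seed=0, epochs=50),
                             n_repeats=10)
        n_test = 8  # 10% of 40 per class, both classes
        sd = 0.5 / np.sqrt(n_test * 10)
        assert abs(res["mean"]["acc"] - 0.5) <= 3 * sd


class TestGridSearch:
    def test_single_point(self):
        g = planted_feature_graph(20, 3.0, seed=0, n_features=6)
        best, table = grid_search(
            g.X, g.phenotypes, g.labels, {"hidden_width": [8]},
            base_config=ModelConfig(epochs=20, seed=0), n_repeats=2,
        )
        assert best.hidden_width == 8
        assert len(table) == 1

    def test_table_size_and_selection(self):
        g = planted_feature_graph(40, 5.0, seed=1, n_features=10)
        best, table = grid_search(
            g.X, g.phenotypes, g.labels,
            {"epochs": [1, 200], "hidden_width": [16]},
            base_config=ModelConfig(seed=1), n_repeats=3,
        )
        assert len(table) == 2  # product of grid dimensions
        assert best.epochs == 200  # the crippled 1-epoch config loses

    def test_empty_grid(self):
        with pytest.raises(ValueError):
            grid_search(np.zeros((4, 2)), None, [0, 0, 1, 1], {})


class TestAttentionRanking:
    def test_uniform_map_flags_nothing(self):
        X = np.random.default_rng(0).standard_normal((10, 25))
        model = TrainedModel(
            thetas=[], attn_w=np.zeros((10, 25)), attn_b=np.zeros(25), history=[],
            config=ModelConfig(), classes=np.array([0, 1]),
        )
        table = rank_roi_attention(model, X, [f"r{i}" for i in range(25)])
        assert np.allclose(table["normalized_weight"], 1 / 25)
        assert not table["display"].any()  # 1/25 < 0.05
        assert table["normalized_weight"].sum() == pytest.approx(1.0)

    def test_attention_disabled_error(self):
        model = TrainedModel(thetas=[], attn_w=None, attn_b=None, history=[],
                             config=ModelConfig(attention_enabled=False),
                             classes=np.array([0, 1]))
        with pytest.raises(ValueError):
            rank_roi_attention(model, np.zeros((2, 2)), ["a", "b"])

    def test_signal_feature_ranks_high(self):
        # attribution configuration: no dropout, larger attention step
        cfg = ModelConfig(dropout=0.0, attention_lr=0.5)
        hits = 0
        for seed in range(20):
            g = planted_feature_graph(30, 5.0, seed=seed, n_features=10,
                                      informative_features=1)
            model = train(g, replace(cfg, seed=seed))
            table = rank_roi_attention(model, g.X, [f"f{i}" for i in range(10)])
            if "f0" in table["roi"].head(3).tolist():
                hits += 1
        assert hits >= 15


class TestCheckpointRoundTrip:
    def test_model_dict_round_trip(self):
        g = planted_feature_graph(10, 2.0, seed=0, n_features=5)
        model = train(g, ModelConfig(epochs=5, seed=0))
        clone = model_from_dict(model_to_dict(model))
        assert np.allclose(forward(g, clone), forward(g, model), atol=0)


def test_propagation_operator_kinds():
    W = np.array([[0.0, 1.0], [1.0, 0.0]])
    L = propagation_operator(W, "laplacian")
    S = propagation_operator(W, "renormalized")
    assert np.array_equal(L, [[1.0, -1.0], [-1.0, 1.0]])
    assert np.allclose(S, 0.5 * np.ones((2, 2)))
    with pytest.raises(ValueError):
        propagation_operator(W, "chebyshev")
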
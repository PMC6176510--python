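import numpy as np
import pytest

from eegsync.clfcnn import (
    CLFCNNConfig,
    OptimizerState,
    build_model,
    fit,
    forward,
    loss_and_gradients,
    predict,
    sgd_momentum_step,
    split_and_crossvalidate,
)


def toy_config(**kw):
    defaults = dict(
        input_dim=4,
        hidden_widths=(3, 2),
        dropout_input=0.0,
        seed=11,
        batch_size=8,
        max_epochs=20,
    )
    defaults.update(kw)
    return CLFCNNConfig(**defaults)


class TestBuildModel:
    def test_default_total_parameter_count(self):
        params = build_model(CLFCNNConfig())
        assert params.param_count == 55_252

    def test_default_edge_counts(self):
        params = build_model(CLFCNNConfig())
        expected = {
            (0, 1): 42_400,  # 529 -> 80
            (0, 2): 10_600,  # 529 -> 20
            (0, 3): 530,  # 529 -> 1
            (1, 2): 1_620,  # 80 -> 20
            (1, 3): 81,  # 80 -> 1
            (2, 3): 21,  # 20 -> 1
        }
        assert {e: params.edge_param_count(e) for e in params.edges} == expected

    def test_toy_widths_arithmetic(self):
        params = build_model(toy_config(input_dim=4, hidden_widths=(2,)))
        # edges (4->2)=10, (4->1)=5, (2->1)=3
        assert params.param_count == 18

    def test_count_matches_tensor_sum_random_widths(self, rng):
        for _ in range(10):
            widths = tuple(int(w) for w in rng.integers(1, 30, size=3)) + (1,)
            cfg = toy_config(input_dim=widths[0], hidden_widths=widths[1:3])
            params = build_model(cfg)
            brute = 0
            for i in range(1, 4):
                for j in range(i):
                    brute += widths[j] * widths[i] + widths[i]
            assert params.param_count == brute
            tensor_sum = sum(w.size for w in params.weights.values()) + sum(
                b.size for b in params.biases.values()
            )
            assert tensor_sum == brute

    def test_adjacent_only_edge_set(self):
        params = build_model(toy_config(cross_layer=False))
        assert params.edges == [(0, 1), (1, 2), (2, 3)]

    def test_bad_widths(self):
        with pytest.raises(ValueError):
            toy_config(hidden_widths=(0, 2))

    def test_seeded_init_reproducible(self):
        a = build_model(toy_config(), seed=3)
        b = build_model(toy_config(), seed=3)
        for e in a.edges:
            np.testing.assert_array_equal(a.weights[e], b.weights[e])


class TestForward:
    def test_zero_params_zero_output(self, rng):
        cfg = toy_config()
        params = build_model(cfg)
        for e in params.edges:
            params.weights[e][:] = 0.0
            params.biases[e][:] = 0.0
        out = forward(params, rng.normal(size=(5, 4)), cfg)
        np.testing.assert_array_equal(out, np.zeros(5))

    def test_output_non_negative(self, rng):
        cfg = toy_config()
        params = build_model(cfg)
        out = forward(params, rng.normal(size=(50, 4)), cfg)
        assert np.all(out >= 0.0)

    def test_hand_computed_toy_network(self):
        # widths 2 -> 1 -> 1, cross edges (0,1), (0,2), (1,2)
        cfg = CLFCNNConfig(input_dim=2, hidden_widths=(1,), dropout_input=0.0)
        params = build_model(cfg)
        params.weights[(0, 1)] = np.array([[1.0], [-2.0]])
        params.biases[(0, 1)] = np.array([0.5])
        params.weights[(0, 2)] = np.array([[3.0], [1.0]])
        params.biases[(0, 2)] = np.array([-1.0])
        params.weights[(1, 2)] = np.array([[2.0]])
        params.biases[(1, 2)] = np.array([0.25])
        x = np.array([[1.0, 2.0]])
        # layer1 = relu(1*1 + 2*(-2) + 0.5) = relu(-2.5) = 0
        # edge(0,2): relu(1*3 + 2*1 - 1) = 4; edge(1,2): relu(0*2 + 0.25) = 0.25
        assert forward(params, x, cfg)[0] == pytest.approx(4.25)

    def test_shape_mismatch(self):
        cfg = toy_config()
        params = build_model(cfg)
        with pytest.raises(ValueError):
            forward(params, np.zeros((2, 7)), cfg)

    def test_dropout_only_when_training(self, rng):
        cfg = toy_config(dropout_input=0.5)
        params = build_model(cfg)
        X = rng.normal(size=(20, 4))
        a = forward(params, X, cfg, training=False)
        b = forward(params, X, cfg, training=False)
        np.testing.assert_array_equal(a, b)
        t1 = forward(params, X, cfg, training=True,
                     rng=np.random.default_rng(0))
        t2 = forward(params, X, cfg, training=True,
                     rng=np.random.default_rng(1))
        assert not np.array_equal(t1, t2)


class TestLossAndGradients:
    def test_perfect_outputs_zero_everything(self):
        cfg = toy_config()
        params = build_model(cfg)
        for e in params.edges:
            params.weights[e][:] = 0.0
            params.biases[e][:] = 0.0
        loss, gw, gb = loss_and_gradients(
            params, np.ones((4, 4)), np.zeros(4), cfg
        )
        assert loss == 0.0
        # output and all rectifier gates are zero, so every gradient is zero
        assert all(np.all(g == 0) for g in gw.values())
        assert all(np.all(g == 0) for g in gb.values())

    def test_empty_batch(self):
        cfg = toy_config()
        params = build_model(cfg)
        with pytest.raises(ValueError, match="empty batch"):
            loss_and_gradients(params, np.zeros((0, 4)), np.zeros(0), cfg)

    @pytest.mark.parametrize("seed", range(20))
    def test_finite_difference_check(self, seed):
        gen = np.random.default_rng(seed)
        widths = tuple(int(w) for w in gen.integers(2, 7, size=2))
        cfg = CLFCNNConfig(
            input_dim=10, hidden_widths=widths, dropout_input=0.0, seed=seed
        )
        params = build_model(cfg, seed=seed)
        for e in params.edges:
            # zero biases leave rectifier inputs exactly at the kink (dead
            # units feed 0 * w + 0); nudge off it so central differences are
            # a valid oracle
            params.biases[e][:] = gen.normal(scale=0.1, size=params.biases[e].shape)
        X = gen.normal(size=(6, 10))
        y = gen.integers(0, 2, size=6).astype(float)
        _, gw, gb = loss_and_gradients(params, X, y, cfg, training=False)
        h = 1e-6
        for store, grads in ((params.weights, gw), (params.biases, gb)):
            for e in params.edges:
                tensor = store[e]
                flat_idx = gen.integers(0, tensor.size, size=min(5, tensor.size))
                for fi in np.unique(flat_idx):
                    idx = np.unravel_index(fi, tensor.shape)
                    orig = tensor[idx]
                    tensor[idx] = orig + h
                    lp, _, _ = loss_and_gradients(params, X, y, cfg)
                    tensor[idx] = orig - h
                    lm, _, _ = loss_and_gradients(params, X, y, cfg)
                    tensor[idx] = orig
                    fd = (lp - lm) / (2 * h)
                    g = grads[e][idx]
                    denom = max(abs(fd), abs(g), 1e-8)
                    assert abs(fd - g) / denom <= 1e-5

    def test_dead_unit_zero_gradient(self):
        cfg = CLFCNNConfig(input_dim=2, hidden_widths=(2,), dropout_input=0.0)
        params = build_model(cfg, seed=0)
        # unit 0 of the hidden layer: strongly negative pre-activation on a
        # positive-feature batch -> rectifier gates its incoming gradients
        params.weights[(0, 1)][:, 0] = -100.0
        params.biases[(0, 1)][0] = -100.0
        X = np.abs(np.random.default_rng(1).normal(size=(8, 2))) + 0.1
        y = np.ones(8)
        _, gw, gb = loss_and_gradients(params, X, y, cfg)
        np.testing.assert_array_equal(gw[(0, 1)][:, 0], 0.0)
        assert gb[(0, 1)][0] == 0.0


class TestSGDMomentumStep:
    def _scalar_setup(self, w0):
        cfg = CLFCNNConfig(input_dim=1, hidden_widths=(1,), dropout_input=0.0)
        params = build_model(cfg)
        for e in params.edges:
            params.weights[e][:] = 0.0
            params.biases[e][:] = 0.0
        params.weights[(0, 1)][0, 0] = w0
        return cfg, params

    def _zero_grads(self, params):
        gw = {e: np.zeros_like(w) for e, w in params.weights.items()}
        gb = {e: np.zeros_like(b) for e, b in params.biases.items()}
        return gw, gb

    def test_decay_only_step(self):
        cfg, params = self._scalar_setup(1.0)
        state = OptimizerState.zeros_like(params)
        gw, gb = self._zero_grads(params)
        sgd_momentum_step(params, state, gw, gb, cfg)
        assert state.velocity_w[(0, 1)][0, 0] == pytest.approx(-2e-6)
        assert params.weights[(0, 1)][0, 0] == pytest.approx(1.0 - 2e-6)

    def test_plain_gradient_step_at_zero_weight(self):
        cfg, params = self._scalar_setup(0.0)
        state = OptimizerState.zeros_like(params)
        gw, gb = self._zero_grads(params)
        gw[(0, 1)][0, 0] = 3.0
        sgd_momentum_step(params, state, gw, gb, cfg)
        assert params.weights[(0, 1)][0, 0] == pytest.approx(-cfg.learning_rate * 3.0)

    def test_two_steps_match_hand_recursion(self):
        cfg, params = self._scalar_setup(2.0)
        state = OptimizerState.zeros_like(params)
        g = 0.5
        v, w = 0.0, 2.0
        for _ in range(2):
            gw, gb = self._zero_grads(params)
            gw[(0, 1)][0, 0] = g
            sgd_momentum_step(params, state, gw, gb, cfg)
            v = 0.9 * v - 2e-4 * 0.01 * w - 0.01 * g
            w = w + v
        assert params.weights[(0, 1)][0, 0] == pytest.approx(w, rel=1e-12)

    def test_reduces_to_vanilla_gd(self, rng):
        cfg = toy_config(momentum=0.0, weight_decay=0.0, learning_rate=0.1)
        params = build_model(cfg, seed=1)
        before = params.copy()
        state = OptimizerState.zeros_like(params)
        gw = {e: rng.normal(size=w.shape) for e, w in params.weights.items()}
        gb = {e: rng.normal(size=b.shape) for e, b in params.biases.items()}
        sgd_momentum_step(params, state, gw, gb, cfg)
        for e in params.edges:
            np.testing.assert_allclose(
                params.weights[e], before.weights[e] - 0.1 * gw[e], atol=1e-15
            )

    def test_loss_non_increasing_small_rate(self, rng):
        cfg = toy_config(
            momentum=0.0, weight_decay=0.0, learning_rate=1e-3, seed=5
        )
        params = build_model(cfg, seed=5)
        state = OptimizerState.zeros_like(params)
        X = rng.normal(size=(16, 4))
        y = rng.integers(0, 2, size=16).astype(float)
        prev = np.inf
        for _ in range(10):
            loss, gw, gb = loss_and_gradients(params, X, y, cfg)
            assert loss <= prev + 1e-12
            sgd_momentum_step(params, state, gw, gb, cfg)
            prev = loss


def separable_dataset(n=200, dim=10, seed=0):
    gen = np.random.default_rng(seed)
    half = n // 2
    X = np.vstack(
        [
            gen.normal(loc=-2.0, scale=0.5, size=(half, dim)),
            gen.normal(loc=2.0, scale=0.5, size=(n - half, dim)),
        ]
    )
    y = np.concatenate([np.zeros(half), np.ones(n - half)])
    perm = gen.permutation(n)
    return X[perm], y[perm]


class TestFit:
    def test_separable_reaches_high_accuracy(self):
        X, y = separable_dataset()
        # the reference learning rate 0.01 with momentum 0.9 drives this
        # rectified-sum architecture into total unit death on small dense
        # problems; a smaller rate trains cleanly
        cfg = CLFCNNConfig(
            input_dim=10, hidden_widths=(16, 8), dropout_input=0.0,
            patience=30, max_epochs=300, seed=2, learning_rate=0.005,
        )
        params, history = fit(X, y, config=cfg)
        assert history.acc[-1] >= 0.99

    def test_epochs_bounded_and_history_lengths(self):
        X, y = separable_dataset(n=60)
        cfg = CLFCNNConfig(
            input_dim=10, hidden_widths=(4,), dropout_input=0.0,
            max_epochs=15, patience=2, seed=0,
        )
        params, history = fit(X, y, X, y, config=cfg)
        assert history.n_epochs <= 15
        assert len(history.loss) == history.n_epochs
        assert len(history.val_acc) == history.n_epochs
        assert len(history.val_loss) == history.n_epochs

    def test_empty_training_set(self):
        cfg = toy_config()
        with pytest.raises(ValueError):
            fit(np.zeros((0, 4)), np.zeros(0), config=cfg)


class TestPredict:
    def test_zero_output_is_non_seizure(self):
        cfg = toy_config()
        params = build_model(cfg)
        for e in params.edges:
            params.weights[e][:] = 0.0
        assert predict(params, np.ones((1, 4)), cfg)[0] == 0

    def test_threshold(self):
        cfg = CLFCNNConfig(input_dim=1, hidden_widths=(1,), dropout_input=0.0)
        params = build_model(cfg)
        for e in params.edges:
            params.weights[e][:] = 0.0
            params.biases[e][:] = 0.0
        params.biases[(0, 2)][0] = 0.7
        assert predict(params, np.zeros((1, 1)), cfg, threshold=0.5)[0] == 1
        assert predict(params, np.zeros((1, 1)), cfg, threshold=0.8)[0] == 0

    def test_order_preserved(self, rng):
        cfg = toy_config()
        params = build_model(cfg, seed=8)
        X = rng.normal(size=(30, 4))
        batch = predict(params, X, cfg)
        singles = np.array([predict(params, X[i : i + 1], cfg)[0] for i in range(30)])
        np.testing.assert_array_equal(batch, singles)


class TestSplitAndCrossvalidate:
    def _run(self, n=100, seed=7, max_epochs=20):
        X, y = separable_dataset(n=n, dim=4, seed=1)
        cfg = CLFCNNConfig(
            input_dim=4, hidden_widths=(6,), dropout_input=0.0,
            max_epochs=max_epochs, patience=5, seed=3, batch_size=16,
            learning_rate=0.001,
        )
        return split_and_crossvalidate(X, y, cfg, split_seed=seed)

    def test_split_proportions(self):
        result = self._run(n=100)
        assert len(result.split_indices["pool"]) == 80
        assert len(result.split_indices["test"]) == 20

    def test_folds_partition_pool(self):
        result = self._run()
        pool = set(result.split_indices["pool"].tolist())
        test = set(result.split_indices["test"].tolist())
        assert pool.isdisjoint(test)
        assert pool | test == set(range(100))
        assert len(result.fold_metrics) == 5

    def test_same_seed_same_split(self):
        a = self._run(seed=7, max_epochs=2)
        b = self._run(seed=7, max_epochs=2)
        np.testing.assert_array_equal(
            a.split_indices["pool"], b.split_indices["pool"]
        )
        np.testing.assert_array_equal(
            a.split_indices["test"], b.split_indices["test"]
        )

    def test_separable_test_metrics(self):
        result = self._run(max_epochs=100)
        assert result.test_metrics.accuracy >= 0.9

    def test_dataset_smaller_than_folds(self):
        cfg = toy_config()
        with pytest.raises(ValueError):
            split_and_crossvalidate(np.zeros((3, 4)), np.zeros(3), cfg, n_folds=5)
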
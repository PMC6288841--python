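import numpy as np
import pytest

from gxepred.densenet import (
    NetConfig,
    NetworkState,
    _loss_and_grads,
    dropout_mask,
    forward,
    init_network,
    predict_net,
    train_network,
)


def _hand_state(output_activation="relu"):
    """x=[1,2] -> hidden relu([[1,0],[0,1]]x + [0,-3]) = [1,0] -> relu(2*1+5*0+1) = 3."""
    return NetworkState(
        weights=[np.array([[1.0, 0.0], [0.0, 1.0]]), np.array([[2.0], [5.0]])],
        biases=[np.array([0.0, -3.0]), np.array([1.0])],
        hidden_activation="relu",
        output_activation=output_activation,
        x_mean=np.zeros(2),
        x_scale=np.ones(2),
    )


class TestInitNetwork:
    def test_same_seed_same_weights(self):
        cfg = NetConfig(n_layers=2, n_units=7, seed=42)
        a, b = init_network(5, cfg), init_network(5, cfg)
        for wa, wb in zip(a.weights, b.weights):
            assert np.array_equal(wa, wb)

    def test_layer_shapes_chain(self):
        cfg = NetConfig(n_layers=2, n_units=50)
        st = init_network(23, cfg)
        assert [w.shape for w in st.weights] == [(23, 50), (50, 50), (50, 1)]
        assert all(np.all(b == 0) for b in st.biases)

    def test_zero_layers_rejected(self):
        with pytest.raises(ValueError):
            NetConfig(n_layers=0)


class TestForward:
    def test_zero_network_outputs_zero(self):
        st = _hand_state()
        for w in st.weights:
            w[:] = 0.0
        for b in st.biases:
            b[:] = 0.0
        assert forward(st, np.array([3.0, -2.0])) == 0.0

    def test_hand_computed_pass(self):
        assert forward(_hand_state(), np.array([1.0, 2.0])) == pytest.approx(3.0)

    def test_relu_output_is_nonnegative(self, rng):
        cfg = NetConfig(n_layers=2, n_units=6, seed=1)
        st = init_network(4, cfg)
        X = rng.standard_normal((50, 4))
        assert np.all(predict_net(st, X) >= 0.0)

    def test_destandardization_inverts_target_scaling(self):
        st = _hand_state(output_activation="linear")
        for w in st.weights:
            w[:] = 0.0
        for b in st.biases:
            b[:] = 0.0
        st.y_mean, st.y_scale = 10.0, 2.0
        assert forward(st, np.array([0.0, 0.0])) == pytest.approx(10.0)

    def test_mask_shape_mismatch_rejected(self):
        st = _hand_state()
        with pytest.raises(ValueError, match="mask"):
            forward(st, np.array([1.0, 2.0]), dropout_masks=[np.ones(3)])


class TestDropoutMask:
    def test_rate_zero_is_all_ones(self):
        assert np.array_equal(dropout_mask(10, 0.0, 1), np.ones(10))

    def test_zeroed_fraction_matches_rate(self):
        rng = np.random.default_rng(8)
        zeroed = [np.mean(dropout_mask(1000, 0.3, rng) == 0.0) for _ in range(1000)]
        assert abs(np.mean(zeroed) - 0.30) < 0.01

    def test_inverted_scaling_is_unbiased(self, rng):
        # E[mask * a] = a: survivors are scaled by 1/(1-rate)
        acts = rng.standard_normal(20)
        means = np.zeros(20)
        for _ in range(10_000):
            means += dropout_mask(20, 0.4, rng) * acts
        means /= 10_000
        assert np.max(np.abs(means - acts)) < 0.05

    def test_rate_one_rejected(self):
        with pytest.raises(ValueError):
            dropout_mask(10, 1.0, 0)


class TestGradients:
    """Analytic backprop against central finite differences — the module's core oracle."""

    @pytest.mark.parametrize("hidden,out,n_layers", [
        ("relu", "linear", 1),
        ("relu", "relu", 2),
        ("linear", "linear", 2),
    ])
    def test_matches_finite_differences(self, hidden, out, n_layers, rng):
        cfg = NetConfig(n_layers=n_layers, n_units=5, seed=3,
                        hidden_activation=hidden, output_activation=out)
        st = init_network(4, cfg)
        st.biases = [rng.standard_normal(b.shape) * 0.1 for b in st.biases]
        X = rng.standard_normal((7, 4))
        z = rng.standard_normal(7) + 2.0
        loss, gW, gb = _loss_and_grads(st, X, z)
        eps = 1e-6
        for params, grads in ((st.weights, gW), (st.biases, gb)):
            for arr, g in zip(params, grads):
                for idx in np.ndindex(arr.shape):
                    arr[idx] += eps
                    lp, *_ = _loss_and_grads(st, X, z)
                    arr[idx] -= 2 * eps
                    lm, *_ = _loss_and_grads(st, X, z)
                    arr[idx] += eps
                    num = (lp - lm) / (2 * eps)
                    assert abs(num - g[idx]) <= 1e-5 * max(1.0, abs(num))

    def test_matches_finite_differences_with_dropout_masks(self, rng):
        cfg = NetConfig(n_layers=2, n_units=4, seed=5)
        st = init_network(3, cfg)
        X = rng.standard_normal((6, 3))
        z = rng.standard_normal(6) + 2.0
        masks = [np.stack([dropout_mask(4, 0.5, rng) for _ in range(6)]) for _ in range(2)]
        _, gW, _ = _loss_and_grads(st, X, z, masks)
        eps = 1e-6
        arr = st.weights[0]
        for idx in np.ndindex(arr.shape):
            arr[idx] += eps
            lp, *_ = _loss_and_grads(st, X, z, masks)
            arr[idx] -= 2 * eps
            lm, *_ = _loss_and_grads(st, X, z, masks)
            arr[idx] += eps
            num = (lp - lm) / (2 * eps)
            assert abs(num - gW[0][idx]) <= 1e-5 * max(1.0, abs(num))


class TestTrainNetwork:
    def test_zero_epochs_is_a_noop(self, rng):
        cfg = NetConfig(n_epochs=0, seed=1)
        st = init_network(3, cfg)
        trained, trace = train_network(st, rng.standard_normal((10, 3)), rng.standard_normal(10), cfg)
        assert trace == []
        for wa, wb in zip(st.weights, trained.weights):
            assert np.array_equal(wa, wb)

    def test_loss_drops_on_noiseless_relu_target(self, rng):
        w = rng.standard_normal(4)
        X = rng.standard_normal((200, 4))
        y = np.maximum(X @ w, 0.0)
        cfg = NetConfig(n_layers=1, n_units=32, n_epochs=200, dropout_rate=0.0, seed=1)
        st = init_network(4, cfg)
        _, trace = train_network(st, X, y, cfg)
        assert trace[-1] < 0.1 * trace[0]

    def test_longer_run_prefixes_shorter_loss_trace(self, rng):
        X = rng.standard_normal((40, 3))
        y = rng.standard_normal(40)
        cfg_short = NetConfig(n_epochs=5, n_units=8, seed=4)
        cfg_long = NetConfig(n_epochs=10, n_units=8, seed=4)
        _, t_short = train_network(init_network(3, cfg_short), X, y, cfg_short)
        _, t_long = train_network(init_network(3, cfg_long), X, y, cfg_long)
        assert t_long[:5] == t_short

    def test_linear_net_approaches_least_squares(self, rng):
        # dropout 0, single linear hidden layer: training converges toward OLS
        X = rng.standard_normal((60, 3))
        beta = np.array([1.5, -2.0, 0.5])
        y = X @ beta + 3.0
        cfg = NetConfig(n_layers=1, n_units=8, n_epochs=600, dropout_rate=0.0,
                        hidden_activation="linear", output_activation="linear",
                        learning_rate=0.01, seed=2)
        trained, _ = train_network(init_network(3, cfg), X, y, cfg)
        Xd = np.column_stack([X, np.ones(60)])
        ls_pred = Xd @ np.linalg.lstsq(Xd, y, rcond=None)[0]
        assert np.max(np.abs(predict_net(trained, X) - ls_pred)) < 0.05

    def test_relu_output_can_fit_negative_targets(self, rng):
        # the standardize-and-shift scheme lets a ReLU output reach negatives
        X = rng.standard_normal((80, 2))
        y = X[:, 0] - 5.0  # strictly negative targets
        cfg = NetConfig(n_layers=1, n_units=16, n_epochs=300, dropout_rate=0.0, seed=6)
        trained, _ = train_network(init_network(2, cfg), X, y, cfg)
        pred = predict_net(trained, X)
        assert pred.min() < -3.0
        assert np.corrcoef(pred, y)[0, 1] > 0.9

    def test_empty_training_set_rejected(self):
        cfg = NetConfig(n_epochs=1)
        with pytest.raises(ValueError):
            train_network(init_network(2, cfg), np.empty((0, 2)), np.empty(0), cfg)


class TestPredictNet:
    def test_prediction_is_deterministic(self, rng):
        cfg = NetConfig(n_layers=2, n_units=6, seed=9)
        st = init_network(5, cfg)
        X = rng.standard_normal((20, 5))
        assert np.array_equal(predict_net(st, X), predict_net(st, X))

    def test_hand_oracle_prediction(self):
        assert predict_net(_hand_state(), np.array([[1.0, 2.0]]))[0] == pytest.approx(3.0)

    def test_dimension_mismatch_rejected(self, rng):
        st = init_network(5, NetConfig())
        with pytest.raises(ValueError):
            predict_net(st, rng.standard_normal((4, 3)))
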
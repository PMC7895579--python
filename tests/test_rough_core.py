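"""Rough-neuron forward pass, backpropagation and training dynamics."""

import copy
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from inrnn import (ConfigurationError, OutputLayer, RNNConfig, RNNModel,
                   RoughLayer, backprop_step, baum_haussler_hidden_count,
                   network_forward, rough_layer_forward, sigmoid, train_rnn)
from conftest import (analytic_gradient_via_update, numeric_gradient,
                      random_tiny_model)


class TestHiddenSizing:
    @pytest.mark.parametrize("args, expected", [
        ((1701, 0.1, 21, 3), 7),    # 170.1/24 = 7.0875, floored
        ((10, 0.01, 21, 3), 1),     # clamped at 1
        ((2400, 0.1, 21, 3), 10),   # 240/24 exactly
    ])
    def test_rule(self, args, expected):
        assert baum_haussler_hidden_count(*args) == expected

    def test_nonpositive_arguments_rejected(self):
        with pytest.raises(ConfigurationError):
            baum_haussler_hidden_count(0, 0.1, 21, 3)


class TestSigmoid:
    def test_zero_maps_to_half_for_any_steepness(self):
        for lam in (0.1, 1.0, 5.0):
            assert sigmoid(0.0, lam) == 0.5

    def test_closed_form_value(self):
        assert sigmoid(math.log(3), 1.0) == pytest.approx(0.75, abs=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(-50, 50), st.floats(0.1, 5))
    def test_antisymmetry(self, x, lam):
        assert sigmoid(-x, lam) == pytest.approx(1 - sigmoid(x, lam),
                                                 abs=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(-10, 10), st.floats(0.1, 2))
    def test_strictly_increasing_away_from_saturation(self, x, lam):
        assert sigmoid(x + 0.5, lam) > sigmoid(x, lam)


def _single_neuron_layer(w_lower, w_upper):
    return RoughLayer(np.array([[w_lower]]), np.array([[w_upper]]),
                      np.zeros(1), np.zeros(1))


class TestRoughLayerForward:
    def test_branch_swap_worked_example(self):
        # Lower weights give the *larger* activation here, so branches swap.
        frag = rough_layer_forward(np.array([1.0]),
                                   _single_neuron_layer(0.4, -0.2), 1.0)
        assert frag["I_lower"][0] == pytest.approx(0.4)
        assert frag["I_upper"][0] == pytest.approx(-0.2)
        assert frag["O_lower"][0] == pytest.approx(0.4502, abs=1e-4)
        assert frag["O_upper"][0] == pytest.approx(0.5987, abs=1e-4)
        assert frag["O_combined"][0] == pytest.approx(1.0489, abs=1e-4)
        assert frag["swapped"][0]

    def test_equal_weight_pair_collapses(self):
        frag = rough_layer_forward(np.array([1.0]),
                                   _single_neuron_layer(0.3, 0.3), 1.0)
        assert frag["O_lower"][0] == frag["O_upper"][0]
        assert frag["O_combined"][0] == pytest.approx(
            2 * sigmoid(0.3, 1.0))
        assert frag["tied"][0]

    def test_lower_never_exceeds_upper_on_random_layers(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            layer = RoughLayer(rng.normal(size=(4, 3)),
                               rng.normal(size=(4, 3)),
                               rng.normal(size=4), rng.normal(size=4))
            frag = rough_layer_forward(rng.uniform(size=3), layer, 1.0)
            assert np.all(frag["O_lower"] <= frag["O_upper"])
            assert np.all((frag["O_combined"] >= 0)
                          & (frag["O_combined"] <= 2))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            rough_layer_forward(np.ones(2), _single_neuron_layer(0.1, 0.2),
                                1.0)


def _tiny_model(output_weight=1.0):
    config = RNNConfig(hidden_sizes=(1,))
    return RNNModel(n_inputs=1, layers=[_single_neuron_layer(0.4, -0.2)],
                    output=OutputLayer(np.array([[output_weight]]),
                                       np.zeros(1)),
                    config=config)


class TestNetworkForward:
    def test_chained_worked_example(self):
        scores, state = network_forward(np.array([1.0]), _tiny_model())
        assert scores[0] == pytest.approx(0.7406, abs=1e-4)
        assert state.output_input[0] == pytest.approx(1.0489, abs=1e-4)

    def test_all_zero_weights_score_half(self):
        model = _tiny_model()
        model.layers[0].W_lower[:] = 0
        model.layers[0].W_upper[:] = 0
        model.output.W[:] = 0
        scores, _ = network_forward(np.array([0.7]), model)
        assert scores[0] == 0.5

    def test_scores_bounded_on_random_models(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            model = random_tiny_model(rng)
            scores, _ = network_forward(rng.uniform(size=3), model)
            assert np.all((scores > 0) & (scores < 1))

    def test_equal_weight_pairs_match_plain_mlp(self):
        """With W_L = W_U the network is a conventional MLP whose hidden
        activations are doubled; verify against an independent forward."""
        rng = np.random.default_rng(13)
        model = random_tiny_model(rng, n_in=4, hidden=(3,), n_out=2)
        layer = model.layers[0]
        layer.W_upper[:] = layer.W_lower
        layer.b_upper[:] = layer.b_lower
        x = rng.uniform(size=4)
        scores, _ = network_forward(x, model)

        lam = model.config.lambda_
        hidden = 2.0 / (1.0 + np.exp(-lam * (layer.W_lower @ x
                                             + layer.b_lower)))
        expected = 1.0 / (1.0 + np.exp(-lam * (model.output.W @ hidden
                                               + model.output.b)))
        np.testing.assert_allclose(scores, expected, atol=1e-12)


class TestBackprop:
    def test_zero_error_leaves_weights_unchanged(self):
        model = _tiny_model()
        scores, _ = network_forward(np.array([1.0]), model)
        before = copy.deepcopy(model)
        backprop_step(model, np.array([1.0]), scores, gamma=0.5)
        np.testing.assert_array_equal(model.output.W, before.output.W)
        np.testing.assert_array_equal(model.layers[0].W_lower,
                                      before.layers[0].W_lower)

    def test_small_step_decreases_squared_error(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            model = random_tiny_model(rng)
            x = rng.uniform(size=3)
            target = np.array([1.0, 0.0])
            before = backprop_step(model, x, target, gamma=0.05)
            scores, _ = network_forward(x, model)
            after = float(np.sum((target - scores) ** 2))
            assert after <= before

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(17)
        for _ in range(5):
            model = random_tiny_model(rng)
            x = rng.uniform(size=3)
            target = rng.integers(0, 2, size=2).astype(float)
            analytic = analytic_gradient_via_update(model, x, target)
            numeric = numeric_gradient(model, x, target)
            for a, n in zip(analytic, numeric):
                np.testing.assert_allclose(a, n, atol=1e-5)


class TestTraining:
    def test_two_class_separable_data_learned(self):
        rng = np.random.default_rng(21)
        n = 60
        labels = np.repeat([0, 1], n // 2)
        features = rng.normal(size=(n, 2)) * 0.3 + labels[:, None] * 3.0
        features = (features - features.min(0)) / np.ptp(features, 0)
        targets = np.eye(2)[labels]
        config = RNNConfig(max_epochs=500, target_mse=1e-3, gamma=0.5,
                           seed=2, hidden_sizes=(3,))
        model = train_rnn(features, targets, config)
        correct = sum(
            int(np.argmax(network_forward(features[i], model)[0])
                == labels[i]) for i in range(n))
        assert correct / n >= 0.95

    def test_identical_seed_reproduces_loss_trace(self):
        rng = np.random.default_rng(4)
        features = rng.uniform(size=(20, 3))
        targets = np.eye(2)[rng.integers(0, 2, size=20)]
        config = RNNConfig(max_epochs=30, seed=8, hidden_sizes=(2,))
        a = train_rnn(features, targets, config)
        b = train_rnn(features, targets, config)
        assert a.loss_trace == b.loss_trace
        np.testing.assert_array_equal(a.output.W, b.output.W)
        np.testing.assert_array_equal(a.layers[0].W_lower, b.layers[0].W_lower)

    def test_loss_trace_trends_downward_on_separable_data(self):
        rng = np.random.default_rng(6)
        labels = np.repeat([0, 1], 15)
        features = rng.normal(size=(30, 2)) * 0.2 + labels[:, None] * 2.0
        features = (features - features.min(0)) / np.ptp(features, 0)
        config = RNNConfig(max_epochs=120, target_mse=1e-6, gamma=0.5,
                           seed=5, hidden_sizes=(2,))
        model = train_rnn(features, np.eye(2)[labels], config)
        trace = np.array(model.loss_trace)
        assert np.all(np.isfinite(trace))
        # trailing-window means decrease (per-sample updates are noisy)
        windows = [trace[i:i + 20].mean() for i in range(0, 100, 20)]
        assert windows[-1] < windows[0]
        assert trace[-20:].mean() <= trace[:20].mean()

    def test_empty_training_set_rejected(self):
        with pytest.raises(ConfigurationError):
            train_rnn(np.empty((0, 3)), np.empty((0, 2)), RNNConfig())

    def test_model_dict_round_trip(self):
        rng = np.random.default_rng(9)
        model = random_tiny_model(rng)
        clone = RNNModel.from_dict(model.to_dict())
        x = rng.uniform(size=3)
        np.testing.assert_allclose(network_forward(x, clone)[0],
                                   network_forward(x, model)[0], atol=1e-15)
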
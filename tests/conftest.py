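"""Shared fixtures: published worked-example tables and trained models.

The membership tables are the worked three-class example published with
the method: five instances, per-class true (T), indeterminacy (I) and
false (F) memberships, their binarized codewords and resolved classes,
plus a 425-instance confusion matrix. They serve as exact fixtures for
the neutrosophic stage and the metrics.
"""

import numpy as np
import pytest

from inrnn import RNNConfig, fit_dual, generate_separable

# Worked-example memberships: rows are instances, columns classes (N, S, P).
TABLE_T = np.array([
    [0.50031, 0.22042, 0.02296],
    [0.99950, 0.00634, 0.00000],
    [0.19951, 0.60074, 0.12381],
    [0.13034, 0.57034, 0.19766],
    [0.14003, 0.00432, 0.98561],
])
TABLE_I = np.array([
    [0.91964, 0.33285, 0.08015],
    [0.08838, 0.01891, 0.02225],
    [0.22239, 0.72470, 0.69965],
    [0.23205, 0.81184, 0.25765],
    [0.64750, 0.00455, 0.18190],
])
TABLE_F = np.array([
    [0.58067, 0.88756, 0.94281],
    [0.08788, 0.98743, 0.97775],
    [0.97712, 0.87604, 0.42416],
    [0.89829, 0.38218, 0.94000],
    [0.49253, 0.99977, 0.16750],
])
# Published binary codewords for the same five instances.
TABLE_BITS = np.array([
    [0, 0, 0],
    [1, 0, 0],
    [0, 0, 0],
    [0, 1, 0],
    [0, 0, 1],
])
TABLE_PREDICTED = ["N", "N", "S", "S", "P"]

# Published 425-instance confusion matrix (rows actual, columns predicted).
TABLE_CONFUSION = np.array([
    [335, 6, 1],
    [11, 41, 0],
    [0, 3, 28],
])


@pytest.fixture(scope="session")
def worked_tables():
    return {"T": TABLE_T, "I": TABLE_I, "F": TABLE_F,
            "bits": TABLE_BITS, "predicted": TABLE_PREDICTED,
            "confusion": TABLE_CONFUSION}


@pytest.fixture(scope="session")
def fast_config():
    """Training budget small enough for the suite, large enough to converge
    on well-separated clusters."""
    return RNNConfig(max_epochs=100, target_mse=5e-3, gamma=0.5, seed=0)


@pytest.fixture(scope="session")
def separable300():
    return generate_separable(300, seed=1)


@pytest.fixture(scope="session")
def trained_dual(separable300, fast_config):
    """One dual model trained on the separable preset, shared across tests."""
    return fit_dual(separable300, fast_config.with_seed(11))


def random_tiny_model(rng, n_in=3, hidden=(2,), n_out=2, lambda_=1.3):
    """A small rough network with weights drawn wide enough that some
    neurons land in the branch-swapped regime (upper weights producing
    the smaller activation)."""
    from inrnn import RNNConfig
    from inrnn.rough_core import _init_model
    config = RNNConfig(lambda_=lambda_, seed=int(rng.integers(2**31)),
                       init_scale=1.5, hidden_sizes=tuple(hidden))
    return _init_model(n_in, tuple(hidden), n_out, config)


def numeric_gradient(model, x, target, h=1e-6):
    """Central finite differences of the loss 0.5·Σ(T − score)² with
    respect to every weight array, as a dict of arrays per layer."""
    import numpy as np
    from inrnn import network_forward

    def loss():
        scores, _ = network_forward(x, model)
        return 0.5 * float(np.sum((target - scores) ** 2))

    arrays = []
    for layer in model.layers:
        arrays += [layer.W_lower, layer.W_upper, layer.b_lower, layer.b_upper]
    arrays += [model.output.W, model.output.b]
    grads = []
    for arr in arrays:
        g = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = arr[idx]
            arr[idx] = orig + h
            up = loss()
            arr[idx] = orig - h
            down = loss()
            arr[idx] = orig
            g[idx] = (up - down) / (2 * h)
        grads.append(g)
    return grads


def analytic_gradient_via_update(model, x, target, gamma=1e-3):
    """Recover the analytic gradient from one backprop step:
    Δw = −γ·g  ⇒  g = (w_before − w_after)/γ. Restores the model."""
    import copy

    import numpy as np
    from inrnn import backprop_step

    before = copy.deepcopy(model)
    backprop_step(model, x, target, gamma)
    pairs = []
    for lb, la in zip(before.layers, model.layers):
        pairs += [(lb.W_lower, la.W_lower), (lb.W_upper, la.W_upper),
                  (lb.b_lower, la.b_lower), (lb.b_upper, la.b_upper)]
    pairs += [(before.output.W, model.output.W),
              (before.output.b, model.output.b)]
    grads = [(b - a) / gamma for b, a in pairs]
    # restore
    for lb, la in zip(before.layers, model.layers):
        la.W_lower[:], la.W_upper[:] = lb.W_lower, lb.W_upper
        la.b_lower[:], la.b_upper[:] = lb.b_lower, lb.b_upper
    model.output.W[:] = before.output.W
    model.output.b[:] = before.output.b
    return grads
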
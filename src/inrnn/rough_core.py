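"""Rough neural networks: paired lower/upper weights with min/max routing.

A rough neuron keeps two weight vectors, a lower and an upper set. Both
produce a pre-activation from the same inputs; after the sigmoid, the
smaller activation becomes the neuron's lower output O_L and the larger
its upper output O_U (the branches swap whenever the "upper" weights
happen to produce the smaller value). The neuron emits their sum
O = O_L + O_U ∈ [0, 2], which feeds the next layer. Input and output
layers are conventional sigmoid neurons, so final scores live in [0, 1]
and can serve directly as membership degrees.

Training is plain stochastic backpropagation of the squared error
0.5·Σ(T − O)² with per-sample updates and per-epoch shuffling. The
gradient through the min/max routing is sent to whichever weight set
produced each branch; because the emitted quantity is the *sum* of the
two branches, this routed gradient coincides with the smooth gradient
of f(I_L) + f(I_U), so finite-difference checks pass everywhere,
branch swaps and ties included.

The hidden width defaults to the Baum–Haussler sizing heuristic
n_train·Te/(n_in + n_out).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data_io import ConfigurationError

__all__ = [
    "RNNConfig",
    "RoughLayer",
    "OutputLayer",
    "ForwardState",
    "RNNModel",
    "baum_haussler_hidden_count",
    "sigmoid",
    "rough_layer_forward",
    "network_forward",
    "backprop_step",
    "train_rnn",
]


@dataclass(frozen=True)
class RNNConfig:
    """Hyperparameters of a rough neural network.

    Attributes
    ----------
    lambda_ : float
        Sigmoid steepness λ in f(x) = 1/(1 + e^{−λx}).
    gamma : float
        Learning rate γ of the delta rule.
    tol_error : float
        Tolerance error Te of the Baum–Haussler hidden-layer sizing.
    max_epochs : int
        Hard cap on training epochs.
    target_mse : float
        Stop once the epoch's mean squared error falls to this level.
    init_scale : float
        Weights start uniform in [−init_scale, +init_scale].
    seed : int
        Seeds both initialization and per-epoch shuffling.
    hidden_sizes : tuple of int, optional
        Explicit rough-layer widths; when None the first (only) hidden
        layer is sized by the Baum–Haussler rule at fit time.
    use_bias : bool
        Include a bias per neuron (a weight on a constant input of 1).
    """

    lambda_: float = 1.0
    gamma: float = 0.1
    tol_error: float = 0.1
    max_epochs: int = 1000
    target_mse: float = 1e-3
    init_scale: float = 0.5
    seed: int = 0
    hidden_sizes: tuple[int, ...] | None = None
    use_bias: bool = True

    def __post_init__(self) -> None:
        if self.lambda_ <= 0 or self.gamma <= 0 or self.init_scale <= 0:
            raise ConfigurationError("lambda_, gamma and init_scale must be > 0")
        if self.max_epochs < 1:
            raise ConfigurationError("max_epochs must be >= 1")
        if self.tol_error <= 0:
            raise ConfigurationError("tol_error must be > 0")

    def with_seed(self, seed: int) -> "RNNConfig":
        return replace(self, seed=seed)


def baum_haussler_hidden_count(n_train: int, tol_error: float,
                               n_in: int, n_out: int) -> int:
    """Hidden-neuron count n_train·Te/(n_in + n_out), floored, at least 1."""
    if n_train <= 0 or tol_error <= 0 or n_in <= 0 or n_out <= 0:
        raise ConfigurationError("all sizing arguments must be positive")
    return max(1, int(n_train * tol_error / (n_in + n_out)))


def sigmoid(x, lambda_: float = 1.0):
    """Logistic activation 1/(1 + e^{−λx}); strictly increasing in x."""
    if lambda_ <= 0:
        raise ConfigurationError("lambda_ must be > 0")
    # scipy.special.expit is equivalent; the direct form keeps λ explicit.
    return 1.0 / (1.0 + np.exp(-lambda_ * np.asarray(x, dtype=float)))


@dataclass
class RoughLayer:
    """Paired lower/upper weight matrices (n_neurons × n_inputs) + biases."""

    W_lower: np.ndarray
    W_upper: np.ndarray
    b_lower: np.ndarray
    b_upper: np.ndarray

    @property
    def n_neurons(self) -> int:
        return self.W_lower.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.W_lower.shape[1]


@dataclass
class OutputLayer:
    """Conventional sigmoid output layer."""

    W: np.ndarray
    b: np.ndarray

    @property
    def n_neurons(self) -> int:
        return self.W.shape[0]


@dataclass
class ForwardState:
    """Everything cached during a forward pass, per rough layer.

    ``swapped`` marks neurons whose lower output came from the *upper*
    weight set (i.e. f(I_U) < f(I_L)); ``tied`` marks exact equality.
    """

    layer_inputs: list[np.ndarray]
    I_lower: list[np.ndarray]
    I_upper: list[np.ndarray]
    f_lower: list[np.ndarray]
    f_upper: list[np.ndarray]
    O_lower: list[np.ndarray]
    O_upper: list[np.ndarray]
    O_combined: list[np.ndarray]
    swapped: list[np.ndarray]
    tied: list[np.ndarray]
    output_input: np.ndarray | None = None
    scores: np.ndarray | None = None


@dataclass
class RNNModel:
    """A trained (or initialized) rough neural network."""

    n_inputs: int
    layers: list[RoughLayer]
    output: OutputLayer
    config: RNNConfig
    loss_trace: list[float] = field(default_factory=list)

    @property
    def n_outputs(self) -> int:
        return self.output.n_neurons

    def to_dict(self) -> dict:
        return {
            "n_inputs": self.n_inputs,
            "layers": [
                {"W_lower": l.W_lower.tolist(), "W_upper": l.W_upper.tolist(),
                 "b_lower": l.b_lower.tolist(), "b_upper": l.b_upper.tolist()}
                for l in self.layers
            ],
            "output": {"W": self.output.W.tolist(),
                       "b": self.output.b.tolist()},
            "config": {
                "lambda_": self.config.lambda_,
                "gamma": self.config.gamma,
                "tol_error": self.config.tol_error,
                "max_epochs": self.config.max_epochs,
                "target_mse": self.config.target_mse,
                "init_scale": self.config.init_scale,
                "seed": self.config.seed,
                "hidden_sizes": list(self.config.hidden_sizes)
                if self.config.hidden_sizes is not None else None,
                "use_bias": self.config.use_bias,
            },
            "loss_trace": self.loss_trace,
        }

    @classmethod
    def from_dict(cls, blob: dict) -> "RNNModel":
        cfg = dict(blob["config"])
        if cfg.get("hidden_sizes") is not None:
            cfg["hidden_sizes"] = tuple(cfg["hidden_sizes"])
        layers = [RoughLayer(np.array(l["W_lower"]), np.array(l["W_upper"]),
                             np.array(l["b_lower"]), np.array(l["b_upper"]))
                  for l in blob["layers"]]
        out = OutputLayer(np.array(blob["output"]["W"]),
                          np.array(blob["output"]["b"]))
        return cls(n_inputs=int(blob["n_inputs"]), layers=layers, output=out,
                   config=RNNConfig(**cfg),
                   loss_trace=list(blob.get("loss_trace", [])))


def rough_layer_forward(inputs: np.ndarray, layer: RoughLayer,
                        lambda_: float) -> dict:
    """One rough layer's forward pass.

    Returns a fragment with pre-activations I_L/I_U, both sigmoid
    activations, the routed lower/upper outputs, the swap/tie masks and
    the combined output O = O_L + O_U.
    """
    inputs = np.asarray(inputs, dtype=float)
    if inputs.shape != (layer.n_inputs,):
        raise ConfigurationError(
            f"input width {inputs.shape} does not match layer width "
            f"({layer.n_inputs},)")
    I_lower = layer.W_lower @ inputs + layer.b_lower
    I_upper = layer.W_upper @ inputs + layer.b_upper
    f_lower = sigmoid(I_lower, lambda_)
    f_upper = sigmoid(I_upper, lambda_)
    swapped = f_upper < f_lower          # upper weights produced the min
    tied = f_upper == f_lower
    O_lower = np.minimum(f_lower, f_upper)
    O_upper = np.maximum(f_lower, f_upper)
    return {
        "inputs": inputs, "I_lower": I_lower, "I_upper": I_upper,
        "f_lower": f_lower, "f_upper": f_upper,
        "O_lower": O_lower, "O_upper": O_upper,
        "swapped": swapped, "tied": tied,
        "O_combined": O_lower + O_upper,
    }


def network_forward(features: np.ndarray,
                    model: RNNModel) -> tuple[np.ndarray, ForwardState]:
    """Full forward pass; returns output scores in [0,1] and the cached state."""
    x = np.asarray(features, dtype=float)
    if x.shape != (model.n_inputs,):
        raise ConfigurationError(
            f"feature width {x.shape} does not match model input width "
            f"({model.n_inputs},)")
    lam = model.config.lambda_
    state = ForwardState([], [], [], [], [], [], [], [], [], [])
    for layer in model.layers:
        frag = rough_layer_forward(x, layer, lam)
        state.layer_inputs.append(frag["inputs"])
        state.I_lower.append(frag["I_lower"])
        state.I_upper.append(frag["I_upper"])
        state.f_lower.append(frag["f_lower"])
        state.f_upper.append(frag["f_upper"])
        state.O_lower.append(frag["O_lower"])
        state.O_upper.append(frag["O_upper"])
        state.O_combined.append(frag["O_combined"])
        state.swapped.append(frag["swapped"])
        state.tied.append(frag["tied"])
        x = frag["O_combined"]
    state.output_input = x
    scores = sigmoid(model.output.W @ x + model.output.b, lam)
    state.scores = scores
    return scores, state


def _gradients(model: RNNModel, state: ForwardState,
               target: np.ndarray) -> list[dict]:
    """Analytic gradients of 0.5·Σ(T − score)² w.r.t. every weight.

    The rough-layer gradient routes each branch's contribution to the
    weight set that produced it (ties split 50/50); since the emitted
    output is the branch sum, the routed total for the lower weight set
    is g_O·f'(I_L) and for the upper set g_O·f'(I_U) in every case.
    """
    lam = model.config.lambda_
    scores = state.scores
    # Output layer: dE/dz = (score − T)·λ·s·(1−s)
    delta = (scores - target) * lam * scores * (1.0 - scores)
    grads: list[dict] = [{"W": np.outer(delta, state.output_input),
                          "b": delta}]
    g_next = model.output.W.T @ delta    # gradient w.r.t. last combined O
    for idx in range(len(model.layers) - 1, -1, -1):
        fL, fU = state.f_lower[idx], state.f_upper[idx]
        delta_L = g_next * lam * fL * (1.0 - fL)
        delta_U = g_next * lam * fU * (1.0 - fU)
        x = state.layer_inputs[idx]
        grads.append({
            "W_lower": np.outer(delta_L, x), "b_lower": delta_L,
            "W_upper": np.outer(delta_U, x), "b_upper": delta_U,
        })
        layer = model.layers[idx]
        g_next = layer.W_lower.T @ delta_L + layer.W_upper.T @ delta_U
    grads.reverse()
    return grads


def backprop_step(model: RNNModel, features: np.ndarray,
                  target: np.ndarray, gamma: float | None = None) -> float:
    """One stochastic gradient step on a single sample, in place.

    Returns the squared error Σ(T − score)² *before* the update.
    """
    if gamma is None:
        gamma = model.config.gamma
    target = np.asarray(target, dtype=float)
    scores, state = network_forward(features, model)
    sq_error = float(np.sum((target - scores) ** 2))
    grads = _gradients(model, state, target)
    out_grad = grads[-1]
    model.output.W -= gamma * out_grad["W"]
    if model.config.use_bias:
        model.output.b -= gamma * out_grad["b"]
    for layer, g in zip(model.layers, grads[:-1]):
        layer.W_lower -= gamma * g["W_lower"]
        layer.W_upper -= gamma * g["W_upper"]
        if model.config.use_bias:
            layer.b_lower -= gamma * g["b_lower"]
            layer.b_upper -= gamma * g["b_upper"]
    return sq_error


def _init_model(n_inputs: int, hidden_sizes: tuple[int, ...], n_outputs: int,
                config: RNNConfig) -> RNNModel:
    rng = np.random.default_rng(config.seed)
    s = config.init_scale

    def uniform(shape):
        return rng.uniform(-s, s, size=shape)

    layers = []
    width = n_inputs
    for h in hidden_sizes:
        bias = uniform(h) if config.use_bias else np.zeros(h)
        bias2 = uniform(h) if config.use_bias else np.zeros(h)
        layers.append(RoughLayer(uniform((h, width)), uniform((h, width)),
                                 bias, bias2))
        width = h
    out_bias = uniform(n_outputs) if config.use_bias else np.zeros(n_outputs)
    output = OutputLayer(uniform((n_outputs, width)), out_bias)
    return RNNModel(n_inputs=n_inputs, layers=layers, output=output,
                    config=config)


def train_rnn(features: np.ndarray, targets: np.ndarray,
              config: RNNConfig) -> RNNModel:
    """Train a rough network by per-sample backpropagation.

    Parameters
    ----------
    features : (n, n_inputs) array
        Normalized attribute rows in [0, 1].
    targets : (n, n_outputs) array
        Codeword targets aligned with the rows.
    config : RNNConfig
        Hyperparameters; when ``hidden_sizes`` is None the single hidden
        layer is sized by the Baum–Haussler rule from n, Te and the widths.

    The per-epoch mean of Σ(T − score)² over samples is appended to the
    model's ``loss_trace``; training stops when it reaches
    ``config.target_mse`` or after ``config.max_epochs`` epochs.
    Deterministic for a given (data, config, seed).
    """
    features = np.asarray(features, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if features.ndim != 2 or features.shape[0] == 0:
        raise ConfigurationError("training set must be a nonempty matrix")
    if targets.shape[0] != features.shape[0]:
        raise ConfigurationError("targets must align with training rows")
    n, n_inputs = features.shape
    n_outputs = targets.shape[1]
    hidden = config.hidden_sizes or (
        baum_haussler_hidden_count(n, config.tol_error, n_inputs, n_outputs),)
    model = _init_model(n_inputs, tuple(hidden), n_outputs, config)

    shuffler = np.random.default_rng(config.seed + 1)
    order = np.arange(n)
    for _ in range(config.max_epochs):
        shuffler.shuffle(order)
        total = 0.0
        for i in order:
            total += backprop_step(model, features[i], targets[i],
                                   config.gamma)
        mse = total / n
        model.loss_trace.append(mse)
        if mse <= config.target_mse:
            break
    return model
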
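"""Feed-forward neural network with sum-squared-error training.

A small fully-connected network: each neuron computes
``z_m = act(sum_n q_mn x_n - c_m0)`` (weights ``q``, per-neuron
threshold ``c``), and training minimises

    W = 1/(2Z) * sum_z sum_g (y_g^z - d_g^z)^2

over the Z training patterns and G output units, stopping at a target
error (default 0.01).  Two learning rules are provided: plain batch
gradient descent and Levenberg-Marquardt (the default for networks
small enough to form the residual Jacobian).  The step activation is
inference-only (non-differentiable).

Class targets are one-hot vectors scaled away from the activation's
saturation limits (0.9/-0.9 for tanh, 0.9/0.1 for sigmoid).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FFNNConfig",
    "FFNNModel",
    "activation",
    "forward",
    "sse_objective",
    "train",
    "predict",
    "one_hot_targets",
    "FFNNClassifier",
]

_LM_PARAM_LIMIT = 5000  # switch to gradient descent above this size


def activation(name: str, eta):
    """Apply one of the supported activations elementwise."""
    eta = np.asarray(eta, dtype=float)
    if name == "linear":
        return eta
    if name == "sigmoid":
        return 1.0 / (1.0 + np.exp(-eta))
    if name == "tanh":
        return np.tanh(eta)
    if name == "step":
        return np.where(eta < 0.0, -1.0, 1.0)
    raise ValueError(f"unknown activation {name!r}")


def _activation_derivative(name: str, out: np.ndarray) -> np.ndarray:
    # derivative expressed through the activation output
    if name == "linear":
        return np.ones_like(out)
    if name == "sigmoid":
        return out * (1.0 - out)
    if name == "tanh":
        return 1.0 - out**2
    raise ValueError(f"activation {name!r} is not differentiable")


@dataclass
class FFNNConfig:
    """Architecture and training settings.

    ``layer_sizes`` lists (input, hidden..., output) unit counts; when
    omitted it is derived as input + (n_layers - 2) hidden layers of
    ``hidden_neurons`` + output.  The conventional 3-layer reading is
    one hidden layer of 10 tanh neurons.
    """

    layer_sizes: tuple | None = None
    n_layers: int = 3
    hidden_neurons: int = 10
    activation: str = "tanh"
    target_sse: float = 0.01
    max_epochs: int = 200
    learning_rule: str = "auto"  # auto | gradient | levenberg_marquardt
    learning_rate: float = 0.1
    seed: int = 0

    def resolved_sizes(self, n_inputs: int, n_outputs: int) -> tuple:
        if self.layer_sizes is not None:
            return tuple(self.layer_sizes)
        hidden = [self.hidden_neurons] * max(self.n_layers - 2, 1)
        return (n_inputs, *hidden, n_outputs)


@dataclass
class FFNNModel:
    weights: list  # per layer, shape (m, n_prev)
    thresholds: list  # per layer, shape (m,)
    config: FFNNConfig
    final_sse: float | None = None

    @property
    def layer_sizes(self) -> tuple:
        return (self.weights[0].shape[1], *(w.shape[0] for w in self.weights))

    @property
    def n_parameters(self) -> int:
        return sum(w.size + c.size for w, c in zip(self.weights, self.thresholds))

    def to_json(self) -> str:
        return json.dumps(
            {
                "layer_sizes": list(self.layer_sizes),
                "activation": self.config.activation,
                "seed": self.config.seed,
                "final_sse": self.final_sse,
                "weights": [w.tolist() for w in self.weights],
                "thresholds": [c.tolist() for c in self.thresholds],
            }
        )


def _init_model(config: FFNNConfig, n_inputs: int, n_outputs: int) -> FFNNModel:
    rng = np.random.default_rng(config.seed)
    sizes = config.resolved_sizes(n_inputs, n_outputs)
    weights, thresholds = [], []
    for n_prev, m in zip(sizes[:-1], sizes[1:]):
        weights.append(rng.uniform(-0.5, 0.5, size=(m, n_prev)))
        thresholds.append(rng.uniform(-0.5, 0.5, size=m))
    return FFNNModel(weights=weights, thresholds=thresholds, config=config)


def _forward_all(model: FFNNModel, X: np.ndarray) -> list:
    """Layer outputs for a batch; entry 0 is the input itself."""
    outs = [X]
    for w, c in zip(model.weights, model.thresholds):
        outs.append(activation(model.config.activation, outs[-1] @ w.T - c))
    return outs


def forward(model: FFNNModel, x: np.ndarray) -> np.ndarray:
    """Output vector for one input pattern (or batch)."""
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("forward requires finite inputs")
    single = x.ndim == 1
    out = _forward_all(model, x[None, :] if single else x)[-1]
    return out[0] if single else out


def sse_objective(model: FFNNModel, inputs: np.ndarray, targets: np.ndarray) -> float:
    """W = 1/(2Z) * sum of squared output errors."""
    inputs = np.asarray(inputs, dtype=float)
    targets = np.asarray(targets, dtype=float)
    y = forward(model, inputs)
    if y.shape != targets.shape:
        raise ValueError(f"target shape {targets.shape} does not match outputs {y.shape}")
    return float(np.sum((y - targets) ** 2) / (2 * inputs.shape[0]))


# ----------------------------------------------------------- parameters

def _flatten(model: FFNNModel) -> np.ndarray:
    return np.concatenate(
        [w.ravel() for w in model.weights] + [c.ravel() for c in model.thresholds]
    )


def _unflatten(model: FFNNModel, theta: np.ndarray) -> None:
    pos = 0
    for w in model.weights:
        w[...] = theta[pos : pos + w.size].reshape(w.shape)
        pos += w.size
    for c in model.thresholds:
        c[...] = theta[pos : pos + c.size]
        pos += c.size


def gradient(model: FFNNModel, inputs: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Analytic gradient of the SSE objective in flattened-parameter order."""
    Z = inputs.shape[0]
    outs = _forward_all(model, np.asarray(inputs, dtype=float))
    act = model.config.activation
    delta = (outs[-1] - targets) * _activation_derivative(act, outs[-1]) / Z
    grads_w, grads_c = [], []
    for layer in range(len(model.weights) - 1, -1, -1):
        grads_w.append(delta.T @ outs[layer])
        grads_c.append(-delta.sum(axis=0))
        if layer > 0:
            delta = (delta @ model.weights[layer]) * _activation_derivative(
                act, outs[layer]
            )
    grads_w.reverse()
    grads_c.reverse()
    return np.concatenate([g.ravel() for g in grads_w] + [g.ravel() for g in grads_c])


def _jacobian(model: FFNNModel, inputs: np.ndarray) -> np.ndarray:
    """Jacobian of the stacked per-pattern output vector w.r.t. parameters."""
    Z = inputs.shape[0]
    G = model.weights[-1].shape[0]
    outs = _forward_all(model, np.asarray(inputs, dtype=float))
    act = model.config.activation
    P = model.n_parameters
    J = np.empty((Z * G, P))
    for g in range(G):
        delta = np.zeros((Z, G))
        delta[:, g] = _activation_derivative(act, outs[-1][:, g])
        rows_w, rows_c = [], []
        d = delta
        for layer in range(len(model.weights) - 1, -1, -1):
            # per-sample gradient of output g w.r.t. layer weights/thresholds
            rows_w.append(np.einsum("zm,zn->zmn", d, outs[layer]).reshape(Z, -1))
            rows_c.append(-d)
            if layer > 0:
                d = (d @ model.weights[layer]) * _activation_derivative(act, outs[layer])
        rows_w.reverse()
        rows_c.reverse()
        J[g::G] = np.hstack(rows_w + rows_c)
    return J


# -------------------------------------------------------------- training

def train(config: FFNNConfig, inputs: np.ndarray, targets: np.ndarray) -> FFNNModel:
    """Fit a network to (inputs, one-hot targets).

    Stops when W <= ``target_sse`` or after ``max_epochs``.  The
    ``auto`` rule uses Levenberg-Marquardt while the parameter count
    stays small and falls back to gradient descent beyond that.
    Divergence (non-finite W) raises with the epoch index.
    """
    inputs = np.asarray(inputs, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if config.activation == "step":
        raise ValueError("the step activation is inference-only")
    model = _init_model(config, inputs.shape[1], targets.shape[1])
    model.final_sse = sse_objective(model, inputs, targets)
    if config.max_epochs == 0:
        return model

    rule = config.learning_rule
    if rule == "auto":
        rule = "levenberg_marquardt" if model.n_parameters <= _LM_PARAM_LIMIT else "gradient"

    if rule == "gradient":
        for epoch in range(config.max_epochs):
            if model.final_sse <= config.target_sse:
                break
            theta = _flatten(model) - config.learning_rate * gradient(
                model, inputs, targets
            )
            _unflatten(model, theta)
            model.final_sse = sse_objective(model, inputs, targets)
            if not np.isfinite(model.final_sse):
                raise FloatingPointError(f"training diverged at epoch {epoch}")
        return model

    if rule != "levenberg_marquardt":
        raise ValueError(f"unknown learning rule {config.learning_rule!r}")

    Z = inputs.shape[0]
    mu = 1e-2
    current = model.final_sse
    for epoch in range(config.max_epochs):
        if current <= config.target_sse:
            break
        theta = _flatten(model)
        residuals = (forward(model, inputs) - targets).ravel() / np.sqrt(Z)
        J = _jacobian(model, inputs) / np.sqrt(Z)
        JtJ = J.T @ J
        Jtr = J.T @ residuals
        accepted = False
        for _ in range(15):  # inflate damping until a step is accepted
            try:
                step = np.linalg.solve(JtJ + mu * np.eye(JtJ.shape[0]), -Jtr)
            except np.linalg.LinAlgError:
                mu *= 10.0
                continue
            _unflatten(model, theta + step)
            candidate = sse_objective(model, inputs, targets)
            if not np.isfinite(candidate):
                raise FloatingPointError(f"training diverged at epoch {epoch}")
            if candidate < current:
                current = candidate
                mu = max(mu / 10.0, 1e-12)
                accepted = True
                break
            mu *= 10.0
        if not accepted:
            _unflatten(model, theta)  # restore; no downhill step found
            break
    model.final_sse = current
    return model


def predict(model: FFNNModel, inputs: np.ndarray) -> np.ndarray:
    """Class labels 1..K via argmax over outputs (ties -> lower class)."""
    y = forward(model, np.atleast_2d(np.asarray(inputs, dtype=float)))
    return np.argmax(y, axis=1) + 1


def one_hot_targets(labels: np.ndarray, n_classes: int, activation_name: str = "tanh") -> np.ndarray:
    """One-hot encode 1..K labels, scaled away from saturation."""
    labels = np.asarray(labels, dtype=int)
    hi, lo = {"tanh": (0.9, -0.9), "sigmoid": (0.9, 0.1)}.get(activation_name, (1.0, 0.0))
    T = np.full((labels.size, n_classes), lo)
    T[np.arange(labels.size), labels - 1] = hi
    return T


class FFNNClassifier:
    """Sklearn-style wrapper used as the wrapper-selection classifier."""

    def __init__(self, config: FFNNConfig | None = None, n_classes: int = 4):
        self.config = config or FFNNConfig()
        self.n_classes = n_classes
        self.model: FFNNModel | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "FFNNClassifier":
        targets = one_hot_targets(y, self.n_classes, self.config.activation)
        self.model = train(self.config, X, targets)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.model is None:
            raise RuntimeError("classifier is not fitted")
        return predict(self.model, X)
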
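"""From-scratch feed-forward sigmoid network for Cancer/Normal scoring.

Every neuron applies the logistic sigmoid S(x) = 1 / (1 + e^(-x)) to its
weighted input sum, chosen for its bounded output and cheap gradient
S'(x) = S(x) (1 - S(x)).  The network is trained by full-batch gradient
descent on mean-squared error (binary cross-entropy available by flag)
with a slowly decaying learning rate lr0 / (1 + k * epoch).  Inputs are
the binarized panel features; the single output neuron scores a sample's
probability of being cancer.

Three preset hidden-layer architectures are provided: A = (7, 4),
B = (10, 10), C = (5, 4, 3).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import CANCER, NORMAL, BinaryMatrix, PipelineError

ARCHITECTURE_PRESETS: dict[str, tuple[int, ...]] = {
    "A": (7, 4),
    "B": (10, 10),
    "C": (5, 4, 3),
}

#: Seeded weight initialization range; the training narrative leaves
#: initialization open, so small symmetric uniform weights are used.
INIT_SCALE = 0.5


def sigmoid(x):
    """Logistic sigmoid, numerically stable over the full float range."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class MLPArchitecture:
    """Hidden layer sizes; input width is the panel size, output is 1."""

    hidden_layer_sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        self.hidden_layer_sizes = tuple(int(s) for s in self.hidden_layer_sizes)
        if any(s < 1 for s in self.hidden_layer_sizes):
            raise PipelineError(
                f"all layer sizes must be >= 1, got {self.hidden_layer_sizes}"
            )

    @classmethod
    def preset(cls, name: str) -> "MLPArchitecture":
        try:
            return cls(ARCHITECTURE_PRESETS[name.upper()])
        except KeyError:
            raise PipelineError(
                f"unknown architecture preset {name!r}; choose from "
                f"{sorted(ARCHITECTURE_PRESETS)}"
            ) from None

    def layer_sizes(self, n_inputs: int) -> list[int]:
        return [n_inputs, *self.hidden_layer_sizes, 1]


@dataclass
class TrainConfig:
    """Gradient-descent schedule: lr(epoch) = lr0 / (1 + decay * epoch)."""

    initial_learning_rate: float = 2.0
    decay_constant: float = 0.01
    max_epochs: int = 20000
    tolerance: float = 1e-9
    loss: str = "mse"  # or "cross_entropy"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_learning_rate <= 0:
            raise PipelineError("initial_learning_rate must be > 0")
        if self.decay_constant < 0:
            raise PipelineError("decay_constant must be >= 0")
        if self.loss not in ("mse", "cross_entropy"):
            raise PipelineError(f"unknown loss {self.loss!r}")

    def learning_rate(self, epoch: int) -> float:
        return self.initial_learning_rate / (1.0 + self.decay_constant * epoch)


@dataclass
class MLPModel:
    """Weights and biases of a sigmoid network, plus its training panel order."""

    architecture: MLPArchitecture
    weights: list[np.ndarray]  # weights[l]: (n_in, n_out)
    biases: list[np.ndarray]  # biases[l]: (n_out,)
    feature_names: list[str] = field(default_factory=list)
    seed: int = 0

    @property
    def n_inputs(self) -> int:
        return self.weights[0].shape[0]

    def forward(self, X: np.ndarray) -> list[np.ndarray]:
        """Activations per layer (input first, output last)."""
        activations = [np.asarray(X, dtype=float)]
        for W, b in zip(self.weights, self.biases):
            activations.append(sigmoid(activations[-1] @ W + b))
        return activations

    def to_json(self, path) -> None:
        payload = {
            "hidden_layer_sizes": list(self.architecture.hidden_layer_sizes),
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "feature_names": self.feature_names,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "MLPModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            architecture=MLPArchitecture(tuple(payload["hidden_layer_sizes"])),
            weights=[np.array(w, dtype=float) for w in payload["weights"]],
            biases=[np.array(b, dtype=float) for b in payload["biases"]],
            feature_names=list(payload["feature_names"]),
            seed=int(payload["seed"]),
        )


def init_network(
    arch: MLPArchitecture,
    n_inputs: int,
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> MLPModel:
    """Seeded uniform(-0.5, 0.5) weights and biases for the given shape."""
    if n_inputs < 1:
        raise PipelineError("n_inputs must be >= 1")
    rng = np.random.default_rng(seed)
    sizes = arch.layer_sizes(n_inputs)
    weights = [
        rng.uniform(-INIT_SCALE, INIT_SCALE, size=(sizes[i], sizes[i + 1]))
        for i in range(len(sizes) - 1)
    ]
    biases = [
        rng.uniform(-INIT_SCALE, INIT_SCALE, size=sizes[i + 1])
        for i in range(len(sizes) - 1)
    ]
    return MLPModel(
        architecture=arch,
        weights=weights,
        biases=biases,
        feature_names=list(feature_names or []),
        seed=seed,
    )


def _loss_and_delta(y_hat: np.ndarray, y: np.ndarray, kind: str):
    """Loss value and output-layer delta (dL/d pre-activation)."""
    if kind == "mse":
        loss = float(np.mean((y_hat - y) ** 2))
        delta = 2.0 * (y_hat - y) * y_hat * (1.0 - y_hat) / len(y)
    else:  # cross_entropy; delta simplifies against the sigmoid derivative
        eps = 1e-12
        clipped = np.clip(y_hat, eps, 1 - eps)
        loss = float(-np.mean(y * np.log(clipped) + (1 - y) * np.log(1 - clipped)))
        delta = (y_hat - y) / len(y)
    return loss, delta


def backprop_gradients(model: MLPModel, X: np.ndarray, y: np.ndarray, loss: str = "mse"):
    """Analytic gradients of the loss w.r.t. every weight and bias."""
    activations = model.forward(X)
    y_hat = activations[-1][:, 0]
    _, delta_out = _loss_and_delta(y_hat, y, loss)
    delta = delta_out[:, None]
    grads_w, grads_b = [], []
    for layer in range(len(model.weights) - 1, -1, -1):
        a_prev = activations[layer]
        grads_w.append(a_prev.T @ delta)
        grads_b.append(delta.sum(axis=0))
        if layer > 0:
            a = activations[layer]
            delta = (delta @ model.weights[layer].T) * a * (1.0 - a)
    return grads_w[::-1], grads_b[::-1]


def train(
    model: MLPModel,
    features: BinaryMatrix,
    config: TrainConfig | None = None,
) -> tuple[MLPModel, list[float]]:
    """Full-batch gradient descent; returns the model and its loss history.

    ``features`` must be the binarized matrix restricted to the panel
    sites (cancer encoded 1, normal 0).  The quarantined test partition is
    refused.  Training stops at ``max_epochs`` or when the epoch-to-epoch
    loss improvement drops below ``tolerance``.
    """
    config = config or TrainConfig()
    if features.is_test:
        raise PipelineError("refusing to train on the quarantined test partition")
    X = features.values.to_numpy(dtype=float)
    y = features.label_vector().astype(float)
    if X.shape[1] != model.n_inputs:
        raise PipelineError(
            f"feature count {X.shape[1]} does not match model input size "
            f"{model.n_inputs}"
        )
    if model.feature_names and model.feature_names != features.site_ids:
        missing = [s for s in model.feature_names if s not in features.site_ids]
        raise PipelineError(
            f"feature columns do not match training panel order; missing {missing}"
        )
    if not model.feature_names:
        model.feature_names = features.site_ids

    history: list[float] = []
    prev_loss = np.inf
    for epoch in range(config.max_epochs):
        y_hat = model.forward(X)[-1][:, 0]
        loss, _ = _loss_and_delta(y_hat, y, config.loss)
        if not np.isfinite(loss):
            raise PipelineError(f"non-finite loss at epoch {epoch}")
        history.append(loss)
        if prev_loss - loss < config.tolerance and epoch > 0:
            break
        prev_loss = loss
        grads_w, grads_b = backprop_gradients(model, X, y, loss=config.loss)
        lr = config.learning_rate(epoch)
        for W, b, gw, gb in zip(model.weights, model.biases, grads_w, grads_b):
            W -= lr * gw
            b -= lr * gb
    return model, history


def predict_scores(model: MLPModel, features: BinaryMatrix | pd.DataFrame) -> pd.Series:
    """Cancer score in (0, 1) per sample (forward pass only)."""
    values = features.values if isinstance(features, BinaryMatrix) else features
    if model.feature_names:
        missing = [s for s in model.feature_names if s not in values.columns]
        if missing:
            raise PipelineError(f"features missing panel sites: {missing}")
        values = values.loc[:, model.feature_names]
    elif values.shape[1] != model.n_inputs:
        raise PipelineError(
            f"feature count {values.shape[1]} != model input size {model.n_inputs}"
        )
    if len(values) == 0:
        return pd.Series(dtype=float, name="score")
    scores = model.forward(values.to_numpy(dtype=float))[-1][:, 0]
    return pd.Series(scores, index=values.index, name="score")


def classify(scores: pd.Series, threshold: float = 0.5) -> pd.Series:
    """Hard labels from scores: Cancer iff score >= threshold."""
    return pd.Series(
        np.where(np.asarray(scores, dtype=float) >= threshold, CANCER, NORMAL),
        index=scores.index if hasattr(scores, "index") else None,
        name="label",
    )
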
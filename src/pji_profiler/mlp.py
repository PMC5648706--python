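"""Minimal feed-forward neural network trained by backpropagation.

Architecture mirrors the diagnostic classifier: input -> 13 -> 9 -> 1 with a
logistic activation at every layer, a single probability output, squared-error
loss against 0/1 class targets, and full-batch gradient descent with a fixed
learning rate. Everything is deterministic given the config seed.

Because relative expression spans several orders of magnitude and logistic
units saturate, features are log-transformed (``ln(x + eps)`` with a per-gene
``eps`` tied to the smallest positive training value) and z-scored before
training; the scaling parameters are estimated on the training data only and
stored with the network so prediction applies exactly the same transform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np


class TrainingError(ValueError):
    """Inputs unusable for training (single class, NaN, too few patients)."""


class PredictionError(ValueError):
    """Prediction input does not match the trained network's features."""


@dataclass(frozen=True)
class NetworkConfig:
    """Training hyperparameters.

    hidden_sizes: neurons per hidden layer; (13, 9) is the diagnostic
    architecture. error_threshold is the misclassification fraction below
    which a network counts as acceptable in wrapper selection (default 20%).
    tol stops training early when the epoch-to-epoch MSE change falls below
    it.
    """

    hidden_sizes: tuple[int, ...] = (13, 9)
    learning_rate: float = 0.05
    max_epochs: int = 10_000
    error_threshold: float = 0.20
    tol: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.error_threshold < 1:
            raise ValueError("error_threshold must lie in (0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden layer sizes must be >= 1")


@dataclass(frozen=True)
class FeatureScaling:
    """Per-feature ``z = (ln(x + eps) - mean) / sd`` transform parameters."""

    eps: np.ndarray
    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "FeatureScaling":
        eps = np.empty(X.shape[1])
        for j in range(X.shape[1]):
            pos = X[:, j][X[:, j] > 0]
            # no positive values at all: fall back to a tiny absolute floor
            eps[j] = pos.min() * 1e-3 if pos.size else 1e-9
        logx = np.log(X + eps)
        mean = logx.mean(axis=0)
        sd = logx.std(axis=0)
        sd[sd == 0] = 1.0  # constant feature: leave centered at 0
        return cls(eps=eps, mean=mean, sd=sd)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.log(X + self.eps) - self.mean) / self.sd


def _logistic(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _init_params(n_in: int, hidden: Sequence[int], rng: np.random.Generator):
    sizes = [n_in, *hidden, 1]
    weights = [rng.uniform(-0.5, 0.5, (sizes[i], sizes[i + 1])) for i in range(len(sizes) - 1)]
    biases = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
    return weights, biases


def _forward(weights, biases, X: np.ndarray) -> list[np.ndarray]:
    """Activations per layer (input excluded); logistic at every layer."""
    acts = []
    a = X
    for W, b in zip(weights, biases):
        a = _logistic(a @ W + b)
        acts.append(a)
    return acts


def _loss_and_gradients(weights, biases, X: np.ndarray, y: np.ndarray):
    """MSE of the scalar output against y plus analytic gradients.

    Backpropagation through logistic layers; returns (mse, dWs, dbs).
    """
    n = len(y)
    acts = _forward(weights, biases, X)
    out = acts[-1][:, 0]
    err = out - y
    mse = float(np.mean(err * err))
    delta = (2.0 / n) * err[:, None] * acts[-1] * (1.0 - acts[-1])
    dWs = [None] * len(weights)
    dbs = [None] * len(weights)
    for layer in range(len(weights) - 1, -1, -1):
        a_prev = X if layer == 0 else acts[layer - 1]
        dWs[layer] = a_prev.T @ delta
        dbs[layer] = delta.sum(axis=0)
        if layer:
            delta = (delta @ weights[layer].T) * acts[layer - 1] * (1.0 - acts[layer - 1])
    return mse, dWs, dbs


@dataclass
class TrainedNetwork:
    """Weights + scaling of one trained classifier network."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    config: NetworkConfig
    scaling: FeatureScaling
    feature_names: tuple[str, ...]
    training_mse: float
    training_error: float

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "scaling": {
                "eps": self.scaling.eps.tolist(),
                "mean": self.scaling.mean.tolist(),
                "sd": self.scaling.sd.tolist(),
            },
            "config": {
                "hidden_sizes": list(self.config.hidden_sizes),
                "learning_rate": self.config.learning_rate,
                "max_epochs": self.config.max_epochs,
                "error_threshold": self.config.error_threshold,
                "tol": self.config.tol,
                "seed": self.config.seed,
            },
            "training_mse": self.training_mse,
            "training_error": self.training_error,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainedNetwork":
        cfg = dict(d["config"])
        cfg["hidden_sizes"] = tuple(cfg["hidden_sizes"])
        return cls(
            weights=[np.asarray(w) for w in d["weights"]],
            biases=[np.asarray(b) for b in d["biases"]],
            config=NetworkConfig(**cfg),
            scaling=FeatureScaling(
                eps=np.asarray(d["scaling"]["eps"]),
                mean=np.asarray(d["scaling"]["mean"]),
                sd=np.asarray(d["scaling"]["sd"]),
            ),
            feature_names=tuple(d["feature_names"]),
            training_mse=float(d["training_mse"]),
            training_error=float(d["training_error"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedNetwork":
        return cls.from_dict(json.loads(Path(path).read_text()))


def train_network(
    X: np.ndarray,
    y: np.ndarray,
    config: NetworkConfig = NetworkConfig(),
    feature_names: Sequence[str] | None = None,
) -> TrainedNetwork:
    """Train one network on raw (unscaled) expression values.

    X is patient x gene (no missing values); y is 0/1 (1 = infection).
    Scaling is fit on X here — callers doing cross-validation therefore get
    leakage-free scaling for free by passing only the training fold.
    Identical inputs and config (including seed) give identical weights.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise TrainingError(f"shape mismatch: X {X.shape}, y {y.shape}")
    if np.isnan(X).any():
        raise TrainingError("X contains missing values; drop incomplete cases first")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise TrainingError("y must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise TrainingError("training labels contain a single class")
    if min((y == 1).sum(), (y == 0).sum()) < 2:
        raise TrainingError("need at least 2 patients per class")

    names = tuple(feature_names) if feature_names is not None else tuple(
        f"x{j}" for j in range(X.shape[1])
    )
    scaling = FeatureScaling.fit(X)
    Xs = scaling.transform(X)
    rng = np.random.default_rng(config.seed)
    weights, biases = _init_params(X.shape[1], config.hidden_sizes, rng)

    lr = config.learning_rate
    prev = np.inf
    mse = np.inf
    for _ in range(config.max_epochs):
        mse, dWs, dbs = _loss_and_gradients(weights, biases, Xs, y)
        if abs(prev - mse) < config.tol:
            break
        prev = mse
        for W, b, dW, db in zip(weights, biases, dWs, dbs):
            W -= lr * dW
            b -= lr * db

    out = _forward(weights, biases, Xs)[-1][:, 0]
    training_mse = float(np.mean((out - y) ** 2))
    training_error = float(np.mean((out >= 0.5) != (y == 1)))
    return TrainedNetwork(
        weights=weights,
        biases=biases,
        config=config,
        scaling=scaling,
        feature_names=names,
        training_mse=training_mse,
        training_error=training_error,
    )


def predict(net: TrainedNetwork, x: np.ndarray) -> float | np.ndarray:
    """Probability of infection for one sample (1-D) or many (2-D).

    Output is strictly inside (0, 1); a sample is classified as infection
    iff the output is >= 0.5.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    X = x[None, :] if single else x
    if X.shape[1] != len(net.feature_names):
        raise PredictionError(
            f"expected {len(net.feature_names)} features "
            f"({', '.join(net.feature_names)}), got {X.shape[1]}"
        )
    if np.isnan(X).any():
        raise PredictionError("input contains missing values")
    out = _forward(net.weights, net.biases, net.scaling.transform(X))[-1][:, 0]
    return float(out[0]) if single else out


def classification_error(net: TrainedNetwork, X: np.ndarray, y: np.ndarray) -> float:
    """Fraction of patients whose thresholded prediction differs from y."""
    y = np.asarray(y).ravel()
    if len(y) == 0:
        raise TrainingError("empty evaluation set")
    out = np.atleast_1d(predict(net, np.asarray(X, dtype=float)))
    return float(np.mean((out >= 0.5) != (y == 1)))
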
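"""Feedforward network trained by backpropagation with MSE loss.

This is the window classifier of the pipeline, written from first
principles because the training rule itself (sigmoid layers, mean-squared
error against one-hot targets, plain gradient descent) is part of the
method being packaged. The forward pass is

    z^(l) = w^(l) a^(l-1) + b^(l),    a^(l) = g(z^(l)),

the loss over a batch of n samples is E = (1/2n) * sum_i ||y_i - yhat_i||^2
(squared errors summed across the output units before the 1/2n factor),
and backpropagation computes

    delta^(L) = (a^(L) - y) * g'(z^(L)),
    delta^(l) = (w^(l+1))^T delta^(l+1) * g'(z^(l)),
    dE/dw^(l) = delta^(l) (a^(l-1))^T,    dE/db^(l) = delta^(l),

followed by the gradient-descent update  w <- w - alpha * dE/dw. Gradients
returned by :func:`backward` are gradients of :func:`mse_loss` on the batch
(so they carry the 1/n averaging; for a single sample they coincide with
the per-sample formulas above) and are verified against central finite
differences in the test suite.

Internally activations are stored row-major (one sample per row), so a
batch forward pass is two matrix products per layer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np

from .preprocess import FeatureDataset

__all__ = [
    "NetworkParams",
    "TrainConfig",
    "TrainTrace",
    "ForwardPass",
    "init_network",
    "forward",
    "mse_loss",
    "backward",
    "sgd_update",
    "train",
    "predict",
    "params_to_dict",
    "params_from_dict",
]

FORMAT_VERSION = 1


def _sigmoid(z: np.ndarray) -> np.ndarray:
    # Clipped for robustness against extreme pre-activations.
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


def _sigmoid_prime(z: np.ndarray) -> np.ndarray:
    s = _sigmoid(z)
    return s * (1.0 - s)


def _tanh_prime(z: np.ndarray) -> np.ndarray:
    return 1.0 - np.tanh(z) ** 2


ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    "sigmoid": (_sigmoid, _sigmoid_prime),
    "tanh": (np.tanh, _tanh_prime),
}


@dataclass
class NetworkParams:
    """Layered weights/biases plus the activation choice.

    ``weights[l]`` has shape ``(n_{l+1}, n_l)`` and ``biases[l]`` shape
    ``(n_{l+1},)`` for ``layer_sizes = (n_0, ..., n_L)``. The hidden
    activation is configurable (sigmoid default, tanh available); the
    output layer is always sigmoid so outputs live in (0, 1) and match the
    one-hot targets of the MSE loss.
    """

    layer_sizes: tuple[int, ...]
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    activation: str = "sigmoid"

    def __post_init__(self) -> None:
        self.layer_sizes = tuple(int(s) for s in self.layer_sizes)
        if len(self.layer_sizes) < 2 or any(s < 1 for s in self.layer_sizes):
            raise ValueError("need >= 2 layers with all sizes >= 1")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if len(self.weights) != self.n_layers or len(self.biases) != self.n_layers:
            raise ValueError("one weight matrix and bias vector per non-input layer")
        self.weights = [np.asarray(w, dtype=float) for w in self.weights]
        self.biases = [np.asarray(b, dtype=float) for b in self.biases]
        for l, (w, b) in enumerate(zip(self.weights, self.biases)):
            want = (self.layer_sizes[l + 1], self.layer_sizes[l])
            if w.shape != want:
                raise ValueError(f"weights[{l}] must have shape {want}, got {w.shape}")
            if b.shape != (self.layer_sizes[l + 1],):
                raise ValueError(f"biases[{l}] shape mismatch: {b.shape}")
            if not (np.all(np.isfinite(w)) and np.all(np.isfinite(b))):
                raise ValueError(f"layer {l} parameters contain non-finite values")

    @property
    def n_layers(self) -> int:
        """Number of weight layers (i.e. non-input layers)."""
        return len(self.layer_sizes) - 1

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            self.layer_sizes,
            [w.copy() for w in self.weights],
            [b.copy() for b in self.biases],
            self.activation,
        )


@dataclass(frozen=True)
class TrainConfig:
    """Gradient-descent hyperparameters.

    ``batch_size=None`` means full-batch descent (the literal reading of
    the update rule); a positive integer selects shuffled mini-batches.
    ``early_stop_patience`` stops when the epoch loss has not improved for
    that many epochs.
    """

    learning_rate: float = 0.1
    epochs: int = 200
    batch_size: int | None = None
    seed: int = 0
    init_scale: float = 0.5
    hidden_sizes: tuple[int, ...] = (32,)
    activation: str = "sigmoid"
    early_stop_patience: int | None = None

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size is not None and self.batch_size < 1:
            raise ValueError("batch_size must be >= 1 when given")
        if self.init_scale < 0:
            raise ValueError("init_scale must be >= 0")


@dataclass
class TrainTrace:
    """Per-epoch loss curve plus the final parameters."""

    losses: np.ndarray
    params: NetworkParams

    def __post_init__(self) -> None:
        self.losses = np.asarray(self.losses, dtype=float)
        if self.losses.size and not (
            np.all(np.isfinite(self.losses)) and np.all(self.losses >= 0)
        ):
            raise ValueError("losses must be finite and non-negative")


@dataclass
class ForwardPass:
    """Cached per-layer pre-activations and activations from one forward pass."""

    zs: list[np.ndarray]  # z^(1) ... z^(L)
    activations: list[np.ndarray]  # a^(0) ... a^(L)

    @property
    def output(self) -> np.ndarray:
        return self.activations[-1]


def init_network(
    layer_sizes,
    seed: int = 0,
    init_scale: float = 0.5,
    activation: str = "sigmoid",
) -> NetworkParams:
    """Random network: weights uniform on ±init_scale/sqrt(fan_in), zero biases."""
    sizes = tuple(int(s) for s in layer_sizes)
    if len(sizes) < 2:
        raise ValueError("need at least an input and an output layer")
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for n_in, n_out in zip(sizes[:-1], sizes[1:]):
        bound = init_scale / np.sqrt(n_in)
        weights.append(rng.uniform(-bound, bound, size=(n_out, n_in)))
        biases.append(np.zeros(n_out))
    return NetworkParams(sizes, weights, biases, activation)


def forward(params: NetworkParams, x: np.ndarray) -> ForwardPass:
    """Propagate inputs through the network, caching every layer.

    ``x`` may be a single input vector of length ``layer_sizes[0]`` or a
    batch ``(n, layer_sizes[0])``; activations keep the same leading shape.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    a = x[None, :] if single else x
    if a.ndim != 2 or a.shape[1] != params.layer_sizes[0]:
        raise ValueError(
            f"input width {x.shape} does not match layer_sizes[0]="
            f"{params.layer_sizes[0]}"
        )
    if not np.all(np.isfinite(a)):
        raise ValueError("input contains non-finite values")
    g, _ = ACTIVATIONS[params.activation]
    zs, acts = [], [a[0] if single else a]
    for l in range(params.n_layers):
        z = acts[-1] @ params.weights[l].T + params.biases[l]
        is_output = l == params.n_layers - 1
        a_next = _sigmoid(z) if is_output else g(z)
        zs.append(z)
        acts.append(a_next)
    if single:
        zs = [z.reshape(-1) if z.ndim == 2 else z for z in zs]
        acts = [a.reshape(-1) if getattr(a, "ndim", 1) == 2 else a for a in acts]
    return ForwardPass(zs, acts)


def mse_loss(predictions: np.ndarray, targets: np.ndarray) -> float:
    """Half mean squared error: E = (1/2n) * sum over all entries of (y - yhat)^2."""
    yhat = np.atleast_2d(np.asarray(predictions, dtype=float))
    y = np.atleast_2d(np.asarray(targets, dtype=float))
    if yhat.shape != y.shape or yhat.shape[0] < 1:
        raise ValueError(f"shape mismatch: predictions {yhat.shape} vs targets {y.shape}")
    n = yhat.shape[0]
    return float(np.sum((y - yhat) ** 2) / (2.0 * n))


def backward(
    params: NetworkParams, fp: ForwardPass, targets: np.ndarray
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Gradients of :func:`mse_loss` w.r.t. every weight and bias.

    ``fp`` must be the cache produced by :func:`forward` on the same
    parameters. Returns ``(grad_w, grad_b)`` with shapes mirroring
    ``params.weights`` / ``params.biases``. For a batch, gradients are the
    mean of the per-sample gradients, matching the 1/n in the loss.
    """
    if not fp.zs or len(fp.zs) != params.n_layers:
        raise RuntimeError("forward-pass cache is missing or inconsistent")
    y = np.atleast_2d(np.asarray(targets, dtype=float))
    a_out = np.atleast_2d(fp.output)
    if y.shape != a_out.shape:
        raise ValueError(f"targets shape {y.shape} does not match output {a_out.shape}")
    n = y.shape[0]
    _, gprime = ACTIVATIONS[params.activation]
    zs = [np.atleast_2d(z) for z in fp.zs]
    acts = [np.atleast_2d(a) for a in fp.activations]

    delta = (a_out - y) * _sigmoid_prime(zs[-1])  # output layer is sigmoid
    grad_w = [np.empty(0)] * params.n_layers
    grad_b = [np.empty(0)] * params.n_layers
    for l in range(params.n_layers - 1, -1, -1):
        grad_w[l] = delta.T @ acts[l] / n
        grad_b[l] = delta.sum(axis=0) / n
        if l > 0:
            delta = (delta @ params.weights[l]) * gprime(zs[l - 1])
    return grad_w, grad_b


def sgd_update(
    params: NetworkParams,
    gradients: tuple[list[np.ndarray], list[np.ndarray]],
    learning_rate: float,
) -> NetworkParams:
    """One gradient-descent step: every parameter decremented by alpha * grad."""
    if learning_rate <= 0:
        raise ValueError("learning_rate must be > 0")
    grad_w, grad_b = gradients
    for l, (gw, gb) in enumerate(zip(grad_w, grad_b)):
        if not (np.all(np.isfinite(gw)) and np.all(np.isfinite(gb))):
            raise FloatingPointError(f"non-finite gradient at layer {l}")
    new_w = [w - learning_rate * gw for w, gw in zip(params.weights, grad_w)]
    new_b = [b - learning_rate * gb for b, gb in zip(params.biases, grad_b)]
    return NetworkParams(params.layer_sizes, new_w, new_b, params.activation)


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if np.any(labels < 0) or np.any(labels >= n_classes):
        raise ValueError(f"labels must lie in [0, {n_classes})")
    out = np.zeros((labels.shape[0], n_classes))
    out[np.arange(labels.shape[0]), labels] = 1.0
    return out


def train(
    dataset: FeatureDataset | tuple[np.ndarray, np.ndarray],
    config: TrainConfig = TrainConfig(),
    n_classes: int = 4,
) -> TrainTrace:
    """Train a network on (normalized) window features by gradient descent.

    ``dataset`` is either a :class:`~wristhar.preprocess.FeatureDataset` or
    a plain ``(features, labels)`` pair. The architecture is
    ``(n_features, *config.hidden_sizes, n_classes)``. The recorded loss
    for each epoch is evaluated on the full dataset after that epoch's
    updates. Training is deterministic under ``config.seed`` (which drives
    both initialization and mini-batch shuffling).
    """
    if isinstance(dataset, FeatureDataset):
        features, labels = dataset.features, dataset.labels
    else:
        features, labels = dataset
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[0] < 1:
        raise ValueError("training features must be a nonempty 2-D matrix")
    y = one_hot(labels, n_classes)

    sizes = (x.shape[1], *config.hidden_sizes, n_classes)
    rng = np.random.default_rng(config.seed)
    params = init_network(sizes, seed=config.seed, init_scale=config.init_scale,
                          activation=config.activation)
    losses = []
    best, since_best = np.inf, 0
    n = x.shape[0]
    for epoch in range(config.epochs):
        if config.batch_size is None:
            fp = forward(params, x)
            params = sgd_update(params, backward(params, fp, y), config.learning_rate)
        else:
            order = rng.permutation(n)
            for start in range(0, n, config.batch_size):
                idx = order[start : start + config.batch_size]
                fp = forward(params, x[idx])
                grads = backward(params, fp, y[idx])
                params = sgd_update(params, grads, config.learning_rate)
        loss = mse_loss(forward(params, x).output, y)
        if not np.isfinite(loss):
            raise FloatingPointError(
                f"loss became non-finite at epoch {epoch}; try a smaller "
                f"learning rate than {config.learning_rate}"
            )
        losses.append(loss)
        if config.early_stop_patience is not None:
            if loss < best - 1e-12:
                best, since_best = loss, 0
            else:
                since_best += 1
                if since_best >= config.early_stop_patience:
                    break
    return TrainTrace(np.asarray(losses), params)


def predict(
    params: NetworkParams, features: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Hard labels and row-normalized scores for a batch of feature rows.

    The label is the argmax of the output activations (ties go to the
    lowest class index); scores are the activations renormalized to sum to
    1 per row, a pseudo-posterior used by the downstream sequence model.
    """
    x = np.atleast_2d(np.asarray(features, dtype=float))
    if x.shape[1] != params.layer_sizes[0]:
        raise ValueError(
            f"feature width {x.shape[1]} does not match network input "
            f"{params.layer_sizes[0]}"
        )
    out = np.atleast_2d(forward(params, x).output)
    labels = np.argmax(out, axis=1)  # first max -> lowest index on ties
    sums = out.sum(axis=1, keepdims=True)
    scores = np.where(sums > 0, out / np.where(sums > 0, sums, 1.0),
                      1.0 / out.shape[1])
    return labels, scores


def params_to_dict(params: NetworkParams) -> dict:
    return {
        "format_version": FORMAT_VERSION,
        "layer_sizes": list(params.layer_sizes),
        "activation": params.activation,
        "weights": [w.tolist() for w in params.weights],
        "biases": [b.tolist() for b in params.biases],
    }


def params_from_dict(d: dict) -> NetworkParams:
    if d.get("format_version") != FORMAT_VERSION:
        raise ValueError(
            f"unsupported network format version {d.get('format_version')!r}; "
            f"this build reads version {FORMAT_VERSION}"
        )
    return NetworkParams(
        tuple(d["layer_sizes"]),
        [np.asarray(w, dtype=float) for w in d["weights"]],
        [np.asarray(b, dtype=float) for b in d["biases"]],
        d["activation"],
    )


def save_params(params: NetworkParams, path: str | Path) -> None:
    Path(path).write_text(json.dumps(params_to_dict(params)))


def load_params(path: str | Path) -> NetworkParams:
    return params_from_dict(json.loads(Path(path).read_text()))
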
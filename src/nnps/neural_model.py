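"""The per-side-effect feedforward classifier.

One independent network is trained for every polypharmacy side effect.  The
architecture is a fully connected feedforward net: input layer of the pair
feature width, hidden layers (300, 200, 100 by default) with ReLU
activations and inverted dropout after each hidden activation, and a single
sigmoid output unit giving the probability p_i that the pair exhibits side
effect i.

Weights are drawn from the Glorot (Xavier) normal initializer,
N(0, 2/(fan_in + fan_out)); biases start at zero.  Training is plain
mini-batch stochastic gradient descent with momentum on the binary
cross-entropy loss, for a fixed number of epochs with no early stopping.
Everything is reproducible from the config seed: the per-epoch shuffle and
the dropout masks are drawn from generators keyed on (seed, epoch).

The implementation is explicit numpy forward/backward passes; gradients are
exact and are verified against central finite differences in the test suite.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

logger = logging.getLogger("nnps")


@dataclass
class ModelConfig:
    """Hyperparameters of one per-side-effect network.

    Defaults are the selected operating point: three hidden layers of
    300/200/100 units, dropout 0.1, learning rate 0.01, momentum 0.9,
    batch size 1024, 50 epochs.
    """

    input_width: int
    hidden_sizes: tuple[int, ...] = (300, 200, 100)
    dropout_rate: float = 0.1
    learning_rate: float = 0.01
    momentum: float = 0.9
    batch_size: int = 1024
    epochs: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        self.hidden_sizes = tuple(int(h) for h in self.hidden_sizes)
        if self.input_width < 1 or any(h < 1 for h in self.hidden_sizes):
            raise ValueError("layer widths must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")
        if self.batch_size < 1 or self.epochs < 1:
            raise ValueError("batch_size and epochs must be >= 1")

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.input_width, *self.hidden_sizes, 1)


@dataclass
class MLPModel:
    """Weights/biases per layer plus the config that shaped them."""

    weights: list[np.ndarray]  # layer l: (fan_in, fan_out)
    biases: list[np.ndarray]  # layer l: (fan_out,)
    config: ModelConfig

    def __post_init__(self) -> None:
        sizes = self.config.layer_sizes
        for l, (w, b) in enumerate(zip(self.weights, self.biases)):
            if w.shape != (sizes[l], sizes[l + 1]) or b.shape != (sizes[l + 1],):
                raise ValueError(f"layer {l} shapes {w.shape}/{b.shape} break the chain {sizes}")

    @property
    def n_layers(self) -> int:
        return len(self.weights)


@dataclass
class TrainTrace:
    """Per-epoch training loss, validation loss and validation AUROC."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_auroc: list[float] = field(default_factory=list)


def init_model(cfg: ModelConfig) -> MLPModel:
    """Glorot-normal weights, zero biases, reproducible from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    sizes = cfg.layer_sizes
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        std = np.sqrt(2.0 / (fan_in + fan_out))
        weights.append(rng.normal(0.0, std, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return MLPModel(weights, biases, cfg)


def _forward_pass(
    model: MLPModel,
    x: np.ndarray,
    dropout_masks: list[np.ndarray] | None,
):
    """Forward pass returning logits plus the caches backprop needs.

    ``dropout_masks`` are the inverted-dropout multipliers for each hidden
    layer (None means evaluation mode, no dropout).
    """
    a = np.asarray(x, dtype=float)
    if a.ndim == 1:
        a = a[None, :]
    if a.shape[1] != model.config.input_width:
        raise ValueError(
            f"input width {a.shape[1]} != model input width {model.config.input_width}"
        )
    activations = [a]  # post-activation (and post-dropout) outputs per layer
    pre_relu = []
    n_hidden = model.n_layers - 1
    for l in range(n_hidden):
        z = activations[-1] @ model.weights[l] + model.biases[l]
        pre_relu.append(z)
        h = np.maximum(z, 0.0)
        if dropout_masks is not None:
            h = h * dropout_masks[l]
        activations.append(h)
    logits = (activations[-1] @ model.weights[-1] + model.biases[-1])[:, 0]
    return logits, activations, pre_relu


def forward(
    model: MLPModel,
    x: np.ndarray,
    train_mode: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Predicted probabilities in (0, 1) for a batch of pair features.

    Dropout is active only when ``train_mode`` is set (supply ``rng``);
    evaluation mode is deterministic.
    """
    masks = None
    if train_mode and model.config.dropout_rate > 0:
        if rng is None:
            rng = np.random.default_rng(model.config.seed)
        masks = _make_dropout_masks(model, np.atleast_2d(x).shape[0], rng)
    logits, _, _ = _forward_pass(model, x, masks)
    return _sigmoid(logits)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _make_dropout_masks(
    model: MLPModel, n: int, rng: np.random.Generator
) -> list[np.ndarray]:
    rate = model.config.dropout_rate
    keep = 1.0 - rate
    masks = []
    for h in model.config.hidden_sizes:
        masks.append((rng.random((n, h)) < keep).astype(float) / keep)
    return masks


def binary_cross_entropy(y: np.ndarray, p: np.ndarray) -> float:
    """Mean BCE of probabilities, clipped away from 0/1 for finiteness."""
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    y = np.asarray(y, dtype=float)
    return float(np.mean(-y * np.log(p) - (1.0 - y) * np.log(1.0 - p)))


def _bce_from_logits(y: np.ndarray, logits: np.ndarray) -> float:
    # log(1+e^z) - y z, numerically stable for large |z|
    return float(np.mean(np.logaddexp(0.0, logits) - np.asarray(y, float) * logits))


def gradients(
    model: MLPModel,
    x: np.ndarray,
    y: np.ndarray,
    dropout_masks: list[np.ndarray] | None = None,
) -> tuple[list[np.ndarray], list[np.ndarray], float]:
    """Analytic gradients of mean BCE w.r.t. every weight and bias.

    Returns (dWs, dbs, batch loss).  With ``dropout_masks`` given, the same
    masks used in the forward pass enter the backward pass, so the gradient
    is exact for the dropped-out network.
    """
    y = np.asarray(y, dtype=float).ravel()
    logits, activations, pre_relu = _forward_pass(model, x, dropout_masks)
    n = len(y)
    p = _sigmoid(logits)
    delta = ((p - y) / n)[:, None]  # d(mean BCE)/d(logits), (n, 1)

    dWs: list[np.ndarray] = [np.empty(0)] * model.n_layers
    dbs: list[np.ndarray] = [np.empty(0)] * model.n_layers
    for l in range(model.n_layers - 1, -1, -1):
        dWs[l] = activations[l].T @ delta
        dbs[l] = delta.sum(axis=0)
        if l > 0:
            delta = delta @ model.weights[l].T
            if dropout_masks is not None:
                delta = delta * dropout_masks[l - 1]
            delta = delta * (pre_relu[l - 1] > 0)
    return dWs, dbs, _bce_from_logits(y, logits)


def train(
    model: MLPModel,
    x_train: np.ndarray,
    y_train: np.ndarray,
    x_val: np.ndarray | None,
    y_val: np.ndarray | None,
    cfg: ModelConfig | None = None,
) -> tuple[MLPModel, TrainTrace]:
    """Mini-batch SGD with momentum for exactly ``cfg.epochs`` epochs.

    Examples are reshuffled every epoch with a generator keyed on
    (seed, epoch); the last incomplete mini-batch is used, not dropped.
    The recorded training loss is the epoch's average of pre-update batch
    losses; validation loss and AUROC are computed in evaluation mode at the
    end of each epoch.  There is no early stopping.
    """
    from .evaluation import auroc  # local import to avoid a cycle

    cfg = cfg or model.config
    x_train = np.asarray(x_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float).ravel()
    if len(x_train) == 0:
        raise ValueError("training set is empty")
    if set(np.unique(y_train)) - {0.0, 1.0}:
        raise ValueError("labels must be in {0, 1}")
    has_val = x_val is not None and y_val is not None and len(x_val) > 0
    if not has_val:
        warnings.warn("validation set empty: trace records training loss only")

    velocity_w = [np.zeros_like(w) for w in model.weights]
    velocity_b = [np.zeros_like(b) for b in model.biases]
    trace = TrainTrace()
    n = len(x_train)

    for epoch in range(cfg.epochs):
        shuffle_rng = np.random.default_rng([cfg.seed, epoch, 0])
        dropout_rng = np.random.default_rng([cfg.seed, epoch, 1])
        order = shuffle_rng.permutation(n)
        batch_losses = []
        for start in range(0, n, cfg.batch_size):
            batch = order[start : start + cfg.batch_size]
            xb, yb = x_train[batch], y_train[batch]
            masks = (
                _make_dropout_masks(model, len(batch), dropout_rng)
                if cfg.dropout_rate > 0
                else None
            )
            dWs, dbs, loss = gradients(model, xb, yb, masks)
            batch_losses.append(loss)
            for l in range(model.n_layers):
                velocity_w[l] = cfg.momentum * velocity_w[l] - cfg.learning_rate * dWs[l]
                velocity_b[l] = cfg.momentum * velocity_b[l] - cfg.learning_rate * dbs[l]
                model.weights[l] += velocity_w[l]
                model.biases[l] += velocity_b[l]
        trace.train_loss.append(float(np.mean(batch_losses)))
        if has_val:
            p_val = forward(model, x_val)
            trace.val_loss.append(binary_cross_entropy(y_val, p_val))
            labels = np.asarray(y_val).ravel()
            if len(np.unique(labels)) == 2:
                trace.val_auroc.append(auroc(labels, p_val))
            else:
                trace.val_auroc.append(float("nan"))
    return model, trace


# ---------------------------------------------------------------------------
# Serialization: JSON manifest + one text array file per parameter
# ---------------------------------------------------------------------------


def save_model(model: MLPModel, directory: str | Path) -> None:
    """Write a model container that round-trips bit-exactly.

    Layout: ``manifest.json`` (config and shapes) plus ``layer_<l>_W.tsv`` /
    ``layer_<l>_b.tsv`` text arrays at 17 significant digits (lossless for
    float64).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": asdict(model.config),
        "layer_sizes": list(model.config.layer_sizes),
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    for l, (w, b) in enumerate(zip(model.weights, model.biases)):
        np.savetxt(directory / f"layer_{l:02d}_W.tsv", w, fmt="%.17e", delimiter="\t")
        np.savetxt(directory / f"layer_{l:02d}_b.tsv", b, fmt="%.17e", delimiter="\t")


def load_model(directory: str | Path) -> MLPModel:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    cfg_dict = dict(manifest["config"])
    cfg_dict["hidden_sizes"] = tuple(cfg_dict["hidden_sizes"])
    cfg = ModelConfig(**cfg_dict)
    weights, biases = [], []
    for l in range(len(cfg.layer_sizes) - 1):
        w = np.loadtxt(directory / f"layer_{l:02d}_W.tsv", delimiter="\t", ndmin=2)
        b = np.loadtxt(directory / f"layer_{l:02d}_b.tsv", delimiter="\t", ndmin=1)
        weights.append(w)
        biases.append(b)
    return MLPModel(weights, biases, cfg)
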
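"""Stacked autoencoder for nonlinear reduction of high-order network features.

The encoder applies L tanh layers, h = tanh(W x + b), mapping the input
dimension down to a bottleneck; the decoder mirrors the dimensions in
reverse with strictly *linear* layers, x' = W h + b, and the whole stack is
trained jointly on the mean squared reconstruction error ||x' - x||^2 by
minibatch gradient descent (Adam by default; plain SGD available).
Gradients are computed by hand-derived backpropagation in numpy; the
analytic gradients are validated against central finite differences in the
test suite.

Layer widths interpolate geometrically between the input dimension and the
bottleneck. Inputs are expected to be standardized by the caller (the
pipeline z-scores with training-fold statistics) — tanh saturates otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import FitError, ValidationError

__all__ = [
    "AutoencoderModel",
    "TrainConfig",
    "geometric_dims",
    "fit_autoencoder",
    "encode",
    "reconstruct",
    "loss_and_gradients",
]

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    epochs: int = 200
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    optimizer: str = "adam"  # or "sgd"


@dataclass
class AutoencoderModel:
    """Parameters of the trained stack.

    ``layer_dims`` runs input -> bottleneck (strictly decreasing); the
    decoder dimensions are the reverse. Weight ``enc_W[i]`` has shape
    (layer_dims[i], layer_dims[i+1]).
    """

    layer_dims: list[int]
    enc_W: list[np.ndarray] = field(default_factory=list)
    enc_b: list[np.ndarray] = field(default_factory=list)
    dec_W: list[np.ndarray] = field(default_factory=list)
    dec_b: list[np.ndarray] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        dims = list(self.layer_dims)
        if len(dims) < 2:
            raise ValidationError("need at least one encoder layer")
        if any(b >= a for a, b in zip(dims[:-1], dims[1:])):
            raise ValidationError(f"layer dims must strictly decrease, got {dims}")
        if dims[-1] < 1:
            raise ValidationError("bottleneck dimension must be >= 1")
        self.layer_dims = dims

    @property
    def n_layers(self) -> int:
        return len(self.layer_dims) - 1

    @property
    def input_dim(self) -> int:
        return self.layer_dims[0]

    @property
    def bottleneck_dim(self) -> int:
        return self.layer_dims[-1]


def geometric_dims(input_dim: int, bottleneck: int, n_layers: int) -> list[int]:
    """Geometric interpolation input_dim -> bottleneck over n_layers layers.

    The bottleneck is clipped so the sequence can strictly decrease.
    """
    if n_layers < 1:
        raise ValidationError("n_layers must be >= 1")
    if input_dim < 2:
        raise ValidationError("input dimension must be >= 2")
    bottleneck = max(1, min(bottleneck, input_dim - n_layers))
    ratio = (bottleneck / input_dim) ** (1.0 / n_layers)
    dims = [input_dim]
    for i in range(1, n_layers):
        dims.append(int(round(input_dim * ratio**i)))
    dims.append(bottleneck)
    # enforce strict decrease (small input dims can collide after rounding)
    for i in range(1, len(dims)):
        dims[i] = min(dims[i], dims[i - 1] - 1)
    if dims[-1] < 1:
        raise ValidationError(
            f"cannot fit {n_layers} strictly decreasing layers under dim {input_dim}"
        )
    return dims


def _init_model(layer_dims: list[int], seed: int) -> AutoencoderModel:
    rng = np.random.default_rng(seed)
    model = AutoencoderModel(layer_dims=list(layer_dims), seed=seed)
    for din, dout in zip(layer_dims[:-1], layer_dims[1:]):
        s = np.sqrt(6.0 / (din + dout))
        model.enc_W.append(rng.uniform(-s, s, size=(din, dout)))
        model.enc_b.append(np.zeros(dout))
    rdims = layer_dims[::-1]
    for din, dout in zip(rdims[:-1], rdims[1:]):
        s = np.sqrt(6.0 / (din + dout))
        model.dec_W.append(rng.uniform(-s, s, size=(din, dout)))
        model.dec_b.append(np.zeros(dout))
    return model


def _forward(model: AutoencoderModel, X: np.ndarray):
    enc_acts = [X]
    h = X
    for W, b in zip(model.enc_W, model.enc_b):
        h = np.tanh(h @ W + b)
        enc_acts.append(h)
    dec_acts = []
    r = h
    for W, b in zip(model.dec_W, model.dec_b):
        r = r @ W + b  # decoder is strictly linear
        dec_acts.append(r)
    return enc_acts, dec_acts


def loss_and_gradients(model: AutoencoderModel, X: np.ndarray):
    """MSE reconstruction loss and its analytic gradients.

    Returns (loss, grads) with grads keyed like the model fields:
    ``("enc_W", i)``, ``("enc_b", i)``, ``("dec_W", i)``, ``("dec_b", i)``.
    """
    X = np.asarray(X, dtype=np.float64)
    enc_acts, dec_acts = _forward(model, X)
    recon = dec_acts[-1]
    diff = recon - X
    loss = float(np.mean(diff**2))
    grads: dict[tuple[str, int], np.ndarray] = {}
    g = 2.0 * diff / diff.size
    dec_inputs = [enc_acts[-1]] + dec_acts[:-1]
    for j in range(len(model.dec_W) - 1, -1, -1):
        grads[("dec_W", j)] = dec_inputs[j].T @ g
        grads[("dec_b", j)] = g.sum(axis=0)
        g = g @ model.dec_W[j].T
    for i in range(len(model.enc_W) - 1, -1, -1):
        g = g * (1.0 - enc_acts[i + 1] ** 2)  # tanh'
        grads[("enc_W", i)] = enc_acts[i].T @ g
        grads[("enc_b", i)] = g.sum(axis=0)
        g = g @ model.enc_W[i].T
    return loss, grads


class _Sgd:
    def __init__(self, lr: float) -> None:
        self.lr = lr

    def step(self, model: AutoencoderModel, grads) -> None:
        for (kind, i), g in grads.items():
            getattr(model, kind)[i] -= self.lr * g


class _Adam:
    """Adam with the standard defaults (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, lr: float) -> None:
        self.lr = lr
        self.t = 0
        self.m: dict = {}
        self.v: dict = {}

    def step(self, model: AutoencoderModel, grads) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        for key, g in grads.items():
            m = self.m.get(key, 0.0) * b1 + (1 - b1) * g
            v = self.v.get(key, 0.0) * b2 + (1 - b2) * g**2
            self.m[key], self.v[key] = m, v
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            kind, i = key
            getattr(model, kind)[i] -= self.lr * mhat / (np.sqrt(vhat) + eps)


_OPTIMIZERS = {"sgd": _Sgd, "adam": _Adam}


def reconstruction_loss(model: AutoencoderModel, X: np.ndarray) -> float:
    _, dec_acts = _forward(model, np.asarray(X, dtype=np.float64))
    return float(np.mean((dec_acts[-1] - X) ** 2))


def fit_autoencoder(
    X: np.ndarray, layer_dims: list[int], cfg: TrainConfig | None = None
) -> tuple[AutoencoderModel, list[float]]:
    """Train the stack on rows of X; returns (model, per-epoch loss history).

    Fully reproducible from ``cfg.seed`` (initialisation and batch order).
    """
    cfg = cfg or TrainConfig()
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("need a 2-D matrix with at least 2 samples")
    if X.shape[1] != layer_dims[0]:
        raise ValidationError(
            f"input dim {X.shape[1]} does not match layer_dims[0]={layer_dims[0]}"
        )
    n = X.shape[0]
    batch = cfg.batch_size
    if n < batch:
        logger.warning(
            "batch_size %d > %d samples; falling back to full-batch training",
            batch,
            n,
        )
        batch = n
    if cfg.optimizer not in _OPTIMIZERS:
        raise ValidationError(f"unknown optimizer {cfg.optimizer!r}; options: {sorted(_OPTIMIZERS)}")
    model = _init_model(layer_dims, cfg.seed)
    opt = _OPTIMIZERS[cfg.optimizer](cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    history: list[float] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        for start in range(0, n, batch):
            idx = order[start : start + batch]
            _, grads = loss_and_gradients(model, X[idx])
            opt.step(model, grads)
        epoch_loss = reconstruction_loss(model, X)
        if not np.isfinite(epoch_loss):
            raise FitError(
                f"reconstruction loss diverged at epoch {epoch + 1}; "
                "try a smaller learning rate"
            )
        history.append(epoch_loss)
    return model, history


def encode(model: AutoencoderModel, X: np.ndarray) -> np.ndarray:
    """Encoder pass: N x D -> N x bottleneck, entries in (-1, 1)."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.input_dim:
        raise ValidationError(
            f"expected N x {model.input_dim} input, got {X.shape}"
        )
    h = X
    for W, b in zip(model.enc_W, model.enc_b):
        h = np.tanh(h @ W + b)
    return h


def reconstruct(model: AutoencoderModel, X: np.ndarray) -> np.ndarray:
    """Full encoder+decoder pass."""
    _, dec_acts = _forward(model, np.asarray(X, dtype=np.float64))
    return dec_acts[-1]
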
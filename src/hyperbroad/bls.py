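"""Broad Learning System: random feature mapping + ridge closed form.

A BLS is a flat network. The input X (N x D) is projected by n groups of
random mapping nodes,

    Z_i = phi(X W_ei + beta_ei),    i = 1..n,   Z = [Z_1 | ... | Z_n],

then the concatenated mapping nodes feed m groups of enhancement nodes,

    H_j = delta(Z W_hj + beta_hj),  j = 1..m,   H = [H_1 | ... | H_m].

All random weights/biases are drawn uniform on [-1, 1] and never trained.
The only learned parameter is the output weight matrix solved in closed
form by ridge regression against one-hot class targets:

    W_out = argmin ||A W - Y||^2 + lambda ||W||^2,   A = [Z | H]
          = (A^T A + lambda I)^{-1} A^T Y.

Classification decodes argmax over the c class scores, ties broken toward
the earlier class in ``class_codes``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .exceptions import FitError, ValidationError

__all__ = ["BlsConfig", "BlsModel", "bls_features", "fit_bls", "predict_bls"]

ACTIVATIONS = {
    "tanh": np.tanh,
    "identity": lambda x: x,
}


@dataclass
class BlsConfig:
    """Architecture and solver settings.

    Defaults follow the multi-center operating point: 20 mapping groups of
    window size 100 (2000 mapping nodes) and one enhancement group of 10
    nodes; both activations tanh (tansig is tanh algebraically).
    """

    n_map_groups: int = 20
    nodes_per_group: int = 100
    n_enh_groups: int = 1
    enh_nodes_per_group: int = 10
    ridge: float = 1e-8
    map_activation: str = "tanh"
    enh_activation: str = "tanh"

    def validate(self) -> None:
        for name in ("n_map_groups", "nodes_per_group", "n_enh_groups", "enh_nodes_per_group"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be >= 1")
        if self.ridge <= 0:
            raise ValidationError("ridge penalty lambda must be > 0")
        for act in (self.map_activation, self.enh_activation):
            if act not in ACTIVATIONS:
                raise ValidationError(
                    f"unknown activation {act!r}; options: {sorted(ACTIVATIONS)}"
                )


@dataclass
class BlsModel:
    config: BlsConfig
    seed: int
    input_dim: int
    map_params: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    enh_params: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)
    W_out: np.ndarray | None = None
    class_codes: list[str] = field(default_factory=list)

    @property
    def n_feature_nodes(self) -> int:
        c = self.config
        return c.n_map_groups * c.nodes_per_group + c.n_enh_groups * c.enh_nodes_per_group


def _draw_params(model: BlsModel) -> None:
    cfg = model.config
    rng = np.random.default_rng(model.seed)
    for _ in range(cfg.n_map_groups):
        W = rng.uniform(-1.0, 1.0, size=(model.input_dim, cfg.nodes_per_group))
        b = rng.uniform(-1.0, 1.0, size=cfg.nodes_per_group)
        model.map_params.append((W, b))
    z_dim = cfg.n_map_groups * cfg.nodes_per_group
    for _ in range(cfg.n_enh_groups):
        W = rng.uniform(-1.0, 1.0, size=(z_dim, cfg.enh_nodes_per_group))
        b = rng.uniform(-1.0, 1.0, size=cfg.enh_nodes_per_group)
        model.enh_params.append((W, b))


def bls_features(model: BlsModel, X: np.ndarray) -> np.ndarray:
    """Node activations A = [Z_1 .. Z_n | H_1 .. H_m] for rows of X."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.input_dim:
        raise ValidationError(f"expected N x {model.input_dim} input, got {X.shape}")
    phi = ACTIVATIONS[model.config.map_activation]
    delta = ACTIVATIONS[model.config.enh_activation]
    z_groups = [phi(X @ W + b) for W, b in model.map_params]
    z = np.hstack(z_groups)
    h_groups = [delta(z @ W + b) for W, b in model.enh_params]
    return np.hstack([z] + h_groups)


def fit_bls(
    X: np.ndarray,
    labels,
    cfg: BlsConfig | None = None,
    seed: int = 0,
) -> BlsModel:
    """Draw random nodes and solve the ridge system for W_out.

    ``labels`` may be any hashable class codes; classes are ordered
    lexicographically and one-hot encoded. Requires at least two classes.
    """
    cfg = cfg or BlsConfig()
    cfg.validate()
    X = np.asarray(X, dtype=np.float64)
    labels = np.asarray(labels)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("need a 2-D matrix with at least 2 samples")
    if labels.shape[0] != X.shape[0]:
        raise ValidationError("labels length must match number of rows")
    classes = sorted(np.unique(labels).tolist())
    if len(classes) < 2:
        raise FitError(
            f"training data contains a single class {classes}; need both classes"
        )
    model = BlsModel(config=cfg, seed=seed, input_dim=X.shape[1], class_codes=[str(c) for c in classes])
    _draw_params(model)
    a = bls_features(model, X)
    y = np.zeros((X.shape[0], len(classes)))
    for j, c in enumerate(classes):
        y[labels == c, j] = 1.0
    gram = a.T @ a + cfg.ridge * np.eye(a.shape[1])
    model.W_out = scipy.linalg.solve(gram, a.T @ y, assume_a="sym")
    return model


def predict_bls(model: BlsModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Scores A W_out and argmax-decoded labels.

    Ties break toward the earlier entry of ``class_codes`` (np.argmax
    returns the first maximum).
    """
    if model.W_out is None:
        raise ValidationError("model has not been fitted")
    scores = bls_features(model, X) @ model.W_out
    idx = np.argmax(scores, axis=1)
    labels = np.asarray(model.class_codes, dtype=object)[idx]
    return labels, scores
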
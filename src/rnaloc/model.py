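"""Feature assembly and the shallow feed-forward localization network.

The default architecture is a single 200-unit ReLU hidden layer with
dropout, followed by a softmax output over the compartments. The loss
is the Kullback-Leibler divergence KL(Q || P) between the observed
compartment distribution Q (a probability vector in continuous mode, a
one-hot vector in discrete mode — in which case the loss reduces to
cross-entropy) and the predicted distribution P. Training uses Adam
with Nesterov momentum (Nadam). The implementation is plain numpy:
forward pass, analytic backpropagation and the optimizer update are
written out explicitly, and everything stochastic (weight
initialisation, shuffling, dropout masks) draws from one seeded
generator, so a (seed, data, config) triple reproduces the final
weights bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from rnaloc.io import LocalizationTarget

KL_EPSILON = 1e-7


@dataclass
class FeatureMatrix:
    """Row-per-mRNA feature matrix with a named block layout."""

    ids: list[str]
    values: np.ndarray
    block_layout: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.ids):
            raise ValueError("values must be a (n_ids, D) matrix")
        if self.block_layout and sum(self.block_layout.values()) != self.values.shape[1]:
            raise ValueError("block_layout spans must sum to the feature dimension")

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def rows_for(self, order: Sequence[str]) -> np.ndarray:
        index = {m: i for i, m in enumerate(self.ids)}
        missing = [m for m in order if m not in index]
        if missing:
            raise KeyError(f"ids missing from feature matrix: {missing[:5]}")
        return self.values[[index[m] for m in order]]


@dataclass
class ModelConfig:
    """Hyper-parameters of the localization network.

    The defaults are the selected values of the original study: 300
    epochs, batch size 512, one hidden layer of 200 fully connected
    neurons, dropout rate 0.2, with 10% of the training data held out
    to monitor validation loss. The learning rate of the Nadam
    optimizer defaults to the conventional 0.001.
    """

    hidden_layers: int = 1
    hidden_units: int = 200
    dropout_rate: float = 0.2
    epochs: int = 300
    batch_size: int = 512
    validation_fraction: float = 0.1
    learning_rate: float = 0.001
    beta_1: float = 0.9
    beta_2: float = 0.999
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_layers < 0:
            raise ValueError("hidden_layers must be >= 0")
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class TrainedModel:
    config: ModelConfig
    compartments: list[str]
    input_dim: int
    weights: list[np.ndarray]  # alternating W, b per layer
    training_history: dict[str, list[float]] = field(default_factory=dict)

    @property
    def n_parameters(self) -> int:
        return int(sum(w.size for w in self.weights))

    def layer_dims(self) -> list[int]:
        dims = [self.input_dim]
        for W in self.weights[::2]:
            dims.append(W.shape[1])
        return dims

    def save(self, path: str | Path) -> None:
        meta = {
            "config": asdict(self.config),
            "compartments": self.compartments,
            "input_dim": self.input_dim,
            "training_history": self.training_history,
        }
        arrays = {f"w{i}": w for i, w in enumerate(self.weights)}
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            weights = [data[f"w{i}"] for i in range(len(data.files) - 1)]
        return cls(
            config=ModelConfig(**meta["config"]),
            compartments=meta["compartments"],
            input_dim=meta["input_dim"],
            weights=weights,
            training_history=meta["training_history"],
        )


def assemble_features(
    kmer: FeatureMatrix,
    distance: FeatureMatrix,
    ppi: FeatureMatrix | None = None,
) -> FeatureMatrix:
    """Concatenate feature blocks per mRNA in fixed (kmer, distance, ppi) order.

    All blocks must cover the same id set; with the default encoders the
    result is 1024 + 144 + 500 = 1668 columns, or 1168 without PPI.
    """
    blocks = [("kmer", kmer), ("distance", distance)]
    if ppi is not None:
        blocks.append(("ppi", ppi))
    base_ids = set(kmer.ids)
    for name, block in blocks[1:]:
        if set(block.ids) != base_ids:
            missing = sorted(base_ids ^ set(block.ids))
            raise ValueError(f"id mismatch in {name} block: {missing[:5]}")
    order = list(kmer.ids)
    values = np.hstack([block.rows_for(order) for _, block in blocks])
    layout = {name: block.n_features for name, block in blocks}
    return FeatureMatrix(ids=order, values=values, block_layout=layout)


def relu(x):
    """Rectified linear unit, max(0, x); elementwise on arrays."""
    return np.maximum(0, x)


def softmax(x: np.ndarray) -> np.ndarray:
    """Row-wise softmax with max-subtraction for overflow safety."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("softmax of an empty vector")
    shifted = x - np.max(x, axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def kl_divergence(Q: np.ndarray, P: np.ndarray, epsilon: float = KL_EPSILON) -> float:
    """KL(Q || P) = sum Q log((Q+eps)/(P+eps)), Q observed, P predicted.

    For 2-D inputs the mean over rows is returned (the batch loss).
    """
    Q = np.atleast_2d(np.asarray(Q, dtype=float))
    P = np.atleast_2d(np.asarray(P, dtype=float))
    if Q.shape != P.shape:
        raise ValueError(f"shape mismatch {Q.shape} vs {P.shape}")
    per_row = np.sum(Q * (np.log(Q + epsilon) - np.log(P + epsilon)), axis=1)
    return float(per_row.mean())


def _layer_sizes(config: ModelConfig, input_dim: int, n_out: int,
                 hidden_units: Sequence[int] | None = None) -> list[int]:
    if hidden_units is not None:
        hidden = list(hidden_units)
    else:
        hidden = [config.hidden_units] * config.hidden_layers
    return [input_dim, *hidden, n_out]


def build_model(
    config: ModelConfig,
    input_dim: int,
    n_compartments: int,
    hidden_units: Sequence[int] | None = None,
) -> TrainedModel:
    """Initialise an untrained network.

    Hidden layers use He-scaled random initialisation from the seeded
    generator; the output layer starts at zero so an untrained model
    predicts the uniform distribution. ``hidden_units`` overrides the
    config with an explicit per-layer width list (used e.g. for the
    k-mer baseline with two input-width hidden layers);
    ``hidden_layers=0`` gives plain softmax regression.
    """
    if input_dim < 1 or n_compartments < 1:
        raise ValueError("input_dim and n_compartments must be >= 1")
    sizes = _layer_sizes(config, input_dim, n_compartments, hidden_units)
    rng = np.random.default_rng(config.seed)
    weights: list[np.ndarray] = []
    for li, (d_in, d_out) in enumerate(zip(sizes[:-1], sizes[1:])):
        last = li == len(sizes) - 2
        if last:
            W = np.zeros((d_in, d_out))
        else:
            W = rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out))
        weights.extend([W, np.zeros(d_out)])
    return TrainedModel(
        config=config,
        compartments=[f"c{i}" for i in range(n_compartments)],
        input_dim=input_dim,
        weights=weights,
    )


def baseline_kmer_model(config: ModelConfig, input_dim: int, n_compartments: int) -> TrainedModel:
    """Baseline: two hidden layers, each as wide as the input vector."""
    return build_model(config, input_dim, n_compartments,
                       hidden_units=[input_dim, input_dim])


def _forward(weights: list[np.ndarray], X: np.ndarray,
             dropout_rate: float = 0.0, rng: np.random.Generator | None = None):
    """Forward pass; returns probabilities and per-layer caches for backprop."""
    caches = []
    a = X
    n_layers = len(weights) // 2
    for li in range(n_layers):
        W, b = weights[2 * li], weights[2 * li + 1]
        z = a @ W + b
        if li == n_layers - 1:
            p = softmax(z)
            caches.append((a, None))
            return p, caches
        h = relu(z)
        mask = None
        if dropout_rate > 0 and rng is not None:
            # inverted dropout: scale at train time, identity at predict time
            mask = (rng.random(h.shape) >= dropout_rate) / (1.0 - dropout_rate)
            h = h * mask
        caches.append((a, (z, mask)))
        a = h
    raise AssertionError("unreachable")


def _backward(weights, caches, P, Q):
    """Analytic gradients of the mean KL loss w.r.t. every W and b."""
    n = P.shape[0]
    # d(mean KL)/d(logits): with loss term -Q log(P+eps),
    # r_j = Q_j P_j / (P_j + eps) and dL/dz_i = P_i * sum_j r_j - r_i
    r = Q * P / (P + KL_EPSILON)
    delta = (P * r.sum(axis=1, keepdims=True) - r) / n
    grads = [None] * len(weights)
    n_layers = len(weights) // 2
    for li in range(n_layers - 1, -1, -1):
        a_in, hidden_cache = caches[li]
        grads[2 * li] = a_in.T @ delta
        grads[2 * li + 1] = delta.sum(axis=0)
        if li > 0:
            z_prev, mask_prev = caches[li - 1][1]
            delta = delta @ weights[2 * li].T
            if mask_prev is not None:
                delta = delta * mask_prev
            delta = delta * (z_prev > 0)
    return grads


class _Nadam:
    """Adam with Nesterov momentum (Dozat 2016), Keras-style update."""

    def __init__(self, params: list[np.ndarray], lr: float, beta_1: float, beta_2: float,
                 eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta_1, beta_2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2, t = self.b1, self.b2, self.t
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            # Nesterov look-ahead on the first-moment estimate
            m_hat = b1 * self.m[i] / (1 - b1 ** (t + 1)) + (1 - b1) * g / (1 - b1**t)
            v_hat = self.v[i] / (1 - b2**t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def train(
    model: TrainedModel,
    X: FeatureMatrix,
    Y: LocalizationTarget,
    config: ModelConfig | None = None,
) -> TrainedModel:
    """Train in place by mini-batch Nadam on the mean KL loss.

    A validation split of ``validation_fraction`` (default 10%) of the
    training data is carved off once (seeded) and its loss recorded per
    epoch alongside the training loss; no early stopping is applied.
    Discrete targets are one-hot encoded, so the loss path is the same
    in both modes. Raises on a non-finite loss.
    """
    config = config or model.config
    Q_all = Y.as_matrix(order=X.ids)
    X_all = X.values
    if X_all.shape[1] != model.input_dim:
        raise ValueError(f"feature width {X_all.shape[1]} != model input {model.input_dim}")
    if len(Y.compartments) != len(model.compartments):
        raise ValueError("target compartments do not match the model output")
    model.compartments = list(Y.compartments)

    rng = np.random.default_rng(config.seed)
    n = X_all.shape[0]
    perm = rng.permutation(n)
    n_val = max(1, int(round(config.validation_fraction * n))) if n > 1 else 0
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    X_tr, Q_tr = X_all[tr_idx], Q_all[tr_idx]
    X_val, Q_val = X_all[val_idx], Q_all[val_idx]

    opt = _Nadam(model.weights, config.learning_rate, config.beta_1, config.beta_2)
    history = {"train_loss": [], "val_loss": []}
    for epoch in range(config.epochs):
        order = rng.permutation(len(X_tr))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(X_tr), config.batch_size):
            batch = order[start : start + config.batch_size]
            Xb, Qb = X_tr[batch], Q_tr[batch]
            P, caches = _forward(model.weights, Xb, config.dropout_rate, rng)
            loss = kl_divergence(Qb, P)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}; "
                    "lower the learning rate or rescale the features"
                )
            grads = _backward(model.weights, caches, P, Qb)
            opt.step(model.weights, grads)
            epoch_loss += loss
            n_batches += 1
        history["train_loss"].append(epoch_loss / max(n_batches, 1))
        if len(X_val):
            P_val, _ = _forward(model.weights, X_val)
            history["val_loss"].append(kl_divergence(Q_val, P_val))
    model.training_history = history
    return model


def predict_proba(model: TrainedModel, X: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Predicted compartment distribution per row (dropout disabled)."""
    values = X.values if isinstance(X, FeatureMatrix) else np.atleast_2d(np.asarray(X, dtype=float))
    if values.shape[1] != model.input_dim:
        raise ValueError(f"feature width {values.shape[1]} != model input {model.input_dim}")
    P, _ = _forward(model.weights, values)
    return P


def assign_locations(
    probs: np.ndarray,
    mode: str = "argmax",
    threshold: float = 0.5,
) -> list[list[int]]:
    """Turn probability rows into compartment index sets.

    ``argmax`` assigns exactly one compartment (ties broken toward the
    lowest index); ``threshold`` assigns every compartment with
    probability strictly above the threshold (possibly none).
    """
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    if mode == "argmax":
        return [[int(np.argmax(row))] for row in probs]
    if mode == "threshold":
        if not 0 < threshold < 1:
            raise ValueError("threshold must be in (0, 1)")
        return [list(np.flatnonzero(row > threshold)) for row in probs]
    raise ValueError(f"unknown assignment mode {mode!r}")
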
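"""Bottleneck autoencoder for multi-omics dimension reduction.

A fully connected symmetric autoencoder written directly in numpy: tanh
hidden layers (default architecture 500-100-500, so a 100-dimensional
bottleneck), linear reconstruction output, mean-squared-error loss with L1
and L2 weight penalties on every dense layer, inverted dropout after each
hidden layer except the bottleneck, and plain stochastic gradient descent
with a ``lr / (1 + decay * step)`` learning-rate schedule. Training is
single-threaded and fully determined by the config seed, so identical
configs give bit-identical loss traces and latent features.

The bottleneck activations are the compressed patient representation handed
to Cox screening and clustering; dropout is disabled at encode time, so
:func:`encode` is a pure function of (model, data).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix

_ACTIVATIONS = {
    "tanh": (np.tanh, lambda a: 1.0 - a * a),
    "identity": (lambda z: z, lambda a: np.ones_like(a)),
}


@dataclass
class AEConfig:
    """Hyperparameters. Defaults are the full-fidelity settings; tests and the
    scaled-down pipeline use :meth:`scaled_down` overrides."""

    hidden_layers: tuple = (500, 100, 500)
    l1_weight: float = 0.001
    l2_weight: float = 0.0001
    learning_rate: float = 0.01
    decay: float = 1e-6
    epochs: int = 150
    dropout: float = 0.5
    batch_size: int = 1
    activation: str = "tanh"
    seed: int = 0

    def validate(self) -> None:
        if len(self.hidden_layers) % 2 != 1:
            raise ValueError("hidden_layers must have an odd length so the "
                             "middle layer is the bottleneck")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}; "
                             f"choose from {sorted(_ACTIVATIONS)}")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    @property
    def bottleneck_index(self) -> int:
        return len(self.hidden_layers) // 2

    @property
    def bottleneck_width(self) -> int:
        return self.hidden_layers[self.bottleneck_index]

    @classmethod
    def scaled_down(cls, seed: int = 0, **overrides) -> "AEConfig":
        """Configuration for few-hundred-feature inputs.

        Relative to the full-fidelity defaults (sized for >10k features):
        the architecture shrinks with the input dimension (64-2-64; the
        default keeps the bottleneck below 1% of the feature count), the
        L1/L2 penalties shrink because per-element reconstruction gradients
        scale as 1/n_features and the unscaled penalties would dominate
        (the remaining L1 pressure still suppresses uninformative bottleneck
        dimensions, its role in the full-size model), per-sample SGD becomes
        full-batch gradient descent with a proportionally larger step, and
        dropout is disabled — 0.5 dropout next to a 2-unit bottleneck is
        overwhelming noise in a net this small.
        """
        params = dict(hidden_layers=(64, 2, 64), epochs=2000, batch_size=100000,
                      learning_rate=0.5, dropout=0.0,
                      l1_weight=2e-4, l2_weight=1e-4, seed=seed)
        params.update(overrides)
        return cls(**params)


@dataclass
class AEModel:
    weights: list           # numpy arrays, one per dense layer
    biases: list
    config: AEConfig
    loss_trace: list = field(default_factory=list)  # mean MSE per epoch
    feature_names: list = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        arrays = {f"W{i}": w for i, w in enumerate(self.weights)}
        arrays.update({f"b{i}": b for i, b in enumerate(self.biases)})
        cfg = asdict(self.config)
        cfg["hidden_layers"] = list(cfg["hidden_layers"])
        meta = json.dumps({"config": cfg, "loss_trace": self.loss_trace,
                           "feature_names": self.feature_names,
                           "n_layers": len(self.weights)})
        np.savez_compressed(path, meta=np.array(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "AEModel":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["meta"]))
            n = meta["n_layers"]
            weights = [data[f"W{i}"] for i in range(n)]
            biases = [data[f"b{i}"] for i in range(n)]
        cfg = meta["config"]
        cfg["hidden_layers"] = tuple(cfg["hidden_layers"])
        return cls(weights, biases, AEConfig(**cfg), meta["loss_trace"],
                   meta["feature_names"])


def _init_layers(dims: list[int], rng: np.random.Generator):
    """Glorot-uniform weights, zero biases."""
    weights, biases = [], []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return weights, biases


def train_autoencoder(X: ExpressionMatrix | pd.DataFrame | np.ndarray,
                      config: AEConfig | None = None) -> AEModel:
    """Train the autoencoder on a standardized patients-by-features matrix.

    Raises if the loss becomes non-finite (divergence); in that case reduce
    ``learning_rate``.
    """
    config = config or AEConfig()
    config.validate()
    if isinstance(X, ExpressionMatrix):
        names, data = list(X.features), X.to_numpy()
    elif isinstance(X, pd.DataFrame):
        names, data = list(X.columns), X.to_numpy(dtype=float)
    else:
        data = np.asarray(X, dtype=float)
        names = [f"f{i}" for i in range(data.shape[1])]
    if not np.isfinite(data).all():
        raise ValueError("input matrix contains non-finite values")

    n, d = data.shape
    dims = [d] + list(config.hidden_layers) + [d]
    rng = np.random.default_rng(config.seed)
    weights, biases = _init_layers(dims, rng)
    act, act_grad = _ACTIVATIONS[config.activation]
    n_hidden = len(config.hidden_layers)
    bneck = config.bottleneck_index
    # inverted dropout after each hidden layer except the bottleneck
    drop_layers = [i for i in range(n_hidden) if i != bneck] if config.dropout > 0 else []

    lr0, decay = config.learning_rate, config.decay
    step = 0
    loss_trace: list[float] = []
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        sq_sum = 0.0
        for start in range(0, n, config.batch_size):
            batch = data[order[start:start + config.batch_size]]
            bsz = batch.shape[0]
            # forward; keep pre-dropout activations for the tanh derivative
            inputs = [batch]          # input fed to each dense layer
            pre_drop = []             # activation before any dropout mask
            masks: dict[int, np.ndarray] = {}
            h = batch
            for li in range(n_hidden):
                a = act(h @ weights[li] + biases[li])
                pre_drop.append(a)
                if li in drop_layers:
                    mask = (rng.random(a.shape) >= config.dropout) / (1.0 - config.dropout)
                    a = a * mask
                    masks[li] = mask
                h = a
                inputs.append(h)
            out = h @ weights[-1] + biases[-1]

            resid = out - batch
            sq_sum += float((resid ** 2).sum())
            # backward: mean over batch elements
            delta = 2.0 * resid / (bsz * d)
            for li in range(n_hidden, -1, -1):
                a_prev = inputs[li]
                gW = a_prev.T @ delta
                gb = delta.sum(axis=0)
                if config.l1_weight:
                    gW += config.l1_weight * np.sign(weights[li])
                if config.l2_weight:
                    gW += 2.0 * config.l2_weight * weights[li]
                if li > 0:
                    delta = delta @ weights[li].T
                    if (li - 1) in masks:
                        delta = delta * masks[li - 1]
                    delta = delta * act_grad(pre_drop[li - 1])
                lr = lr0 / (1.0 + decay * step)
                weights[li] -= lr * gW
                biases[li] -= lr * gb
            step += 1
        epoch_loss = sq_sum / (n * d)
        if not np.isfinite(epoch_loss):
            raise FloatingPointError(
                "training diverged (non-finite loss); try a smaller learning_rate")
        loss_trace.append(epoch_loss)

    return AEModel(weights, biases, config, loss_trace, names)


def encode(model: AEModel, X: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    """Bottleneck features (patients x latent dims). Dropout is off."""
    if isinstance(X, ExpressionMatrix):
        df = X.values
    else:
        df = X
    names = list(df.columns)
    if names != model.feature_names:
        missing = [f for f in model.feature_names if f not in set(names)]
        extra = [f for f in names if f not in set(model.feature_names)]
        if missing or extra:
            raise ValueError(f"feature schema mismatch: missing {missing[:5]}, "
                             f"extra {extra[:5]}")
        df = df[model.feature_names]

    act, _ = _ACTIVATIONS[model.config.activation]
    h = df.to_numpy(dtype=float)
    for li in range(model.config.bottleneck_index + 1):
        h = act(h @ model.weights[li] + model.biases[li])
    cols = [f"latent{i:03d}" for i in range(h.shape[1])]
    return pd.DataFrame(h, index=df.index, columns=cols)
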
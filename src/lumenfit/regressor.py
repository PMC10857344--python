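"""Convolutional regressor predicting B-spline shape parameters from images.

A deliberately small feedforward network maps a single-channel cross-section
image directly to the ``D`` radial control distances of the lumen contour:
three 3x3 "same"-padded convolution layers with 8 kernels each and ReLU
activations, a flattening step, three fully connected ReLU layers of 64, 32
and 16 units, and a linear output layer of ``D`` units.  For the default
15x15 input and D = 10 this network has exactly 119,290 trainable weights.

The implementation is self-contained numpy: forward and backward passes for
the convolution/dense stack, mean-squared-error loss, the Adam optimizer and
validation-based early stopping with best-weight restoration.  At this scale
a full training run takes minutes on one CPU core, and inference is a
handful of small matrix products per image.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .forward import CrossSectionImage

__all__ = [
    "RegressorConfig",
    "TrainedRegressor",
    "build",
    "trainable_parameter_count",
    "train",
    "predict",
    "evaluate",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class RegressorConfig:
    input_side: int = 15
    conv_channels: int = 8
    conv_layers: int = 3
    kernel_size: int = 3
    dense_units: tuple[int, int, int] = (64, 32, 16)
    output_dim: int = 10
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 500
    early_stopping_patience: int = 15
    predict_intensities: bool = False  # extend the head to also predict (a, b)

    def __post_init__(self) -> None:
        if self.input_side < 3:
            raise ValueError("input_side must be at least 3 pixels")

    @property
    def n_outputs(self) -> int:
        return self.output_dim + (2 if self.predict_intensities else 0)


def trainable_parameter_count(config: RegressorConfig) -> int:
    """Closed-form weight count of the architecture (kernels + biases)."""
    k2 = config.kernel_size**2
    c = config.conv_channels
    count = (k2 * 1 + 1) * c  # first conv, single input channel
    count += (config.conv_layers - 1) * (k2 * c + 1) * c
    fan_in = config.input_side**2 * c
    for units in config.dense_units:
        count += (fan_in + 1) * units
        fan_in = units
    count += (fan_in + 1) * config.n_outputs
    return count


# --- network internals ----------------------------------------------------

def _glorot(rng: np.random.Generator, shape: tuple, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


def _init_weights(config: RegressorConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    k = config.kernel_size
    c = config.conv_channels
    weights: dict[str, np.ndarray] = {}
    cin = 1
    for layer in range(config.conv_layers):
        weights[f"Wc{layer}"] = _glorot(rng, (k, k, cin, c), k * k * cin, k * k * c)
        weights[f"bc{layer}"] = np.zeros(c, dtype=np.float32)
        cin = c
    fan_in = config.input_side**2 * c
    dims = list(config.dense_units) + [config.n_outputs]
    for layer, units in enumerate(dims):
        weights[f"Wd{layer}"] = _glorot(rng, (fan_in, units), fan_in, units)
        weights[f"bd{layer}"] = np.zeros(units, dtype=np.float32)
        fan_in = units
    return weights


def _conv_forward(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """3x3 same-padded convolution on (B, H, W, Cin) via shifted matmuls."""
    B, H, Wd, _ = x.shape
    k = W.shape[0]
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    dtype = np.result_type(x.dtype, W.dtype)
    out = np.broadcast_to(b, (B, H, Wd, W.shape[3])).astype(dtype).copy()
    for dy in range(k):
        for dx in range(k):
            out += xp[:, dy:dy + H, dx:dx + Wd, :] @ W[dy, dx]
    return out


def _conv_backward(x: np.ndarray, W: np.ndarray, dout: np.ndarray,
                   need_dx: bool) -> tuple[np.ndarray | None, np.ndarray, np.ndarray]:
    B, H, Wd, Cin = x.shape
    k = W.shape[0]
    pad = k // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    dW = np.zeros_like(W)
    dflat = dout.reshape(-1, W.shape[3])
    for dy in range(k):
        for dx in range(k):
            patch = xp[:, dy:dy + H, dx:dx + Wd, :].reshape(-1, Cin)
            dW[dy, dx] = patch.T @ dflat
    db = dflat.sum(axis=0)
    dx_arr = None
    if need_dx:
        dxp = np.zeros_like(xp)
        for dy in range(k):
            for dx in range(k):
                dxp[:, dy:dy + H, dx:dx + Wd, :] += dout @ W[dy, dx].T
        dx_arr = dxp[:, pad:-pad, pad:-pad, :]
    return dx_arr, dW, db


def _forward(weights: dict, config: RegressorConfig, x: np.ndarray,
             cache: list | None = None) -> np.ndarray:
    """Forward pass; ``x`` is (B, side, side) float32.  Caches pre-ReLU inputs."""
    h = x[..., None].astype(np.float32)
    for layer in range(config.conv_layers):
        z = _conv_forward(h, weights[f"Wc{layer}"], weights[f"bc{layer}"])
        if cache is not None:
            cache.append(("conv", layer, h, z))
        h = np.maximum(z, 0.0)
    h = h.reshape(h.shape[0], -1)
    n_dense = len(config.dense_units)
    for layer in range(n_dense + 1):
        z = h @ weights[f"Wd{layer}"] + weights[f"bd{layer}"]
        if cache is not None:
            cache.append(("dense", layer, h, z))
        h = np.maximum(z, 0.0) if layer < n_dense else z
    return h


def _backward(weights: dict, config: RegressorConfig, cache: list,
              dloss: np.ndarray) -> dict[str, np.ndarray]:
    grads: dict[str, np.ndarray] = {}
    n_dense = len(config.dense_units)
    dh = dloss
    for kind, layer, h_in, z in reversed(cache):
        if kind == "dense":
            dz = dh if layer == n_dense else dh * (z > 0)
            grads[f"Wd{layer}"] = h_in.T @ dz
            grads[f"bd{layer}"] = dz.sum(axis=0)
            dh = dz @ weights[f"Wd{layer}"].T
        else:
            if dh.ndim == 2:  # coming out of the flatten step
                dh = dh.reshape(z.shape[0], config.input_side, config.input_side, -1)
            dz = dh * (z > 0)
            dx, dW, db = _conv_backward(h_in, weights[f"Wc{layer}"], dz, need_dx=layer > 0)
            grads[f"Wc{layer}"] = dW
            grads[f"bc{layer}"] = db
            dh = dx
    return grads


class _Adam:
    def __init__(self, weights: dict, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in weights.items()}
        self.v = {k: np.zeros_like(v) for k, v in weights.items()}
        self.t = 0

    def step(self, weights: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for key, g in grads.items():
            m = self.m[key]
            v = self.v[key]
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            weights[key] -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


# --- public API -----------------------------------------------------------

@dataclass
class TrainedRegressor:
    weights: dict[str, np.ndarray]
    config: RegressorConfig
    training_history: pd.DataFrame | None = field(default=None, repr=False)
    seed: int = 0

    def predict(self, images: np.ndarray) -> np.ndarray:
        return predict(self, images)


def build(config: RegressorConfig = RegressorConfig(), seed: int = 0
          ) -> tuple[TrainedRegressor, int]:
    """Instantiate an untrained network; returns (model, trainable weight count)."""
    rng = np.random.default_rng(seed)
    weights = _init_weights(config, rng)
    count = int(sum(w.size for w in weights.values()))
    expected = trainable_parameter_count(config)
    assert count == expected, f"weight allocation ({count}) != closed form ({expected})"
    return TrainedRegressor(weights=weights, config=config, seed=seed), count


def _mse(pred: np.ndarray, target: np.ndarray) -> float:
    return float(np.mean((pred - target) ** 2))


def train(model: TrainedRegressor, train_x: np.ndarray, train_y: np.ndarray,
          val_x: np.ndarray, val_y: np.ndarray, seed: int = 0,
          verbose: bool = False) -> TrainedRegressor:
    """Mini-batch Adam/MSE training with early stopping on validation loss.

    Stops at ``max_epochs`` or once validation MSE has not improved for
    ``early_stopping_patience`` epochs, restoring the best-validation weights.
    """
    config = model.config
    if train_x.shape[0] == 0 or val_x.shape[0] == 0:
        raise ValueError("training and validation splits must be non-empty")
    train_x = np.asarray(train_x, dtype=np.float32)
    train_y = np.asarray(train_y, dtype=np.float32)
    val_x = np.asarray(val_x, dtype=np.float32)
    val_y = np.asarray(val_y, dtype=np.float32)
    rng = np.random.default_rng(seed)
    weights = model.weights
    optimizer = _Adam(weights, config.learning_rate)
    history: list[dict] = []
    best_val = np.inf
    best_weights = {k: v.copy() for k, v in weights.items()}
    patience_left = config.early_stopping_patience
    n = train_x.shape[0]
    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        train_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            xb, yb = train_x[idx], train_y[idx]
            cache: list = []
            pred = _forward(weights, config, xb, cache)
            err = pred - yb
            if not np.all(np.isfinite(err)):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            dloss = (2.0 / err.size) * err
            grads = _backward(weights, config, cache, dloss)
            optimizer.step(weights, grads)
            train_loss += float(np.sum(err**2))
        train_loss /= n * train_y.shape[1]
        val_loss = _mse(_forward(weights, config, val_x), val_y)
        history.append({"epoch": epoch, "train_mse": train_loss, "val_mse": val_loss})
        if verbose:
            print(f"epoch {epoch:3d}  train {train_loss:.3e}  val {val_loss:.3e}")
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_weights = {k: v.copy() for k, v in weights.items()}
            patience_left = config.early_stopping_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break
    return TrainedRegressor(
        weights=best_weights, config=config,
        training_history=pd.DataFrame(history), seed=seed,
    )


def predict(model: TrainedRegressor, images: np.ndarray | CrossSectionImage) -> np.ndarray:
    """Predict shape parameter vectors; deterministic given the weights.

    Accepts a single :class:`CrossSectionImage`, one ``(side, side)`` array or
    a batch ``(n, side, side)``; images must match ``config.input_side``
    exactly (no silent resizing).
    """
    if isinstance(images, CrossSectionImage):
        images = images.intensities
    arr = np.asarray(images, dtype=np.float32)
    single = arr.ndim == 2
    if single:
        arr = arr[None]
    side = model.config.input_side
    if arr.shape[1] != side or arr.shape[2] != side:
        raise ValueError(f"expected {side}x{side} input, got {arr.shape[1]}x{arr.shape[2]}")
    out = _forward(model.weights, model.config, arr)
    return out[0] if single else out


def evaluate(model: TrainedRegressor, images: np.ndarray, targets: np.ndarray,
             R: float | None = None, delta_s: float | None = None) -> dict:
    """Per-parameter error statistics on a labeled split.

    Reports per-element mean error and error std, mean absolute error and its
    std, the pooled error standard deviation over all elements, and (when
    ``R`` and ``delta_s`` are given) the MAE expressed in mm via
    ``MAE * R * delta_s``.  Also returns histogram data of the pooled errors.
    """
    pred = predict(model, images)
    err = pred - np.asarray(targets, dtype=np.float32)
    abs_err = np.abs(err)
    counts, edges = np.histogram(err.ravel(), bins=81)
    report = {
        "mean_error": err.mean(axis=0),
        "std_error": err.std(axis=0),
        "mae_mean": abs_err.mean(axis=0),
        "mae_std": abs_err.std(axis=0),
        "pooled_mean": float(err.mean()),
        "pooled_std": float(err.std()),
        "histogram_counts": counts,
        "histogram_edges": edges,
        "n": int(err.shape[0]),
    }
    if R is not None and delta_s is not None:
        report["mae_mm"] = report["mae_mean"] * R * delta_s
    return report


# --- serialization --------------------------------------------------------

def save_model(path, model: TrainedRegressor) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savez(path / "weights.npz", **model.weights)
    meta = {"config": asdict(model.config), "seed": model.seed}
    meta["config"]["dense_units"] = list(model.config.dense_units)
    with open(path / "config.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    if model.training_history is not None:
        model.training_history.to_csv(path / "history.csv", index=False)


def load_model(path) -> TrainedRegressor:
    path = Path(path)
    with open(path / "config.json") as fh:
        meta = json.load(fh)
    cfg = meta["config"]
    cfg["dense_units"] = tuple(cfg["dense_units"])
    config = RegressorConfig(**cfg)
    with np.load(path / "weights.npz") as data:
        weights = {k: data[k] for k in data.files}
    history = None
    hist_path = path / "history.csv"
    if hist_path.exists():
        history = pd.read_csv(hist_path)
    return TrainedRegressor(weights=weights, config=config,
                            training_history=history, seed=meta["seed"])
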
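"""Convolutional regression network mapping a feature matrix to a level in [0, 1].

The network reads the 5 x 100 x 1 per-site input with a 5x5 convolution
(valid padding, stride 1, 128 filters), after which the feature map is one
row tall and the remaining two convolutions are 3x1. Max pooling of size 2
follows the first and second convolutions. The trace of temporal lengths is

    100 --conv 5x5--> 96 --pool 2--> 48 --conv 3--> 46 --pool 2--> 23
        --conv 3--> 21

so the map entering the dense stage is 21 x 1 x 128. The first dense layer
maps its flattened 2688 values to 1280 units (a 10 x 1 x 128 representation)
and the second maps those to a single sigmoid output. Convolutions use ReLU
activations. Training minimizes mean squared error with Adam; mean absolute
error is tracked as the metric, and early stopping monitors it on a
held-out validation split.

Everything here is plain numpy: convolutions are im2col matrix products and
gradients are derived by hand, which keeps training bit-reproducible from a
single integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ModelSpec",
    "TrainingConfig",
    "TrainedModel",
    "CNNRegressor",
    "build_model",
    "train",
    "predict",
]


@dataclass(frozen=True)
class ModelSpec:
    """Architecture constants of the network."""

    n_filters: int = 128
    kernel1: tuple[int, int] = (5, 5)   # rows x columns of the first (2-D) kernel
    kernel_1d: int = 3                  # second and third (1-D) kernels
    pool_size: int = 2
    dense_units: int = 1280             # 10 x 128 after the first dense layer
    input_rows: int = 5
    input_length: int = 100

    def shape_trace(self) -> list[tuple[str, tuple[int, ...]]]:
        """Named (rows, temporal length, channels) shapes through the network."""
        if self.kernel1[0] != self.input_rows:
            raise ValueError(
                f"first kernel height {self.kernel1[0]} must consume all "
                f"{self.input_rows} input rows"
            )
        t = [("input", (self.input_rows, self.input_length, 1))]
        L = self.input_length - self.kernel1[1] + 1
        t.append(("conv1", (1, L, self.n_filters)))
        L //= self.pool_size
        t.append(("pool1", (1, L, self.n_filters)))
        L = L - self.kernel_1d + 1
        t.append(("conv2", (1, L, self.n_filters)))
        L //= self.pool_size
        t.append(("pool2", (1, L, self.n_filters)))
        L = L - self.kernel_1d + 1
        t.append(("conv3", (1, L, self.n_filters)))
        if L < 1:
            raise ValueError(f"shape trace collapsed before the dense stage: {t}")
        if self.dense_units % self.n_filters != 0:
            raise ValueError(
                f"dense_units {self.dense_units} not a multiple of n_filters; trace {t}"
            )
        t.append(("dense1", (self.dense_units // self.n_filters, 1, self.n_filters)))
        t.append(("dense2", (1,)))
        return t

    @property
    def conv_output_length(self) -> int:
        """Temporal length of the feature map entering the dense stage."""
        return dict(self.shape_trace())["conv3"][1]


@dataclass(frozen=True)
class TrainingConfig:
    """Optimizer settings: Adam on MSE with a short linear learning-rate warmup.

    The warmup matters: Adam's first updates move every parameter by a full
    learning-rate step, which can drive the sigmoid output into saturation
    where MSE gradients vanish; ramping the rate over the first
    ``warmup_steps`` batches avoids that.
    """

    max_epochs: int = 50
    batch_size: int = 128
    learning_rate: float = 1e-3
    warmup_steps: int = 50
    validation_fraction: float = 0.1
    patience: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.validation_fraction < 1):
            raise ValueError("validation fraction must be in (0, 1)")


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _windows(x: np.ndarray, k: int) -> np.ndarray:
    """(n, L, C) -> (n, L-k+1, k*C) stride-1 im2col along the temporal axis."""
    v = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)  # (n, O, C, k)
    return np.ascontiguousarray(v.transpose(0, 1, 3, 2)).reshape(
        x.shape[0], x.shape[1] - k + 1, k * x.shape[2]
    )


def _windows_backward(d_cols: np.ndarray, k: int, L: int, C: int) -> np.ndarray:
    """Scatter-add gradient of :func:`_windows` back to (n, L, C)."""
    n, O, _ = d_cols.shape
    d_cols = d_cols.reshape(n, O, k, C)
    dx = np.zeros((n, L, C), dtype=d_cols.dtype)
    for j in range(k):
        dx[:, j : j + O, :] += d_cols[:, :, j, :]
    return dx


class CNNRegressor:
    """The network with its weights; see the module docstring for the layout.

    Weights are kept in ``dtype`` (float32 by default, which roughly halves
    training time with no measurable effect on the recalibration error;
    float64 is available for numerical checks).
    """

    def __init__(self, spec: ModelSpec | None = None, seed: int = 0, dtype=np.float32):
        self.spec = spec or ModelSpec()
        self.spec.shape_trace()  # validate before allocating
        self.dtype = np.dtype(dtype)
        s = self.spec
        rng = np.random.default_rng(seed)
        k1 = s.input_rows * s.kernel1[1]
        k2 = s.kernel_1d * s.n_filters
        flat = s.conv_output_length * s.n_filters
        raw = {
            "W1": _glorot(rng, k1, s.n_filters, (k1, s.n_filters)),
            "b1": np.zeros(s.n_filters),
            "W2": _glorot(rng, k2, s.n_filters, (k2, s.n_filters)),
            "b2": np.zeros(s.n_filters),
            "W3": _glorot(rng, k2, s.n_filters, (k2, s.n_filters)),
            "b3": np.zeros(s.n_filters),
            "W4": _glorot(rng, flat, s.dense_units, (flat, s.dense_units)),
            "b4": np.zeros(s.dense_units),
            "W5": _glorot(rng, s.dense_units, 1, (s.dense_units, 1)),
            "b5": np.zeros(1),
        }
        self.params: dict[str, np.ndarray] = {
            k: v.astype(self.dtype) for k, v in raw.items()
        }

    # ---- forward -----------------------------------------------------------

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        s = self.spec
        X = np.asarray(X, dtype=self.dtype)
        if X.ndim == 4 and X.shape[1:] == (s.input_rows, s.input_length, 1):
            X = X[..., 0]
        if X.ndim != 3 or X.shape[1:] != (s.input_rows, s.input_length):
            raise ValueError(
                f"expected input of shape (n, {s.input_rows}, {s.input_length}, 1), "
                f"got {X.shape}"
            )
        return X

    @staticmethod
    def _conv(cols: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
        """(n, O, k) @ (k, f) + b as one 2-D GEMM."""
        n, O, k = cols.shape
        return (cols.reshape(n * O, k) @ W).reshape(n, O, -1) + b

    def forward(self, X: np.ndarray, want_cache: bool = False):
        p, s = self.params, self.spec
        X = self._prepare(X)
        n = X.shape[0]
        # conv1 consumes all input rows: patches are 5x5 blocks along the width
        v = np.lib.stride_tricks.sliding_window_view(X, s.kernel1[1], axis=2)
        cols1 = np.ascontiguousarray(v.transpose(0, 2, 1, 3)).reshape(
            n, -1, s.input_rows * s.kernel1[1]
        )
        Z1 = self._conv(cols1, p["W1"], p["b1"])
        A1 = np.maximum(Z1, 0)
        P1, arg1 = _maxpool(A1, s.pool_size)
        cols2 = _windows(P1, s.kernel_1d)
        Z2 = self._conv(cols2, p["W2"], p["b2"])
        A2 = np.maximum(Z2, 0)
        P2, arg2 = _maxpool(A2, s.pool_size)
        cols3 = _windows(P2, s.kernel_1d)
        Z3 = self._conv(cols3, p["W3"], p["b3"])
        A3 = np.maximum(Z3, 0)
        F = A3.reshape(n, -1)
        Z4 = F @ p["W4"] + p["b4"]
        A4 = np.maximum(Z4, 0)
        Z5 = A4 @ p["W5"] + p["b5"]
        out = 1.0 / (1.0 + np.exp(-Z5[:, 0].astype(np.float64)))
        if not want_cache:
            return out
        cache = dict(
            cols1=cols1, Z1=Z1, arg1=arg1, P1=P1,
            cols2=cols2, Z2=Z2, arg2=arg2, P2=P2,
            cols3=cols3, Z3=Z3, F=F, Z4=Z4, A4=A4, out=out,
        )
        return out, cache

    # ---- backward ----------------------------------------------------------

    @staticmethod
    def _conv_grads(cols: np.ndarray, dZ: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n, O, k = cols.shape
        f = dZ.shape[2]
        gW = cols.reshape(n * O, k).T @ dZ.reshape(n * O, f)
        return gW, dZ.sum(axis=(0, 1))

    def backward(self, cache: dict, d_out: np.ndarray) -> dict[str, np.ndarray]:
        """Gradients of the loss w.r.t. parameters given d loss / d output."""
        p, s = self.params, self.spec
        out = cache["out"]
        dZ5 = (d_out * out * (1.0 - out))[:, None].astype(self.dtype)
        g = {}
        g["W5"] = cache["A4"].T @ dZ5
        g["b5"] = dZ5.sum(axis=0)
        dA4 = dZ5 @ p["W5"].T
        dZ4 = dA4 * (cache["Z4"] > 0)
        g["W4"] = cache["F"].T @ dZ4
        g["b4"] = dZ4.sum(axis=0)
        dF = dZ4 @ p["W4"].T
        dZ3 = dF.reshape(cache["Z3"].shape) * (cache["Z3"] > 0)
        g["W3"], g["b3"] = self._conv_grads(cache["cols3"], dZ3)
        n, O3, f = dZ3.shape
        dcols3 = (dZ3.reshape(n * O3, f) @ p["W3"].T).reshape(n, O3, -1)
        dP2 = _windows_backward(dcols3, s.kernel_1d, cache["P2"].shape[1], s.n_filters)
        dA2 = _maxpool_backward(dP2, cache["arg2"], cache["Z2"].shape, s.pool_size)
        dZ2 = dA2 * (cache["Z2"] > 0)
        g["W2"], g["b2"] = self._conv_grads(cache["cols2"], dZ2)
        n, O2, f = dZ2.shape
        dcols2 = (dZ2.reshape(n * O2, f) @ p["W2"].T).reshape(n, O2, -1)
        dP1 = _windows_backward(dcols2, s.kernel_1d, cache["P1"].shape[1], s.n_filters)
        dA1 = _maxpool_backward(dP1, cache["arg1"], cache["Z1"].shape, s.pool_size)
        dZ1 = dA1 * (cache["Z1"] > 0)
        g["W1"], g["b1"] = self._conv_grads(cache["cols1"], dZ1)
        return g

    def predict(self, X: np.ndarray, batch_size: int = 512) -> np.ndarray:
        X = self._prepare(X)
        parts = [self.forward(X[i : i + batch_size]) for i in range(0, len(X), batch_size)]
        return np.concatenate(parts) if parts else np.empty(0)

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}


def _maxpool(A: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Non-overlapping max pool of size p along axis 1; trailing remainder dropped."""
    n, L, C = A.shape
    O = L // p
    blocks = A[:, : O * p, :].reshape(n, O, p, C)
    arg = blocks.argmax(axis=2)
    out = np.take_along_axis(blocks, arg[:, :, None, :], axis=2)[:, :, 0, :]
    return out, arg


def _maxpool_backward(dP: np.ndarray, arg: np.ndarray, shape, p: int) -> np.ndarray:
    n, L, C = shape
    O = L // p
    dA = np.zeros(shape, dtype=dP.dtype)
    blocks = dA[:, : O * p, :].reshape(n, O, p, C)
    np.put_along_axis(blocks, arg[:, :, None, :], dP[:, :, None, :], axis=2)
    dA[:, : O * p, :] = blocks.reshape(n, O * p, C)
    return dA


@dataclass
class TrainedModel:
    """A fitted network: spec, weights, training history and feature scheme."""

    spec: ModelSpec
    params: dict[str, np.ndarray]
    history: pd.DataFrame
    scheme: str = "2mer"
    metadata: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray, batch_size: int = 512) -> np.ndarray:
        net = CNNRegressor(self.spec, seed=0)
        net.params = self.params
        return net.predict(X, batch_size=batch_size)

    def save(self, path: str) -> None:
        meta = {
            "spec": asdict(self.spec),
            "scheme": self.scheme,
            "metadata": self.metadata,
            "history": self.history.to_dict(orient="list"),
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **self.params)

    @classmethod
    def load(cls, path: str) -> "TrainedModel":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            params = {k: z[k] for k in z.files if k != "__meta__"}
        spec_d = meta["spec"]
        spec_d["kernel1"] = tuple(spec_d["kernel1"])
        return cls(
            spec=ModelSpec(**spec_d),
            params=params,
            history=pd.DataFrame(meta["history"]),
            scheme=meta["scheme"],
            metadata=meta["metadata"],
        )


def build_model(spec: ModelSpec | None = None, seed: int = 0) -> CNNRegressor:
    """Construct the untrained network with reproducible weight initialization."""
    return CNNRegressor(spec, seed=seed)


def train(
    model: CNNRegressor,
    features: np.ndarray,
    targets: Sequence[float],
    config: TrainingConfig | None = None,
    scheme: str = "2mer",
    metadata: dict | None = None,
) -> TrainedModel:
    """Fit the network by minimizing MSE with Adam.

    A validation split is held out from the training examples; after every
    epoch the MSE and MAE of both splits are recorded, and training stops
    when the validation MAE has not improved for ``patience`` epochs. The
    weights from the best validation epoch are returned.
    """
    cfg = config or TrainingConfig()
    X = model._prepare(features)
    y = np.asarray(targets, dtype=np.float64)
    if len(X) != len(y):
        raise ValueError(f"{len(X)} feature matrices but {len(y)} targets")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("targets must lie in [0, 1]")
    n_val = max(1, int(round(cfg.validation_fraction * len(y))))
    if len(y) - n_val < 1:
        raise ValueError(f"too few examples ({len(y)}) for validation split")
    rng = np.random.default_rng(cfg.seed)
    order = rng.permutation(len(y))
    val_idx, tr_idx = order[:n_val], order[n_val:]
    Xtr, ytr, Xval, yval = X[tr_idx], y[tr_idx], X[val_idx], y[val_idx]

    adam_m = {k: np.zeros_like(v) for k, v in model.params.items()}
    adam_v = {k: np.zeros_like(v) for k, v in model.params.items()}
    b1, b2, eps, t = 0.9, 0.999, 1e-8, 0

    history: list[dict] = []
    best_mae, best_params, best_epoch, stale = np.inf, model.copy_params(), 0, 0
    for epoch in range(cfg.max_epochs):
        perm = rng.permutation(len(ytr))
        for start in range(0, len(ytr), cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            xb, yb = Xtr[idx], ytr[idx]
            out, cache = model.forward(xb, want_cache=True)
            if not np.all(np.isfinite(out)):
                raise FloatingPointError(
                    f"non-finite network output at epoch {epoch}; "
                    "inspect the learning rate and input scaling"
                )
            d_out = 2.0 * (out - yb) / len(yb)
            grads = model.backward(cache, d_out)
            t += 1
            lr = cfg.learning_rate
            if cfg.warmup_steps > 0:
                lr *= min(1.0, t / cfg.warmup_steps)
            for k in model.params:
                adam_m[k] = b1 * adam_m[k] + (1 - b1) * grads[k]
                adam_v[k] = b2 * adam_v[k] + (1 - b2) * grads[k] ** 2
                mhat = adam_m[k] / (1 - b1**t)
                vhat = adam_v[k] / (1 - b2**t)
                model.params[k] -= (lr * mhat / (np.sqrt(vhat) + eps)).astype(
                    model.params[k].dtype
                )
        pred_tr = model.predict(Xtr)
        pred_val = model.predict(Xval)
        row = {
            "epoch": epoch,
            "train_mse": float(np.mean((pred_tr - ytr) ** 2)),
            "train_mae": float(np.mean(np.abs(pred_tr - ytr))),
            "val_mse": float(np.mean((pred_val - yval) ** 2)),
            "val_mae": float(np.mean(np.abs(pred_val - yval))),
        }
        history.append(row)
        if row["val_mae"] < best_mae - 1e-9:
            best_mae, best_params, best_epoch, stale = (
                row["val_mae"], model.copy_params(), epoch, 0,
            )
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    model.params = best_params
    meta = dict(metadata or {})
    meta.update(
        best_epoch=best_epoch,
        best_val_mae=float(best_mae),
        n_train=int(len(ytr)),
        n_val=int(n_val),
        seed=cfg.seed,
    )
    return TrainedModel(
        spec=model.spec,
        params=best_params,
        history=pd.DataFrame(history),
        scheme=scheme,
        metadata=meta,
    )


def predict(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    """Levels in [0, 1], one per input feature matrix."""
    return model.predict(features)
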
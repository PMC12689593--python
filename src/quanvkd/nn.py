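"""Minimal dense/convolutional neural networks with hand-written backprop.

The two classical halves of the hybrid classifier — the high-capacity teacher
CNN (Conv2D 128/256 filters) consuming standardized images and the
lightweight student CNN (Conv2D 64/128) consuming quantum feature maps —
are small enough that a compact numpy implementation with explicit forward
and backward passes covers them.  Layout is NHWC throughout; convolutions
are 3x3 with same padding, pooling is 2x2 max with stride 2 (skipped when a
spatial side is smaller than 2), and weights use seeded Glorot-uniform
initialization.  Gradient correctness is pinned by finite-difference tests.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "ModelSpec",
    "TrainConfig",
    "Sequential",
    "build_model",
    "softmax",
    "cross_entropy",
    "one_hot",
    "train_classifier",
    "weights_checksum",
    "TEACHER_FILTERS",
    "STUDENT_FILTERS",
]

TEACHER_FILTERS = (128, 256)
STUDENT_FILTERS = (64, 128)


# --------------------------------------------------------------------------
# layers
# --------------------------------------------------------------------------

class Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator | None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _glorot(shape: tuple[int, ...], fan_in: int, fan_out: int,
            rng: np.random.Generator) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Conv2D(Layer):
    """3x3 (configurable) convolution with same padding, NHWC."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        fan_in = kernel * kernel * c_in
        fan_out = kernel * kernel * c_out
        self.kernel = kernel
        self.W = _glorot((kernel, kernel, c_in, c_out), fan_in, fan_out, rng)
        self.b = np.zeros(c_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, training, rng):
        k, p = self.kernel, self.kernel // 2
        n, h, w, _ = x.shape
        self._xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        out = np.broadcast_to(self.b, (n, h, w, self.b.shape[0])).copy()
        for i in range(k):
            for j in range(k):
                out += np.tensordot(self._xp[:, i:i + h, j:j + w, :],
                                    self.W[i, j], axes=([3], [0]))
        self._out_shape = (n, h, w)
        return out

    def backward(self, dout):
        k, p = self.kernel, self.kernel // 2
        n, h, w = self._out_shape
        dW, db = self.grads
        dW[...] = 0.0
        db[...] = dout.sum(axis=(0, 1, 2))
        dxp = np.zeros_like(self._xp)
        for i in range(k):
            for j in range(k):
                patch = self._xp[:, i:i + h, j:j + w, :]
                dW[i, j] = np.tensordot(patch, dout, axes=([0, 1, 2], [0, 1, 2]))
                dxp[:, i:i + h, j:j + w, :] += np.tensordot(dout, self.W[i, j],
                                                            axes=([3], [1]))
        return dxp[:, p:p + h, p:p + w, :]


class ReLU(Layer):
    def forward(self, x, training, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/columns are dropped.

    Gradient is split equally among tied maxima so the backward pass is
    deterministic.
    """

    def forward(self, x, training, rng):
        n, h, w, c = x.shape
        h2, w2 = h // 2, w // 2
        self._in_shape = x.shape
        xc = x[:, :h2 * 2, :w2 * 2, :]
        self._x4 = xc.reshape(n, h2, 2, w2, 2, c)
        out = self._x4.max(axis=(2, 4))
        self._out = out
        return out

    def backward(self, dout):
        n, h, w, c = self._in_shape
        h2, w2 = h // 2, w // 2
        mask = self._x4 == self._out[:, :, None, :, None, :]
        counts = mask.sum(axis=(2, 4), keepdims=True)
        d4 = mask * (dout[:, :, None, :, None, :] / counts)
        dx = np.zeros(self._in_shape)
        dx[:, :h2 * 2, :w2 * 2, :] = d4.reshape(n, h2 * 2, w2 * 2, c)
        return dx


class Flatten(Layer):
    def forward(self, x, training, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        super().__init__()
        self.W = _glorot((d_in, d_out), d_in, d_out, rng)
        self.b = np.zeros(d_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, training, rng):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        dW, db = self.grads
        dW[...] = self._x.T @ dout
        db[...] = dout.sum(axis=0)
        return dout @ self.W.T


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, training, rng):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        self._mask = (rng.uniform(size=x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Sequential:
    """Ordered layer stack with explicit forward/backward passes."""

    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training, rng)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def predict_logits(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Evaluation-mode forward pass (dropout disabled), batched."""
        outs = [self.forward(x[i:i + batch_size], training=False)
                for i in range(0, len(x), batch_size)]
        return np.concatenate(outs) if outs else np.empty((0,))

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        for p, w in zip(self.params, weights, strict=True):
            p[...] = w


# --------------------------------------------------------------------------
# model specification
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Architecture settings for the teacher or student CNN.

    The per-role default filter pairs are the configured hyperparameters of
    the hybrid pipeline: teacher (128, 256), student (64, 128).
    """

    role: str
    input_shape: tuple[int, int, int]
    n_classes: int = 4
    conv_filters: tuple[int, int] | None = None
    kernel: int = 3
    dense_units: int = 64
    dropout_rate: float = 0.5

    def __post_init__(self) -> None:
        if self.role not in ("teacher", "student"):
            raise ValueError(f"role must be teacher or student, got {self.role!r}")
        if self.conv_filters is None:
            filters = TEACHER_FILTERS if self.role == "teacher" else STUDENT_FILTERS
            object.__setattr__(self, "conv_filters", filters)
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if min(self.input_shape[:2]) < self.kernel:
            raise ValueError(
                f"input spatial sides {self.input_shape[:2]} smaller than "
                f"kernel {self.kernel}"
            )


def build_model(spec: ModelSpec, seed: int = 0) -> Sequential:
    """Construct the role's CNN.

    Conv(f1, 3x3, same) -> ReLU -> MaxPool(2x2, skipped if a spatial side
    < 2) -> Conv(f2, 3x3, same) -> ReLU -> Flatten -> Dense(dense_units) ->
    ReLU -> Dropout -> Dense(n_classes), emitting logits; softmax is applied
    only at the loss / inference level.
    """
    rng = np.random.default_rng(seed)
    h, w, c = spec.input_shape
    f1, f2 = spec.conv_filters
    layers: list[Layer] = [Conv2D(c, f1, spec.kernel, rng), ReLU()]
    if min(h, w) >= 2:
        layers.append(MaxPool2())
        h, w = h // 2, w // 2
    layers += [Conv2D(f1, f2, spec.kernel, rng), ReLU(), Flatten(),
               Dense(h * w * f2, spec.dense_units, rng), ReLU(),
               Dropout(spec.dropout_rate),
               Dense(spec.dense_units, spec.n_classes, rng)]
    return Sequential(layers)


# --------------------------------------------------------------------------
# probabilities and losses
# --------------------------------------------------------------------------

def softmax(logits: np.ndarray) -> np.ndarray:
    """Max-shifted softmax along the last axis; rejects non-finite input."""
    logits = np.asarray(logits, dtype=float)
    if not np.all(np.isfinite(logits)):
        raise ValueError("softmax requires finite logits")
    shifted = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy(y_onehot: np.ndarray, probs: np.ndarray,
                  eps: float = 1e-12) -> float:
    """-sum(y * log p) with epsilon-clipped probabilities.

    For a single (y, p) pair this is -log p_true; for batches (2-D inputs)
    the mean over samples is returned.
    """
    y = np.asarray(y_onehot, dtype=float)
    p = np.clip(np.asarray(probs, dtype=float), eps, None)
    per_sample = -(y * np.log(p)).sum(axis=-1)
    return float(per_sample if per_sample.ndim == 0 else per_sample.mean())


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    out = np.zeros((len(labels), n_classes))
    out[np.arange(len(labels)), labels] = 1.0
    return out


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings (Adam, batch 8, lr 1e-3, early stopping)."""

    batch_size: int = 8
    max_epochs: int = 100
    lr: float = 1e-3
    optimizer: str = "adam"
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is provided")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be positive")


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v, strict=True):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


LossFn = Callable[[np.ndarray, np.ndarray], tuple[np.ndarray, dict[str, float]]]


def _ce_loss(logits: np.ndarray, y_batch: np.ndarray) -> tuple[np.ndarray, dict[str, float]]:
    probs = softmax(logits)
    n = len(logits)
    loss = cross_entropy(y_batch, probs)
    dlogits = (probs - y_batch) / n
    return dlogits, {"total_loss": loss, "ce_component": loss, "kl_component": 0.0}


def train_classifier(model: Sequential, x_train: np.ndarray, y_train: np.ndarray,
                     x_val: np.ndarray, y_val: np.ndarray,
                     config: TrainConfig,
                     loss_fn: LossFn | None = None) -> list[dict[str, float]]:
    """Mini-batch Adam training with early stopping on validation loss.

    ``y_train``/``y_val`` are one-hot.  ``loss_fn`` maps (logits, y_batch) to
    (dL/dlogits, component dict); the default is plain cross-entropy, and the
    distillation module supplies the combined objective.  Early stopping
    monitors validation cross-entropy with the configured patience and
    restores the best weights.  Returns the per-epoch history.
    """
    if loss_fn is None:
        loss_fn = _ce_loss
    rng = np.random.default_rng(config.seed)
    optimizer = Adam(model.params, config.lr)
    n = len(x_train)
    best_val = np.inf
    best_weights = model.get_weights()
    since_best = 0
    history: list[dict[str, float]] = []

    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        sums: dict[str, float] = {}
        n_batches = 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = model.forward(x_train[idx], training=True, rng=rng)
            dlogits, components = loss_fn(logits, y_train[idx])
            model.backward(dlogits)
            optimizer.step(model.grads)
            for key, value in components.items():
                sums[key] = sums.get(key, 0.0) + value
            n_batches += 1

        val_logits = model.predict_logits(x_val)
        val_probs = softmax(val_logits)
        val_loss = cross_entropy(y_val, val_probs)
        val_acc = float(np.mean(val_probs.argmax(axis=1) == y_val.argmax(axis=1)))
        row = {key: value / n_batches for key, value in sums.items()}
        row.update(epoch=epoch, val_loss=val_loss, val_accuracy=val_acc)
        history.append(row)

        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_weights = model.get_weights()
            since_best = 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break

    model.set_weights(best_weights)
    return history


def save_model(model: Sequential, spec: ModelSpec, path, seed: int = 0) -> None:
    """Checkpoint: weights in a compressed array archive plus a JSON sidecar
    carrying the architecture spec and init seed."""
    import json
    from dataclasses import asdict
    from pathlib import Path

    path = Path(path)
    np.savez_compressed(path, **{f"p{i}": p for i, p in enumerate(model.params)})
    meta = asdict(spec)
    meta["seed"] = seed
    sidecar = path.with_suffix(path.suffix + ".json") if path.suffix != ".npz" \
        else path.with_suffix(".json")
    sidecar.write_text(json.dumps(meta, indent=2))


def load_model(path) -> tuple[Sequential, ModelSpec]:
    """Rebuild a checkpointed model from its archive and sidecar."""
    import json
    from pathlib import Path

    path = Path(path)
    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text())
    seed = meta.pop("seed", 0)
    meta["input_shape"] = tuple(meta["input_shape"])
    if meta.get("conv_filters") is not None:
        meta["conv_filters"] = tuple(meta["conv_filters"])
    spec = ModelSpec(**meta)
    model = build_model(spec, seed=seed)
    with np.load(path) as z:
        model.set_weights([z[f"p{i}"] for i in range(len(model.params))])
    return model, spec


def weights_checksum(model: Sequential) -> str:
    """SHA-256 over all parameter bytes; used to prove the teacher stayed frozen."""
    digest = hashlib.sha256()
    for p in model.params:
        digest.update(np.ascontiguousarray(p).tobytes())
    return digest.hexdigest()
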
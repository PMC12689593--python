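"""Teacher-student knowledge distillation.

A frozen, already-trained teacher provides temperature-softened class
probabilities; the student minimizes the combined objective

    alpha * CE(y, softmax(S)) + (1 - alpha) * KL(soft(T) || soft(S))

with soft(L) = softmax(L / temperature).  Defaults follow the pipeline's
hyperparameter table: temperature 5, alpha 0.5.  The KL direction is
teacher-as-reference, the standard distillation convention.  The classical
T^2 rescaling of the KL term is off by default and available via
``squared_t_scaling``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .nn import (ModelSpec, Sequential, TrainConfig, build_model, cross_entropy,
                 softmax, train_classifier, weights_checksum)

__all__ = [
    "DistillConfig",
    "softened_probs",
    "kl_divergence",
    "distill_loss",
    "train_with_distillation",
    "write_history_csv",
]

_EPS = 1e-12


@dataclass(frozen=True)
class DistillConfig:
    """Temperature and mixing weight of the combined objective."""

    temperature: float = 5.0
    alpha: float = 0.5
    squared_t_scaling: bool = False

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")


def softened_probs(logits: np.ndarray, temperature: float) -> np.ndarray:
    """softmax(logits / T); T=1 is the ordinary softmax, T -> inf flattens
    toward uniform."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return softmax(np.asarray(logits, dtype=float) / temperature)


def kl_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """KL(p || q) = sum p log(p/q) with epsilon clipping; direction is
    reference-first (teacher || student)."""
    p = np.clip(np.asarray(p, dtype=float), _EPS, None)
    q = np.clip(np.asarray(q, dtype=float), _EPS, None)
    per = (p * (np.log(p) - np.log(q))).sum(axis=-1)
    return float(per if per.ndim == 0 else per.mean())


def distill_loss(y_onehot: np.ndarray, student_logits: np.ndarray,
                 teacher_logits: np.ndarray, cfg: DistillConfig) -> float:
    """Combined objective alpha*CE + (1-alpha)*KL(soft teacher || soft student).

    With ``squared_t_scaling`` the KL term is additionally multiplied by T^2
    (the classical correction keeping soft-target gradients on the hard-label
    scale); the default formulation omits it.
    """
    y = np.asarray(y_onehot, dtype=float)
    s = np.asarray(student_logits, dtype=float)
    t = np.asarray(teacher_logits, dtype=float)
    if s.shape != t.shape or y.shape != s.shape:
        raise ValueError(f"shape mismatch: y {y.shape}, student {s.shape}, "
                         f"teacher {t.shape}")
    ce = cross_entropy(y, softmax(s))
    kl = kl_divergence(softened_probs(t, cfg.temperature),
                       softened_probs(s, cfg.temperature))
    if cfg.squared_t_scaling:
        kl *= cfg.temperature**2
    return cfg.alpha * ce + (1.0 - cfg.alpha) * kl


def make_distill_loss_fn(teacher_logits: np.ndarray, cfg: DistillConfig):
    """Per-batch loss/gradient closure for the shared training loop.

    The gradient of the KL term with respect to the student logits is
    (soft(S) - soft(T)) / T, scaled by (1 - alpha) (and T^2 when the
    classical rescaling is on); the CE term contributes
    alpha * (softmax(S) - y).  ``teacher_logits`` must be aligned with the
    training array the loop indexes into.
    """

    def loss_fn(student_logits: np.ndarray, y_batch: np.ndarray, idx: np.ndarray):
        t_logits = teacher_logits[idx]
        n = len(student_logits)
        probs = softmax(student_logits)
        soft_s = softened_probs(student_logits, cfg.temperature)
        soft_t = softened_probs(t_logits, cfg.temperature)
        ce = cross_entropy(y_batch, probs)
        kl = kl_divergence(soft_t, soft_s)
        kl_scale = cfg.temperature**2 if cfg.squared_t_scaling else 1.0
        total = cfg.alpha * ce + (1.0 - cfg.alpha) * kl_scale * kl
        dlogits = (cfg.alpha * (probs - y_batch)
                   + (1.0 - cfg.alpha) * kl_scale
                   * (soft_s - soft_t) / cfg.temperature) / n
        return dlogits, {"total_loss": total, "ce_component": ce,
                         "kl_component": kl}

    return loss_fn


def train_with_distillation(teacher: Sequential, student_spec: ModelSpec,
                            x_train: np.ndarray, y_train: np.ndarray,
                            x_val: np.ndarray, y_val: np.ndarray,
                            cfg: DistillConfig, train_config: TrainConfig,
                            teacher_inputs: np.ndarray | None = None,
                            ) -> tuple[Sequential, list[dict[str, float]]]:
    """Train a fresh student against the frozen teacher's soft targets.

    The teacher's logits over the training set are computed once up front
    (the teacher never updates, which a before/after weight checksum
    asserts).  ``teacher_inputs`` lets the teacher read a different view of
    the same samples (standardized images) than the student (quantum feature
    maps); it defaults to the student's inputs.  Returns the trained student
    and the per-epoch history with total/CE/KL components.
    """
    if not teacher.params:
        raise RuntimeError("teacher has no parameters; train it first")
    checksum_before = weights_checksum(teacher)
    t_inputs = x_train if teacher_inputs is None else teacher_inputs
    if len(t_inputs) != len(x_train):
        raise ValueError("teacher_inputs must align with x_train")
    teacher_logits = teacher.predict_logits(t_inputs)

    base_fn = make_distill_loss_fn(teacher_logits, cfg)
    # The shared loop passes (logits, y_batch); smuggle batch indices by
    # aligning teacher logits through a stateful wrapper set per batch.
    state = {"idx": None}

    def loss_fn(student_logits, y_batch):
        return base_fn(student_logits, y_batch, state["idx"])

    student = build_model(student_spec, seed=train_config.seed)
    history = _train_with_indices(student, x_train, y_train, x_val, y_val,
                                  train_config, loss_fn, state)

    if weights_checksum(teacher) != checksum_before:
        raise RuntimeError("teacher weights changed during distillation")
    return student, history


def _train_with_indices(model, x_train, y_train, x_val, y_val, config,
                        loss_fn, state) -> list[dict[str, float]]:
    """Index-aware wrapper over the shared loop.

    Reimplements the batching of :func:`train_classifier` only insofar as the
    loss closure must know which samples are in the batch (to fetch the
    matching teacher logits); all optimization mechanics are identical.
    """
    from .nn import Adam

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
            state["idx"] = idx
            logits = model.forward(x_train[idx], training=True, rng=rng)
            dlogits, components = loss_fn(logits, y_train[idx])
            model.backward(dlogits)
            optimizer.step(model.grads)
            for key, value in components.items():
                sums[key] = sums.get(key, 0.0) + value
            n_batches += 1

        val_probs = softmax(model.predict_logits(x_val))
        val_loss = cross_entropy(y_val, val_probs)
        val_acc = float(np.mean(val_probs.argmax(axis=1) == y_val.argmax(axis=1)))
        row = {key: value / n_batches for key, value in sums.items()}
        row.update(epoch=epoch, val_loss=val_loss, val_accuracy=val_acc)
        history.append(row)

        if val_loss < best_val - 1e-12:
            best_val, best_weights, since_best = val_loss, model.get_weights(), 0
        else:
            since_best += 1
            if since_best >= config.patience:
                break

    model.set_weights(best_weights)
    return history


def write_history_csv(history: list[dict[str, float]], path: str | Path) -> None:
    """Training-history CSV: epoch, total/CE/KL components, validation stats."""
    columns = ["epoch", "total_loss", "ce_component", "kl_component",
               "val_loss", "val_accuracy"]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=columns, extrasaction="ignore")
        writer.writeheader()
        for row in history:
            writer.writerow({c: row.get(c, "") for c in columns})
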
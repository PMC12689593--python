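"""End-to-end orchestration of the hybrid experiment.

One :func:`run_experiment` call performs, per split repeat: phantom
generation, optional rebalancing, deterministic preprocessing, quantum
feature extraction (cached), teacher training on standardized images,
student training on the quantum feature maps both without and with
knowledge distillation, and evaluation — writing per-repeat classification
tables, confusion matrices, ROC points, aggregated summaries, and a
reproducibility manifest.  In the default deterministic single-threaded
mode two runs from the same configuration produce bit-identical summaries.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np

from . import __version__
from .config import RunConfig, config_to_dict
from .distillation import train_with_distillation, write_history_csv
from .evaluation import (EvalReport, aggregate_repeats, evaluate_probs,
                         make_splits, write_confusion_json, write_per_class_csv,
                         write_roc_points_csv, write_summary_csv)
from .nn import (ModelSpec, Sequential, build_model, one_hot, softmax,
                 train_classifier, weights_checksum)
from .preprocess import prepare_roi, resize_image, standardize, to_grayscale
from .quanvolution import quanvolve_dataset
from .synthetic import LabeledDataset, generate_dataset, rebalance

__all__ = ["run_experiment", "prepare_inputs", "run_single_arm"]

logger = logging.getLogger(__name__)

ARMS = ("teacher", "student_no_kd", "student_kd")

# fixed offsets deriving stage seeds from the run seed
_SEED_REBALANCE = 1_000
_SEED_TEACHER = 100
_SEED_STUDENT = 200
_SEED_DISTILL = 300


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and original cause."""


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - stage boundary
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s finished in %.1fs", name, time.perf_counter() - t0)
            return result
        return inner
    return wrap


@_stage("synthesize")
def _make_dataset(config: RunConfig) -> LabeledDataset:
    dataset = generate_dataset(config.phantom, config.n_total)
    if config.rebalance_targets is not None:
        rng = np.random.default_rng(config.seed + _SEED_REBALANCE)
        dataset = rebalance(dataset, config.rebalance_targets, rng)
    return dataset


@_stage("preprocess")
def _teacher_view(dataset: LabeledDataset, config: RunConfig) -> np.ndarray:
    """Standardized full-size images, NHWC with one channel.

    Standardization uses the dataset-level mean and standard deviation, the
    shift-and-scale normalization the classical branch trains on.
    """
    resized = np.stack([
        resize_image(to_grayscale(img), config.preprocess.target_side)
        for img in dataset.images
    ])
    mu, sigma = float(resized.mean()), float(resized.std())
    std = standardize(resized, mu, sigma, config.preprocess.epsilon)
    return std.pixels[..., None]


@_stage("quanvolve")
def _student_view(dataset: LabeledDataset, config: RunConfig,
                  cache_path: Path | None) -> np.ndarray:
    return quanvolve_dataset(dataset, config.pqc, config.preprocess,
                             cache_path=cache_path)


def prepare_inputs(config: RunConfig, run_dir: Path | None = None):
    """Dataset plus both model views (teacher images, student feature maps)."""
    dataset = _make_dataset(config)
    teacher_x = _teacher_view(dataset, config)
    cache = None if run_dir is None or config.pqc.trainable \
        else run_dir / "feature_maps.npz"
    student_x = _student_view(dataset, config, cache)
    if config.teacher_on_quantum_features:
        teacher_x = student_x
    return dataset, teacher_x, student_x


def _carve_validation(train_idx: np.ndarray, labels: np.ndarray, seed: int,
                      fraction: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Split a stratified validation subset out of the training indices."""
    rng = np.random.default_rng(seed)
    val_parts, fit_parts = [], []
    for k in np.unique(labels[train_idx]):
        members = rng.permutation(train_idx[labels[train_idx] == k])
        n_val = max(1, int(round(len(members) * fraction)))
        val_parts.append(members[:n_val])
        fit_parts.append(members[n_val:])
    return np.sort(np.concatenate(fit_parts)), np.sort(np.concatenate(val_parts))


def run_single_arm(model: Sequential, x: np.ndarray, y_onehot: np.ndarray,
                   fit_idx: np.ndarray, val_idx: np.ndarray, config: RunConfig,
                   seed: int, loss_fn=None) -> list[dict]:
    from .nn import TrainConfig

    train_cfg = TrainConfig(
        batch_size=config.train.batch_size, max_epochs=config.train.max_epochs,
        lr=config.train.lr, patience=config.train.patience, seed=seed)
    return train_classifier(model, x[fit_idx], y_onehot[fit_idx],
                            x[val_idx], y_onehot[val_idx], train_cfg,
                            loss_fn=loss_fn)


def _model_spec(role: str, overrides, input_shape, n_classes) -> ModelSpec:
    return ModelSpec(role=role, input_shape=input_shape, n_classes=n_classes,
                     conv_filters=overrides.conv_filters,
                     dense_units=overrides.dense_units,
                     dropout_rate=overrides.dropout_rate)


def run_experiment(config: RunConfig) -> dict:
    """Run the full experiment; returns the aggregated summaries per arm.

    The run directory receives, per repeat, each arm's per-class table,
    confusion matrix and ROC points, plus training histories; at the top
    level the aggregated summary CSV per arm and a manifest with the
    configuration hash, seeds and library versions.
    """
    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    dataset, teacher_x, student_x = prepare_inputs(config, run_dir)
    labels = dataset.labels
    n_classes = dataset.n_classes
    y_onehot = one_hot(labels, n_classes)

    from .evaluation import SplitProtocol
    protocol = SplitProtocol(
        test_fraction=config.split.test_fraction,
        n_repeats=config.split.n_repeats,
        stratified=config.split.stratified,
        base_seed=config.split.base_seed or config.seed,
    )
    splits = make_splits(labels, protocol)

    reports: dict[str, list[EvalReport]] = {arm: [] for arm in ARMS}
    for r, (train_idx, test_idx) in enumerate(splits):
        rep_dir = run_dir / f"repeat_{r}"
        rep_dir.mkdir(exist_ok=True)
        fit_idx, val_idx = _carve_validation(train_idx, labels,
                                             seed=config.seed + 50 + r)

        teacher = None
        if config.train_teacher:
            t_spec = _model_spec("teacher", config.teacher,
                                 teacher_x.shape[1:], n_classes)
            teacher = build_model(t_spec, seed=config.seed + _SEED_TEACHER + r)
            history = run_single_arm(teacher, teacher_x, y_onehot, fit_idx,
                                     val_idx, config,
                                     seed=config.seed + _SEED_TEACHER + r)
            write_history_csv(history, rep_dir / "history_teacher.csv")
            _evaluate_and_write(teacher, teacher_x, labels, test_idx, n_classes,
                                dataset.class_names, rep_dir, "teacher",
                                reports, r)

        s_spec = _model_spec("student", config.student, student_x.shape[1:],
                             n_classes)
        student = build_model(s_spec, seed=config.seed + _SEED_STUDENT + r)
        history = run_single_arm(student, student_x, y_onehot, fit_idx, val_idx,
                                 config, seed=config.seed + _SEED_STUDENT + r)
        write_history_csv(history, rep_dir / "history_student_no_kd.csv")
        _evaluate_and_write(student, student_x, labels, test_idx, n_classes,
                            dataset.class_names, rep_dir, "student_no_kd",
                            reports, r)

        if config.kd:
            checksum_before = weights_checksum(teacher)
            from .nn import TrainConfig
            train_cfg = TrainConfig(
                batch_size=config.train.batch_size,
                max_epochs=config.train.max_epochs, lr=config.train.lr,
                patience=config.train.patience,
                seed=config.seed + _SEED_DISTILL + r)
            kd_student, history = train_with_distillation(
                teacher, s_spec, student_x[fit_idx], y_onehot[fit_idx],
                student_x[val_idx], y_onehot[val_idx], config.distill,
                train_cfg, teacher_inputs=teacher_x[fit_idx])
            assert weights_checksum(teacher) == checksum_before
            write_history_csv(history, rep_dir / "history_student_kd.csv")
            _evaluate_and_write(kd_student, student_x, labels, test_idx,
                                n_classes, dataset.class_names, rep_dir,
                                "student_kd", reports, r)

    summaries = {}
    for arm, arm_reports in reports.items():
        if not arm_reports:
            continue
        summary = aggregate_repeats(arm_reports)
        summaries[arm] = summary
        write_summary_csv(summary, arm, run_dir / f"summary_{arm}.csv")

    _write_manifest(config, run_dir)
    return summaries


def _evaluate_and_write(model, x, labels, test_idx, n_classes, class_names,
                        rep_dir: Path, arm: str, reports, split_id: int) -> None:
    probs = softmax(model.predict_logits(x[test_idx]))
    report = evaluate_probs(labels[test_idx], probs, n_classes, split_id)
    reports[arm].append(report)
    write_per_class_csv(report, class_names, rep_dir / f"per_class_{arm}.csv")
    write_confusion_json(report, class_names, rep_dir / f"confusion_{arm}.json")
    for k in range(n_classes):
        if 0 < np.sum(labels[test_idx] == k) < len(test_idx):
            write_roc_points_csv(labels[test_idx], probs, k,
                                 rep_dir / f"roc_{arm}_class{k}.csv")


def _write_manifest(config: RunConfig, run_dir: Path) -> None:
    import pandas
    import scipy

    cfg_dict = config_to_dict(config)
    cfg_json = json.dumps(cfg_dict, sort_keys=True, default=str)
    manifest = {
        "config": cfg_dict,
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
        "seed": config.seed,
        "versions": {
            "quanvkd": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
        },
    }
    (run_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=str))
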
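"""Run configuration: defaults, validation, and YAML loading.

A :class:`RunConfig` bundles every stage's settings.  Defaults are the
pipeline's configured hyperparameters: batch size 8, up to 100 epochs with
early stopping, Adam at learning rate 1e-3, dropout 0.5, distillation
temperature 5 with alpha 0.5, teacher/student Conv2D filter pairs 128/256
and 64/128, and the imbalanced 4-class phantom proportions.

:func:`validate_config` fills defaults into a raw mapping, rejects unknown
keys with a closest-match suggestion, and reports *all* violations at once.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import yaml

from .distillation import DistillConfig
from .evaluation import SplitProtocol
from .nn import TrainConfig
from .preprocess import PreprocessConfig
from .qsim import PQCParams
from .synthetic import DEFAULT_PROPORTIONS, PhantomSpec

__all__ = ["RunConfig", "ModelOverrides", "validate_config", "load_config"]


@dataclass(frozen=True)
class ModelOverrides:
    """Optional architecture overrides for one role (None keeps defaults)."""

    conv_filters: tuple[int, int] | None = None
    dense_units: int = 64
    dropout_rate: float = 0.5


@dataclass(frozen=True)
class RunConfig:
    """Everything one end-to-end experiment needs."""

    seed: int = 0
    n_total: int = 1600
    rebalance_targets: tuple[int, ...] | None = None
    kd: bool = True
    train_teacher: bool = True
    teacher_on_quantum_features: bool = False
    out_dir: str = "runs/experiment"
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    pqc: PQCParams = field(default_factory=PQCParams)
    teacher: ModelOverrides = field(default_factory=ModelOverrides)
    student: ModelOverrides = field(default_factory=ModelOverrides)
    distill: DistillConfig = field(default_factory=DistillConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    split: SplitProtocol = field(default_factory=SplitProtocol)

    def __post_init__(self) -> None:
        if self.kd and not self.train_teacher:
            raise ValueError(
                "knowledge distillation requested (kd=true) but the teacher "
                "stage is disabled (train_teacher=false); distillation "
                "depends on a trained teacher"
            )


_SECTIONS: dict[str, type] = {
    "phantom": PhantomSpec,
    "preprocess": PreprocessConfig,
    "pqc": PQCParams,
    "teacher": ModelOverrides,
    "student": ModelOverrides,
    "distill": DistillConfig,
    "train": TrainConfig,
    "split": SplitProtocol,
}

_TOP_SCALARS = ("seed", "n_total", "rebalance_targets", "kd", "train_teacher",
                "teacher_on_quantum_features", "out_dir")

_TUPLE_KEYS = {"class_proportions", "conv_filters", "rebalance_targets"}


def _suggest(key: str, known: list[str]) -> str:
    close = difflib.get_close_matches(key, known, n=1)
    return f"unknown key {key!r}" + (f"; did you mean {close[0]!r}?" if close else "")


def validate_config(raw: Mapping[str, Any]) -> RunConfig:
    """Build a :class:`RunConfig` from a raw mapping.

    Missing keys take defaults; unknown keys are rejected with a suggestion;
    every type/range violation found is reported in a single error.
    """
    errors: list[str] = []
    known_top = list(_TOP_SCALARS) + list(_SECTIONS)
    top_kwargs: dict[str, Any] = {}
    section_kwargs: dict[str, dict[str, Any]] = {name: {} for name in _SECTIONS}

    for key, value in dict(raw).items():
        if key in _SECTIONS:
            cls = _SECTIONS[key]
            known_fields = [f.name for f in fields(cls)]
            if not isinstance(value, Mapping):
                errors.append(f"section {key!r} must be a mapping")
                continue
            for sub_key, sub_value in value.items():
                if sub_key not in known_fields:
                    errors.append(f"in section {key!r}: "
                                  + _suggest(sub_key, known_fields))
                    continue
                if sub_key in _TUPLE_KEYS and sub_value is not None:
                    sub_value = tuple(sub_value)
                section_kwargs[key][sub_key] = sub_value
        elif key in _TOP_SCALARS:
            if key in _TUPLE_KEYS and value is not None:
                value = tuple(value)
            top_kwargs[key] = value
        else:
            errors.append(_suggest(key, known_top))

    sections: dict[str, Any] = {}
    for name, cls in _SECTIONS.items():
        try:
            sections[name] = cls(**section_kwargs[name])
        except (TypeError, ValueError) as exc:
            errors.append(f"in section {name!r}: {exc}")

    config = None
    if not errors:
        try:
            config = RunConfig(**top_kwargs, **sections)
        except (TypeError, ValueError) as exc:
            errors.append(str(exc))
    if errors:
        raise ValueError("invalid configuration:\n  - " + "\n  - ".join(errors))
    return config


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML configuration file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return validate_config(raw)


def config_to_dict(config: RunConfig) -> dict:
    """JSON-serializable mirror of a run configuration (for the manifest)."""
    from dataclasses import asdict

    out = asdict(config)
    out["pqc"] = config.pqc.to_dict()
    return out
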
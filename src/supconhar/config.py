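"""Run configuration: serializable description of a full reproducible run.

A ``RunConfig`` captures everything a run needs — dataset source, window
preprocessing, user split, architecture, augmentation policy and training
settings — and round-trips losslessly through YAML. Unknown keys are hard
errors: silently ignoring a typo would break reproducibility.

Named presets encode the published per-dataset training settings (learning
rate, projection hidden size 256, batch 256, temperature 0.1, epochs with
early-stopping patience 30, auxiliary weight) for the three public-corpus
profiles, plus a ``synthetic`` preset that scales the same recipe down to
the bundled desk-scale generator (smaller encoder, batch 128, short
epoch budget) so the full ablation harness runs on one CPU in minutes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .augment import AugmentationPolicy
from .model import ArchitectureConfig
from .prep import SplitSpec
from .synth import SyntheticSpec
from .trainer import TrainConfig

__all__ = ["RunConfig", "PRESETS", "preset", "load_config", "save_config"]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class PrepOptions:
    target_rate: float = 50.0
    window_seconds: float = 1.0
    overlap: float = 0.5
    standardize: bool = True


@dataclass(frozen=True)
class DataSource:
    """Either a synthetic spec or a dataset file with its format."""

    kind: str = "synthetic"  # synthetic | long_csv | packed
    path: str | None = None
    synthetic: SyntheticSpec = field(default_factory=SyntheticSpec)

    def __post_init__(self) -> None:
        if self.kind not in ("synthetic", "long_csv", "packed"):
            raise ValueError(f"unknown dataset kind {self.kind!r}")
        if self.kind != "synthetic" and not self.path:
            raise ValueError(f"dataset kind {self.kind!r} requires a path")


@dataclass(frozen=True)
class RunConfig:
    schema_version: int = SCHEMA_VERSION
    data: DataSource = field(default_factory=DataSource)
    prep: PrepOptions = field(default_factory=PrepOptions)
    split: SplitSpec = field(default_factory=SplitSpec)
    arch: ArchitectureConfig = field(
        default_factory=lambda: ArchitectureConfig(in_channels=6, n_classes=6))
    policy: AugmentationPolicy = field(default_factory=AugmentationPolicy)
    train: TrainConfig = field(default_factory=TrainConfig)
    out_dir: str = "runs"
    log_level: str = "INFO"


def _from_dict(cls, data: dict):
    if not isinstance(data, dict):
        raise TypeError(f"expected mapping for {cls.__name__}, got {type(data).__name__}")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        target = _NESTED.get((cls, name))
        if target is not None and value is not None:
            kwargs[name] = _from_dict(target, value)
        elif name in _TUPLE_FIELDS.get(cls, ()) and value is not None:
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


_NESTED = {
    (RunConfig, "data"): DataSource,
    (RunConfig, "prep"): PrepOptions,
    (RunConfig, "split"): SplitSpec,
    (RunConfig, "arch"): ArchitectureConfig,
    (RunConfig, "policy"): AugmentationPolicy,
    (RunConfig, "train"): TrainConfig,
    (DataSource, "synthetic"): SyntheticSpec,
}

_TUPLE_FIELDS = {
    SplitSpec: ("fractions",),
    ArchitectureConfig: ("block_filters", "classifier_hidden"),
    AugmentationPolicy: ("enabled_ops",),
}


def run_config_from_dict(data: dict) -> RunConfig:
    version = data.get("schema_version", None)
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"config schema_version {version!r} unsupported (expected {SCHEMA_VERSION})")
    return _from_dict(RunConfig, data)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as f:
        return run_config_from_dict(yaml.safe_load(f))


def save_config(cfg: RunConfig, path: str | Path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(asdict(cfg), f, sort_keys=False)


def _published(alpha: float, epochs: int, lam: float, in_channels: int,
               n_classes: int) -> RunConfig:
    return RunConfig(
        arch=ArchitectureConfig(in_channels=in_channels, n_classes=n_classes,
                                projector_hidden=256),
        train=TrainConfig(learning_rate=alpha, batch_size=256, tau=0.1,
                          max_epochs=epochs, early_stop_patience=30, lam=lam),
    )


def preset(name: str, **overrides) -> RunConfig:
    """A named RunConfig preset; overrides replace top-level fields."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return dataclasses.replace(PRESETS[name](), **overrides)


PRESETS = {
    # published per-dataset training settings
    "mobiact": lambda: _published(3e-4, 200, 0.2, in_channels=6, n_classes=11),
    "ucihar": lambda: _published(3e-4, 100, 0.4, in_channels=6, n_classes=6),
    "uschad": lambda: _published(1e-4, 200, 0.3, in_channels=6, n_classes=12),
    # desk-scale recipe for the bundled synthetic generator
    "synthetic": lambda: RunConfig(
        arch=ArchitectureConfig(in_channels=6, n_classes=6,
                                block_filters=(16, 32, 32),
                                projector_hidden=64, projector_out=32,
                                classifier_hidden=(64, 32)),
        train=TrainConfig(learning_rate=2e-3, batch_size=128, tau=0.1, lam=0.3,
                          max_epochs=20, early_stop_patience=20,
                          pretrain_epochs=20, finetune_epochs=20),
    ),
}
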
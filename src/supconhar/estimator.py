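"""Model-object front end: construct from windows, ``fit()``, inspect results.

`MultiTaskSupConHAR` wraps the full pipeline the way statistical modelling
packages expose an estimator: build the model object from a prepared
`WindowSet` (or long-format DataFrame) plus configuration, call ``fit()``,
and receive a `HARResults` carrying the trained networks, the training
history, the held-out evaluation report and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .augment import AugmentationPolicy
from .model import ArchitectureConfig, ModelBundle, build_model, count_parameters, predict
from .prep import (
    SensorRecording,
    SplitSpec,
    WindowSet,
    apply_standardizer,
    concat_window_sets,
    fit_standardizer,
    make_windows,
    split_by_users,
)
from .trainer import (
    EvalReport,
    TrainConfig,
    TrainHistory,
    evaluate,
    train_multitask,
    train_two_stage,
)

__all__ = ["MultiTaskSupConHAR", "HARResults"]


class MultiTaskSupConHAR:
    """Joint activity-classification + user-aware contrastive model.

    Parameters
    ----------
    windows : WindowSet
        Labeled windows (activity + user) for all available users.
    arch, train_config, policy
        Architecture, optimization and augmentation settings; defaults give
        the desk-scale recipe sized to the window set's channels/classes.
    split : SplitSpec
        User-disjoint split used by ``fit``; evaluation is on unseen users.
    standardize : bool
        Standardize channels with train-user statistics (default on).
    """

    def __init__(
        self,
        windows: WindowSet,
        arch: ArchitectureConfig | None = None,
        train_config: TrainConfig | None = None,
        policy: AugmentationPolicy | None = None,
        split: SplitSpec | None = None,
        standardize: bool = True,
    ):
        self.windows = windows
        self.arch = arch or ArchitectureConfig(
            in_channels=windows.X.shape[1], n_classes=windows.n_classes,
            block_filters=(16, 32, 32), projector_hidden=64, projector_out=32,
            classifier_hidden=(64, 32))
        self.train_config = train_config or TrainConfig()
        self.policy = policy or AugmentationPolicy()
        self.split = split or SplitSpec()
        self.standardize = standardize

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, sampling_rate: float,
        window_seconds: float = 1.0, overlap: float = 0.5, **kwargs
    ) -> "MultiTaskSupConHAR":
        """Build from a long-format frame (columns user, activity, t, ch0..chK)."""
        chans = [c for c in df.columns if c.startswith("ch")]
        n_classes = int(df["activity"].max()) + 1
        sets = []
        for (user, act), grp in df.groupby(["user", "activity"], sort=False):
            rec = SensorRecording(grp[chans].to_numpy().T, sampling_rate,
                                  user_id=str(user), activity_label=int(act))
            sets.append(make_windows(rec, window_seconds, overlap, n_classes=n_classes))
        return cls(concat_window_sets(sets), **kwargs)

    def fit(self, seed: int | None = None) -> "HARResults":
        """Split by users, train per the configured mode, evaluate on test users."""
        cfg = self.train_config if seed is None else replace(self.train_config, seed=seed)
        split = self.split if seed is None else replace(self.split, seed=seed)
        train, val, test = split_by_users(self.windows, split)
        stats = None
        if self.standardize:
            stats = fit_standardizer(train)
            train = apply_standardizer(train, stats)
            val = apply_standardizer(val, stats)
            test = apply_standardizer(test, stats)
        bundle = build_model(self.arch, seed=cfg.seed)
        if cfg.mode == "two_stage":
            bundle, history = train_two_stage(bundle, train, val, cfg, self.policy)
        else:
            bundle, history = train_multitask(bundle, train, val, cfg, self.policy)
        report = evaluate(bundle, test, self.windows.n_classes)
        return HARResults(self, bundle, history, report, stats,
                          test_users=sorted(set(test.y_user.astype(str))))


class HARResults:
    """Fitted model, training history and unseen-user evaluation report."""

    def __init__(self, model: MultiTaskSupConHAR, bundle: ModelBundle,
                 history: TrainHistory, report: EvalReport,
                 standardizer: tuple[np.ndarray, np.ndarray] | None,
                 test_users: list[str]):
        self.model = model
        self.bundle = bundle
        self.history = history
        self.report = report
        self.standardizer = standardizer
        self.test_users = test_users

    @property
    def macro_f1(self) -> float:
        return self.report.macro_f1

    def predict(self, windows: WindowSet) -> np.ndarray:
        """Activity labels for new raw windows (train-stats standardization)."""
        if self.standardizer is not None:
            windows = apply_standardizer(windows, self.standardizer)
        return predict(self.bundle, windows)

    def summary(self) -> str:
        cfg = self.model.train_config
        counts = count_parameters(self.bundle)
        lines = [
            "Multi-task supervised contrastive HAR — fit summary",
            "=" * 55,
            f"mode: {cfg.mode}   strategy: {cfg.strategy}   "
            f"lambda: {cfg.lam}   tau: {cfg.tau}",
            f"parameters: encoder {counts['encoder']:,}  projector "
            f"{counts['projector']:,}  classifier {counts['classifier']:,}  "
            f"total {counts['total']:,}",
            f"epochs run: {len(self.history.l_ce)}  best epoch: "
            f"{self.history.best_epoch}  ({self.history.stopping_reason})",
            f"held-out (unseen) test users: {', '.join(self.test_users)}",
            "",
            str(self.report),
        ]
        return "\n".join(lines)
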
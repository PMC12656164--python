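"""Windowing, resampling, standardization and user-disjoint splitting.

Converts continuous multichannel inertial recordings into the fixed-length
labeled windows the model consumes, and builds the user-disjoint splits used
to measure generalization to unseen people: fractional splits over the user
roster (default 60/20/20) and leave-one-subject-out (LOSO) folds.

Windows use 0-based, half-open ``[start, start + L)`` intervals throughout.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterator, Sequence

import numpy as np
from scipy.signal import resample_poly

logger = logging.getLogger(__name__)

__all__ = [
    "SensorRecording",
    "Window",
    "WindowSet",
    "SplitSpec",
    "resample",
    "make_windows",
    "concat_window_sets",
    "split_by_users",
    "loso_splits",
    "fit_standardizer",
    "apply_standardizer",
]


@dataclass(frozen=True)
class SensorRecording:
    """One user's continuous multichannel stream with a single activity label.

    ``values`` is a (channels, timesteps) array in native sensor units
    (m/s^2 for accelerometer axes, rad/s for gyroscope axes).
    """

    values: np.ndarray
    sampling_rate: float
    user_id: str
    activity_label: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[1] < 1:
            raise ValueError("values must be a (channels, timesteps>=1) matrix")
        if not np.all(np.isfinite(v)):
            raise ValueError("recording contains NaN or Inf values")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        object.__setattr__(self, "values", v)

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_timesteps(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class Window:
    """A fixed-length labeled segment: the model's unit sample."""

    x: np.ndarray  # (channels, L)
    y_act: int
    y_user: str
    start: int  # 0-based offset into the source recording


@dataclass
class WindowSet:
    """Ordered collection of labeled windows stored as packed arrays.

    ``X`` has shape (N, channels, L); ``y_act`` holds integer activity labels
    in ``[0, n_classes)``; ``y_user`` holds opaque user identifiers.
    """

    X: np.ndarray
    y_act: np.ndarray
    y_user: np.ndarray
    n_classes: int
    sampling_rate: float
    starts: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y_act = np.asarray(self.y_act, dtype=np.int64)
        self.y_user = np.asarray(self.y_user)
        if self.X.ndim != 3:
            raise ValueError("X must have shape (N, channels, L)")
        n = len(self.X)
        if len(self.y_act) != n or len(self.y_user) != n:
            raise ValueError("label vectors must align with X")
        if n and (self.y_act.min() < 0 or self.y_act.max() >= self.n_classes):
            raise ValueError("activity labels must lie in [0, n_classes)")
        if self.starts is None:
            self.starts = np.zeros(n, dtype=np.int64)
        else:
            self.starts = np.asarray(self.starts, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.X)

    def __getitem__(self, i: int) -> Window:
        return Window(self.X[i], int(self.y_act[i]), str(self.y_user[i]), int(self.starts[i]))

    @property
    def users(self) -> np.ndarray:
        """Sorted roster of distinct user identifiers."""
        return np.unique(self.y_user)

    def subset(self, idx: np.ndarray) -> "WindowSet":
        return WindowSet(
            self.X[idx], self.y_act[idx], self.y_user[idx],
            n_classes=self.n_classes, sampling_rate=self.sampling_rate,
            starts=self.starts[idx],
        )


@dataclass(frozen=True)
class SplitSpec:
    """How to split a WindowSet over its USER roster (never over windows)."""

    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0
    mode: str = "fractional"  # "fractional" | "loso"

    def __post_init__(self) -> None:
        if self.mode not in ("fractional", "loso"):
            raise ValueError(f"unknown split mode {self.mode!r}")
        if self.mode == "fractional":
            if abs(sum(self.fractions) - 1.0) > 1e-9:
                raise ValueError("fractions must sum to 1")
            if any(f <= 0 for f in self.fractions):
                raise ValueError("every fraction must be > 0 in fractional mode")


def resample(rec: SensorRecording, target_rate: float) -> SensorRecording:
    """Anti-aliased downsampling to ``target_rate`` (polyphase filtering).

    Upsampling is refused: windows are defined at or below the native rate.
    Output length is ``floor(T * target_rate / input_rate)``.
    """
    if target_rate > rec.sampling_rate:
        raise ValueError(
            f"upsampling {rec.sampling_rate} Hz -> {target_rate} Hz is not supported"
        )
    if target_rate == rec.sampling_rate:
        return rec
    ratio = Fraction(target_rate / rec.sampling_rate).limit_denominator(1000)
    out = resample_poly(rec.values, ratio.numerator, ratio.denominator, axis=1)
    n_out = int(np.floor(rec.n_timesteps * target_rate / rec.sampling_rate))
    out = out[:, :n_out]
    return SensorRecording(out, target_rate, rec.user_id, rec.activity_label)


def make_windows(
    rec: SensorRecording,
    window_seconds: float = 1.0,
    overlap: float = 0.5,
    n_classes: int | None = None,
) -> WindowSet:
    """Slice a recording into fixed windows with fractional overlap.

    Window length ``L = round(rate * window_seconds)``; stride
    ``L * (1 - overlap)`` (rounded, floored at 1). A trailing partial window
    is dropped. Each window inherits the recording's labels.
    """
    if not 0 <= overlap < 1:
        raise ValueError("overlap must lie in [0, 1)")
    L = int(round(rec.sampling_rate * window_seconds))
    if L < 1:
        raise ValueError("window shorter than one sample")
    C = n_classes if n_classes is not None else rec.activity_label + 1
    T = rec.n_timesteps
    if T < L:
        warnings.warn(
            f"recording of {T} samples shorter than window of {L}; returning empty set"
        )
        empty = np.empty((0, rec.n_channels, L))
        return WindowSet(empty, [], np.array([], dtype=object),
                         n_classes=C, sampling_rate=rec.sampling_rate)
    stride = max(1, int(round(L * (1.0 - overlap))))
    starts = np.arange(0, T - L + 1, stride, dtype=np.int64)
    X = np.stack([rec.values[:, s:s + L] for s in starts])
    y_act = np.full(len(starts), rec.activity_label, dtype=np.int64)
    y_user = np.full(len(starts), rec.user_id, dtype=object)
    return WindowSet(X, y_act, y_user, n_classes=C,
                     sampling_rate=rec.sampling_rate, starts=starts)


def concat_window_sets(sets: Sequence[WindowSet]) -> WindowSet:
    """Concatenate window sets sharing channel count, length and rate."""
    sets = [s for s in sets if len(s)]
    if not sets:
        raise ValueError("nothing to concatenate")
    C = max(s.n_classes for s in sets)
    rate = sets[0].sampling_rate
    return WindowSet(
        np.concatenate([s.X for s in sets]),
        np.concatenate([s.y_act for s in sets]),
        np.concatenate([s.y_user for s in sets]),
        n_classes=C, sampling_rate=rate,
        starts=np.concatenate([s.starts for s in sets]),
    )


def _largest_remainder_counts(n_users: int, fractions: Sequence[float]) -> list[int]:
    quotas = [n_users * f for f in fractions]
    counts = [int(np.floor(q)) for q in quotas]
    # hand out the remaining seats to the largest fractional remainders;
    # ties go to the earlier split so train is never starved
    remainders = sorted(
        range(len(quotas)), key=lambda i: (-(quotas[i] - counts[i]), i)
    )
    for i in remainders[: n_users - sum(counts)]:
        counts[i] += 1
    # every split must be non-empty when its fraction is positive
    for i, c in enumerate(counts):
        if c == 0:
            donor = int(np.argmax(counts))
            counts[donor] -= 1
            counts[i] += 1
    return counts


def split_by_users(
    ws: WindowSet, spec: SplitSpec
) -> tuple[WindowSet, WindowSet, WindowSet]:
    """Partition by USER roster into (train, val, test) with disjoint users.

    User counts follow largest-remainder rounding of the fractions applied to
    the roster size; the roster is shuffled by ``spec.seed``.
    """
    if spec.mode != "fractional":
        raise ValueError("split_by_users requires a fractional SplitSpec")
    roster = ws.users
    if len(roster) < 3:
        raise ValueError("fractional split requires at least 3 users")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(roster))
    shuffled = roster[order]
    n_tr, n_va, n_te = _largest_remainder_counts(len(roster), spec.fractions)
    tr_users = set(shuffled[:n_tr].tolist())
    va_users = set(shuffled[n_tr:n_tr + n_va].tolist())
    te_users = set(shuffled[n_tr + n_va:].tolist())
    assert not (tr_users & va_users or tr_users & te_users or va_users & te_users)
    parts = []
    for users in (tr_users, va_users, te_users):
        idx = np.flatnonzero(np.isin(ws.y_user.astype(str), sorted(users)))
        parts.append(ws.subset(idx))
    return tuple(parts)  # type: ignore[return-value]


def loso_splits(ws: WindowSet) -> Iterator[tuple[WindowSet, WindowSet]]:
    """Leave-one-subject-out folds, ordered by sorted user id.

    Each fold tests on one user's windows and trains on everyone else's.
    """
    roster = ws.users
    if len(roster) < 2:
        raise ValueError("LOSO requires at least 2 users")
    y_user = ws.y_user.astype(str)
    for user in roster:
        test_idx = np.flatnonzero(y_user == str(user))
        train_idx = np.flatnonzero(y_user != str(user))
        yield ws.subset(train_idx), ws.subset(test_idx)


def fit_standardizer(train: WindowSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel mean and sd over all train timesteps (sd floored at 1e-8)."""
    mean = train.X.mean(axis=(0, 2))
    sd = np.maximum(train.X.std(axis=(0, 2)), 1e-8)
    return mean, sd


def apply_standardizer(
    ws: WindowSet, stats: tuple[np.ndarray, np.ndarray]
) -> WindowSet:
    """Standardize channels with TRAIN statistics only (no leakage)."""
    mean, sd = stats
    X = (ws.X - mean[None, :, None]) / sd[None, :, None]
    return WindowSet(X, ws.y_act, ws.y_user, n_classes=ws.n_classes,
                     sampling_rate=ws.sampling_rate, starts=ws.starts)
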
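"""Stochastic time-series augmentations and two-view generation.

Five label-free transforms standard in contrastive learning on inertial
signals: jittering (additive Gaussian noise, always applied), scaling
(per-channel random gain), channel shuffle, rotation (per-channel random sign
flip) and permutation (shuffling contiguous time segments). ``two_views``
draws two independent passes through the pipeline, yielding the paired views
the contrastive branch consumes.

Every op preserves shape and finiteness and never reads labels. Ops compose
in a fixed order (scaling, channel shuffle, rotation, permutation, after the
jitter base) so a run is a deterministic function of the policy and the RNG
state.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "AugmentationPolicy",
    "jitter",
    "scaling",
    "channel_shuffle",
    "rotation",
    "permutation",
    "apply_policy",
    "two_views",
]

_ALL_OPS = ("scaling", "channel_shuffle", "rotation", "permutation")


@dataclass(frozen=True)
class AugmentationPolicy:
    """Which ops run, their parameters, and the per-op gate probability.

    Jitter is the base augmentation: always applied (probability fixed at 1).
    The other enabled ops each fire independently with probability ``p``.
    Defaults follow common practice for contrastive learning on standardized
    inertial signals: jitter sd 0.05, scale sd 0.1, 4 segments, p = 0.5.
    """

    jitter_sd: float = 0.05
    scale_sd: float = 0.1
    perm_segments: int = 4
    p: float = 0.5
    enabled_ops: tuple[str, ...] = _ALL_OPS
    per_channel: bool = True  # draw scaling/rotation factors per channel

    def __post_init__(self) -> None:
        if not 0 <= self.p <= 1:
            raise ValueError("p must lie in [0, 1]")
        if self.jitter_sd < 0 or self.scale_sd < 0:
            raise ValueError("noise/scale sds must be >= 0")
        if self.perm_segments < 2:
            raise ValueError("perm_segments must be >= 2")
        unknown = set(self.enabled_ops) - set(_ALL_OPS)
        if unknown:
            raise ValueError(f"unknown ops: {sorted(unknown)}")


def jitter(x: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Add elementwise Gaussian noise N(0, sd^2)."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        return x.copy()
    return x + rng.normal(0.0, sd, x.shape)


def scaling(
    x: np.ndarray, sd: float, rng: np.random.Generator, per_channel: bool = True
) -> np.ndarray:
    """Multiply by a random gain s ~ N(1, sd^2), one draw per channel."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if per_channel:
        s = rng.normal(1.0, sd, (x.shape[0], 1))
    else:
        s = rng.normal(1.0, sd)
    return x * s


def channel_shuffle(x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Randomly permute the channel axis."""
    if x.shape[0] == 1:
        logger.debug("channel_shuffle on single-channel input is the identity")
        return x.copy()
    return x[rng.permutation(x.shape[0])]


def rotation(
    x: np.ndarray, rng: np.random.Generator, per_channel: bool = True
) -> np.ndarray:
    """Randomly invert signs: x' = sigma * x with sigma in {-1, +1}."""
    if per_channel:
        sigma = rng.choice([-1.0, 1.0], (x.shape[0], 1))
    else:
        sigma = rng.choice([-1.0, 1.0])
    return x * sigma


def _segment_bounds(L: int, n_seg: int) -> np.ndarray:
    """Cut points for n_seg near-equal contiguous segments (longer first)."""
    lengths = np.full(n_seg, L // n_seg, dtype=np.int64)
    lengths[: L % n_seg] += 1
    return np.concatenate([[0], np.cumsum(lengths)])


def permutation(x: np.ndarray, n_seg: int, rng: np.random.Generator) -> np.ndarray:
    """Cut the time axis into segments and shuffle their order (all channels jointly)."""
    L = x.shape[1]
    if n_seg > L:
        raise ValueError(f"n_seg={n_seg} exceeds window length {L}")
    if n_seg == 1:
        return x.copy()
    bounds = _segment_bounds(L, n_seg)
    order = rng.permutation(n_seg)
    return np.concatenate([x[:, bounds[i]:bounds[i + 1]] for i in order], axis=1)


def apply_policy(
    x: np.ndarray, policy: AugmentationPolicy, rng: np.random.Generator
) -> np.ndarray:
    """One stochastic pass: jitter always, then each enabled op with prob p."""
    out = jitter(x, policy.jitter_sd, rng)
    for op in _ALL_OPS:
        if op not in policy.enabled_ops:
            continue
        if rng.random() >= policy.p:
            continue
        if op == "scaling":
            out = scaling(out, policy.scale_sd, rng, policy.per_channel)
        elif op == "channel_shuffle":
            out = channel_shuffle(out, rng)
        elif op == "rotation":
            out = rotation(out, rng, policy.per_channel)
        elif op == "permutation":
            out = permutation(out, policy.perm_segments, rng)
    return out


def two_views(
    x: np.ndarray, policy: AugmentationPolicy, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Two independent augmented views of the same window."""
    return apply_policy(x, policy, rng), apply_policy(x, policy, rng)
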
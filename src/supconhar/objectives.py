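"""Contrastive pair-mask construction and all training losses.

The user-aware hard-negative strategy is the heart of the method. For an
anchor embedding with activity label ``y_act`` and user label ``y_user``:

* positives are samples with the SAME activity from a DIFFERENT user — they
  pull the representation toward user-invariant activity structure;
* hard negatives are samples from the SAME user with a DIFFERENT activity —
  they push apart the user-specific shortcut features a classifier would
  otherwise exploit.

Three strategies are supported: ``instance`` (sibling augmented view is the
only positive, all others candidates — the NT-Xent/SimCLR convention),
``activity`` (label-defined positives, all off-diagonal candidates — the
standard SupCon convention), and ``activity_user_hard`` (the strategy above,
with the candidate set restricted to positives plus same-user hard
negatives). The losses are computed on l2-normalized embeddings with a
temperature-scaled dot-product similarity:

    L = sum_i -1/|P(i)| sum_{p in P(i)} log exp(z_i.z_p/tau)
                                          / sum_{a in A(i)} exp(z_i.z_a/tau)

Anchors with an empty positive set are skipped (the formula is undefined
there); the reduction is the mean over valid anchors by default so the
auxiliary weight stays comparable across batch sizes (``reduction="sum"``
recovers the plain summed form).

A deliberately naive triple-loop implementation (`brute_force_supcon`)
serves as the independent numerical oracle in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import autograd.numpy as anp
import numpy as np
from autograd.tracer import getval

__all__ = [
    "PairMask", "LossBreakdown", "sibling_view_map", "build_pair_mask",
    "supcon_loss", "xnent_loss", "cross_entropy", "total_loss",
    "brute_force_supcon",
]

STRATEGIES = ("instance", "activity", "activity_user_hard")


@dataclass(frozen=True)
class PairMask:
    """Per-batch boolean positive/candidate structure.

    ``pos[i, j]`` marks j as a positive of anchor i; ``cand[i, j]`` marks j
    as in the denominator set A(i). Invariants: false diagonals, pos a
    subset of cand, both symmetric; ``anchor_valid[i]`` iff P(i) is
    non-empty.
    """

    pos: np.ndarray
    cand: np.ndarray
    strategy: str
    view_map: np.ndarray | None
    anchor_valid: np.ndarray

    @property
    def n(self) -> int:
        return len(self.pos)


def sibling_view_map(n_rows: int) -> np.ndarray:
    """View map for a stacked two-view batch [views1; views2] of 2B rows."""
    if n_rows % 2:
        raise ValueError("stacked view batch must have an even row count")
    b = n_rows // 2
    return np.concatenate([np.arange(b) + b, np.arange(b)])


def build_pair_mask(
    y_act: np.ndarray,
    y_user: np.ndarray,
    view_map: np.ndarray | None,
    strategy: str,
    strict_positives: bool = True,
    restrict_denominator: bool = True,
) -> PairMask:
    """Construct the positive/candidate masks for one batch of embeddings.

    ``strict_positives`` and ``restrict_denominator`` only affect the
    ``activity_user_hard`` strategy: relaxing the former re-admits same-user
    same-activity rows (the sibling view included) as positives; relaxing
    the latter widens A(i) to all off-diagonal rows, the standard SupCon
    denominator.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")
    y_act = np.asarray(y_act)
    y_user = np.asarray(y_user)
    n = len(y_act)
    if len(y_user) != n:
        raise ValueError("y_act and y_user must have the same length")
    off_diag = ~np.eye(n, dtype=bool)
    same_act = (y_act[:, None] == y_act[None, :])
    same_user = (y_user[:, None] == y_user[None, :])

    if strategy == "instance":
        if view_map is None:
            raise ValueError("instance strategy requires a view_map")
        view_map = np.asarray(view_map)
        pos = np.zeros((n, n), dtype=bool)
        pos[np.arange(n), view_map] = True
        cand = off_diag.copy()
    elif strategy == "activity":
        pos = same_act & off_diag
        cand = off_diag.copy()
    else:  # activity_user_hard
        if strict_positives:
            pos = same_act & ~same_user
        else:
            pos = same_act & off_diag
        if restrict_denominator:
            hard_neg = same_user & ~same_act
            cand = pos | hard_neg
        else:
            cand = off_diag.copy()
    pos &= off_diag
    cand &= off_diag
    cand |= pos  # pos must always be a subset of cand
    return PairMask(pos=pos, cand=cand, strategy=strategy,
                    view_map=None if view_map is None else np.asarray(view_map),
                    anchor_valid=pos.any(axis=1))


def supcon_loss(Z, mask: PairMask, tau: float, reduction: str = "mean"):
    """Supervised contrastive loss over unit-norm embeddings.

    Vectorized and autograd-differentiable; numerically stabilized by
    per-anchor max subtraction inside the log-sum-exp. Anchors with empty
    P(i) contribute nothing and are excluded from the mean.
    """
    if tau <= 0:
        raise ValueError("temperature must be positive")
    if reduction not in ("mean", "sum"):
        raise ValueError("reduction must be 'mean' or 'sum'")
    valid = np.flatnonzero(mask.anchor_valid)
    if len(valid) == 0:
        raise ValueError(
            "no anchor in this batch has a positive pair; use the stratified "
            "sampler so every batch carries cross-user positives"
        )
    sims = anp.dot(Z[valid], anp.transpose(Z)) / tau
    pos = mask.pos[valid]
    cand = mask.cand[valid]
    m = np.where(cand, getval(sims), -np.inf).max(axis=1, keepdims=True)
    exps = anp.exp(sims - m) * cand
    log_denom = anp.log(anp.sum(exps, axis=1, keepdims=True))
    log_prob = sims - m - log_denom
    per_anchor = -anp.sum(pos * log_prob, axis=1) / pos.sum(axis=1)
    if reduction == "mean":
        return anp.mean(per_anchor)
    return anp.sum(per_anchor)


def xnent_loss(Z, view_map: np.ndarray, tau: float, reduction: str = "mean"):
    """NT-Xent: each anchor's only positive is its sibling augmented view.

    Exactly the supervised loss under the ``instance`` mask (every other
    row is a denominator candidate), asserted as an equivalence in tests.
    """
    n = len(view_map)
    if n % 2:
        raise ValueError("NT-Xent expects an even number of rows (two views)")
    mask = build_pair_mask(np.zeros(n, dtype=np.int64), np.zeros(n, dtype=np.int64),
                           view_map, strategy="instance")
    return supcon_loss(Z, mask, tau, reduction=reduction)


def cross_entropy(logits, y_act):
    """Mean over the batch of -log softmax probability of the true class."""
    y = np.asarray(y_act)
    m = getval(anp.max(logits, axis=1, keepdims=True))
    lse = anp.log(anp.sum(anp.exp(logits - m), axis=1)) + m[:, 0]
    true_logit = logits[anp.arange(len(y)), y]
    return anp.mean(lse - true_logit)


@dataclass(frozen=True)
class LossBreakdown:
    """The two loss terms and their weighted total L_CE + lambda * L_CL."""

    L_CE: float
    L_CL: float
    L_total: float
    lam: float
    tau: float | None = None
    n_valid_anchors: int = 0


def total_loss(L_CE, L_CL, lam: float, tau: float | None = None,
               n_valid_anchors: int = 0) -> LossBreakdown:
    if not 0 <= lam <= 1:
        raise ValueError("lambda must lie in [0, 1]")
    return LossBreakdown(
        L_CE=float(L_CE), L_CL=float(L_CL),
        L_total=float(L_CE) + lam * float(L_CL),
        lam=lam, tau=tau, n_valid_anchors=n_valid_anchors,
    )


def brute_force_supcon(Z: np.ndarray, mask: PairMask, tau: float,
                       reduction: str = "mean") -> float:
    """Reference triple-loop implementation over explicit (i, p, a) indices.

    No vectorization and no tricks beyond per-anchor max subtraction; used
    as the independent oracle for the vectorized loss.
    """
    Z = np.asarray(Z, dtype=np.float64)
    n = len(Z)
    losses = []
    for i in range(n):
        positives = [j for j in range(n) if mask.pos[i, j]]
        if not positives:
            continue
        candidates = [a for a in range(n) if mask.cand[i, a]]
        m = max(float(np.dot(Z[i], Z[a])) / tau for a in candidates)
        denom = 0.0
        for a in candidates:
            denom += math.exp(float(np.dot(Z[i], Z[a])) / tau - m)
        total = 0.0
        for p in positives:
            log_prob = (float(np.dot(Z[i], Z[p])) / tau - m) - math.log(denom)
            total += log_prob
        losses.append(-total / len(positives))
    if not losses:
        raise ValueError("no valid anchors")
    return float(np.mean(losses) if reduction == "mean" else np.sum(losses))
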
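"""Single-stage multi-task training, the two-stage baseline, and evaluation.

The multi-task step couples two branches through the shared encoder: the raw
windows feed the classifier (cross-entropy), while two augmented views of
the same windows feed the projection head (contrastive loss on the stacked
2B embeddings). All 3B windows pass through the encoder in one forward so
batch-norm statistics see both branches. Gradients route structurally:

    encoder   <- dL_CE + lambda * dL_CL
    classifier<- dL_CE only
    projector <- lambda * dL_CL only

because the classification loss never touches projector parameters and the
contrastive loss never touches classifier parameters. The optimizer steps
only the components the step's objective involves, so untouched components
stay bitwise at their previous values.

The two-stage protocol (the baseline the single-stage method replaces)
first optimizes the contrastive objective alone on encoder + projector,
then freezes the encoder and fits the classifier with cross-entropy on
cached features.

Evaluation uses raw windows only — no augmentation, no projector — and
reports per-class precision/recall/F1, macro-F1 (the primary metric),
weighted F1, accuracy and the confusion matrix.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd
from autograd import value_and_grad
from autograd.tracer import getval
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    f1_score,
    precision_recall_fscore_support,
)

from . import nn
from .augment import AugmentationPolicy, apply_policy
from .model import (
    ArchitectureConfig,
    ModelBundle,
    build_model,
    classifier_forward,
    encoder_forward,
    predict,
    projector_forward,
)
from .objectives import (
    build_pair_mask,
    cross_entropy,
    sibling_view_map,
    supcon_loss,
)
from .prep import SplitSpec, WindowSet, apply_standardizer, fit_standardizer, split_by_users

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig", "TrainHistory", "EvalReport", "train_multitask",
    "train_two_stage", "stratified_batches", "plain_batches", "macro_f1",
    "evaluate", "run_experiment",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings; presets for named dataset profiles live in config."""

    learning_rate: float = 1e-3
    weight_decay: float = 0.01
    batch_size: int = 128
    tau: float = 0.1
    lam: float = 0.3
    max_epochs: int = 30
    early_stop_patience: int = 30
    seed: int = 0
    strategy: str = "activity_user_hard"
    mode: str = "multi_task"  # multi_task | supervised_only | two_stage
    pretrain_epochs: int = 30
    finetune_epochs: int = 30
    sampler: str = "stratified_by_activity_user"  # or "plain"
    strict_positives: bool = True
    restrict_denominator: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.lam <= 1:
            raise ValueError("lambda must lie in [0, 1]")
        if self.tau <= 0:
            raise ValueError("temperature must be positive")
        if self.early_stop_patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")
        if self.mode not in ("multi_task", "supervised_only", "two_stage"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.sampler not in ("plain", "stratified_by_activity_user"):
            raise ValueError(f"unknown sampler {self.sampler!r}")


@dataclass
class TrainHistory:
    """Per-epoch losses and validation macro-F1; best epoch per validation."""

    l_ce: list[float] = field(default_factory=list)
    l_cl: list[float] = field(default_factory=list)
    l_total: list[float] = field(default_factory=list)
    val_macro_f1: list[float] = field(default_factory=list)
    stage: list[int] = field(default_factory=list)
    best_epoch: int = -1
    stopping_reason: str = ""

    def record(self, l_ce: float, l_cl: float, l_total: float,
               val_f1: float, stage: int = 1) -> None:
        self.l_ce.append(l_ce)
        self.l_cl.append(l_cl)
        self.l_total.append(l_total)
        self.val_macro_f1.append(val_f1)
        self.stage.append(stage)


# ---------------------------------------------------------------------------
# batch samplers


def plain_batches(n: int, batch_size: int, rng: np.random.Generator) -> list[np.ndarray]:
    order = rng.permutation(n)
    return [order[i:i + batch_size] for i in range(0, n, batch_size)]


def stratified_batches(
    ws: WindowSet, batch_size: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Batches built from cross-user same-activity pairs.

    Windows of each activity are paired across different users whenever the
    roster allows, pairs are shuffled globally and chunked, so every sampled
    activity in a batch contributes at least two users — guaranteeing
    cross-user positives for the hard-negative strategy. One epoch's batches
    partition the window set exactly (drop-last disabled).
    """
    if len(ws.users) < 2:
        logger.warning("single-user window set: falling back to plain sampling")
        return plain_batches(len(ws), batch_size, rng)
    pairs: list[tuple[int, int]] = []
    singles: list[int] = []
    for act in np.unique(ws.y_act):
        idx = np.flatnonzero(ws.y_act == act)
        by_user: dict[str, list[int]] = {}
        for i in rng.permutation(idx):
            by_user.setdefault(str(ws.y_user[i]), []).append(int(i))
        queues = list(by_user.values())
        while True:
            queues = [q for q in queues if q]
            if len(queues) < 2:
                break
            # draw from the two fullest users to keep pairing cross-user
            queues.sort(key=len, reverse=True)
            pairs.append((queues[0].pop(), queues[1].pop()))
        for q in queues:
            singles.extend(q)
    order = rng.permutation(len(pairs))
    flat: list[int] = []
    for j in order:
        flat.extend(pairs[j])
    flat.extend(rng.permutation(singles).astype(int).tolist())
    seq = np.asarray(flat, dtype=np.int64)
    return [seq[i:i + batch_size] for i in range(0, len(seq), batch_size)]


# ---------------------------------------------------------------------------
# metrics


def macro_f1(y_true, y_pred, n_classes: int) -> float:
    """Unweighted mean of per-class F1 over all ``n_classes`` classes.

    A class absent from both truth and predictions contributes F1 = 0,
    penalizing dropped classes.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) == 0:
        raise ValueError("empty label vectors")
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must align")
    return float(f1_score(y_true, y_pred, labels=np.arange(n_classes),
                          average="macro", zero_division=0))


@dataclass
class EvalReport:
    """Per-class precision/recall/F1/support plus the aggregate metrics."""

    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    support: np.ndarray
    macro_f1: float
    weighted_f1: float
    accuracy: float
    confusion: np.ndarray

    def as_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "precision": self.precision, "recall": self.recall,
            "f1": self.f1, "support": self.support,
        })
        df.index.name = "class"
        return df

    def __str__(self) -> str:
        lines = [self.as_dataframe().to_string(float_format=lambda v: f"{v:.4f}")]
        lines.append(f"macro-F1 {self.macro_f1:.4f}  weighted-F1 {self.weighted_f1:.4f}"
                     f"  accuracy {self.accuracy:.4f}")
        lines.append("confusion matrix (rows = true):")
        lines.append(np.array2string(self.confusion))
        return "\n".join(lines)


def evaluate(bundle: ModelBundle, test: WindowSet, n_classes: int | None = None) -> EvalReport:
    """Inference on raw windows (no augmentation, no projector) + full report."""
    C = n_classes if n_classes is not None else test.n_classes
    y_true = test.y_act
    y_pred = predict(bundle, test)
    labels = np.arange(C)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p, r, f1, support = precision_recall_fscore_support(
            y_true, y_pred, labels=labels, zero_division=0)
    return EvalReport(
        precision=p, recall=r, f1=f1, support=support,
        macro_f1=float(np.mean(f1)),
        weighted_f1=float(f1_score(y_true, y_pred, labels=labels,
                                   average="weighted", zero_division=0)),
        accuracy=float(accuracy_score(y_true, y_pred)),
        confusion=confusion_matrix(y_true, y_pred, labels=labels),
    )


# ---------------------------------------------------------------------------
# training internals


def _augment_views(X: np.ndarray, policy: AugmentationPolicy,
                   rng: np.random.Generator) -> np.ndarray:
    """Stacked [views1; views2] array of shape (2B, C, L)."""
    v1 = np.stack([apply_policy(x, policy, rng) for x in X])
    v2 = np.stack([apply_policy(x, policy, rng) for x in X])
    return np.concatenate([v1, v2]).astype(nn.DTYPE)


def _check_finite(value: float, context: dict) -> None:
    if not np.isfinite(value):
        raise RuntimeError(f"training diverged (non-finite loss); last batch: {context}")


def _multitask_step(
    bundle: ModelBundle,
    opt: nn.AdamW,
    Xb: np.ndarray,
    yb: np.ndarray,
    ub: np.ndarray,
    cfg: TrainConfig,
    policy: AugmentationPolicy,
    rng: np.random.Generator,
    ce_weight: float = 1.0,
) -> tuple[float, float]:
    """One optimization step; returns (L_CE, L_CL) values."""
    arch = bundle.cfg
    B = len(Xb)
    contrastive = cfg.mode != "supervised_only" and cfg.lam > 0
    include_raw = ce_weight > 0
    raw = Xb.astype(nn.DTYPE)
    mask = None
    if contrastive:
        views = _augment_views(Xb, policy, rng)
        y2 = np.concatenate([yb, yb])
        u2 = np.concatenate([ub, ub])
        mask = build_pair_mask(
            y2, u2, sibling_view_map(2 * B), cfg.strategy,
            strict_positives=cfg.strict_positives,
            restrict_denominator=cfg.restrict_denominator,
        )
        if not mask.anchor_valid.any():
            logger.warning("batch without valid anchors; contrastive term skipped")
            contrastive = False
    if not contrastive and not include_raw:
        return 0.0, 0.0  # nothing to optimize this step

    drop_seed = int(rng.integers(2 ** 31))
    values: dict[str, float] = {}

    def loss_fn(p):
        # the two branches share encoder weights but run as separate
        # forwards, so each normalizes with its own batch statistics: the
        # classification branch must not have its batch norm polluted by
        # augmented (sign-flipped, rescaled, shuffled) views
        drop_rng = np.random.default_rng(drop_seed)
        total = 0.0
        l_ce_val, l_cl_val = 0.0, 0.0
        if contrastive:
            f_views = encoder_forward(arch, p["encoder"], bundle.state["encoder"],
                                      views, train=True)
            Z = projector_forward(arch, p["projector"], f_views,
                                  train=True, rng=drop_rng)
            l_cl = supcon_loss(Z, mask, cfg.tau)
            total = total + cfg.lam * l_cl
            l_cl_val = float(getval(l_cl))
        if include_raw:
            # raw branch runs second so the running statistics used at
            # inference lean toward un-augmented inputs
            f_raw = encoder_forward(arch, p["encoder"], bundle.state["encoder"],
                                    raw, train=True)
            logits = classifier_forward(arch, p["classifier"], f_raw,
                                        train=True, rng=drop_rng)
            l_ce = cross_entropy(logits, yb)
            total = total + ce_weight * l_ce
            l_ce_val = float(getval(l_ce))
        values["ce"], values["cl"] = l_ce_val, l_cl_val
        return total

    total_val, grads = value_and_grad(loss_fn)(bundle.params)
    _check_finite(float(total_val), {
        "batch_size": B, "|X|max": float(np.abs(Xb).max()),
        "L_CE": values.get("ce"), "L_CL": values.get("cl"),
    })
    active = set()
    if ce_weight > 0:
        active |= {"encoder", "classifier"}
    if contrastive:
        active |= {"encoder", "projector"}
    for name in sorted(active):
        bundle.params[name] = opt.step(name, bundle.params[name], grads[name])
    return values["ce"], values["cl"]


def _make_batches(train: WindowSet, cfg: TrainConfig,
                  rng: np.random.Generator) -> list[np.ndarray]:
    if cfg.sampler == "stratified_by_activity_user":
        return stratified_batches(train, cfg.batch_size, rng)
    return plain_batches(len(train), cfg.batch_size, rng)


def train_multitask(
    bundle: ModelBundle,
    train: WindowSet,
    val: WindowSet,
    cfg: TrainConfig,
    policy: AugmentationPolicy,
    ce_weight: float = 1.0,
) -> tuple[ModelBundle, TrainHistory]:
    """Joint classification + contrastive optimization with early stopping.

    Early stopping watches validation macro-F1 (the primary metric); the
    returned bundle carries the best-validation epoch's weights, never the
    last epoch's. ``ce_weight`` is a test hook: 0 drops the classification
    branch entirely (contrastive-only training).
    """
    if cfg.mode == "two_stage":
        raise ValueError("use train_two_stage for two-stage configs")
    opt = nn.AdamW(lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    history = TrainHistory()
    best = bundle.copy()
    best_f1 = -np.inf
    patience_left = cfg.early_stop_patience
    for epoch in range(cfg.max_epochs):
        ce_sum = cl_sum = 0.0
        batches = _make_batches(train, cfg, rng)
        for idx in batches:
            l_ce, l_cl = _multitask_step(
                bundle, opt, train.X[idx], train.y_act[idx], train.y_user[idx],
                cfg, policy, rng, ce_weight=ce_weight)
            ce_sum += l_ce * len(idx)
            cl_sum += l_cl * len(idx)
        n = len(train)
        l_ce_ep, l_cl_ep = ce_sum / n, cl_sum / n
        val_f1 = (macro_f1(val.y_act, predict(bundle, val), train.n_classes)
                  if len(val) and ce_weight > 0 else 0.0)
        history.record(l_ce_ep, l_cl_ep, l_ce_ep * (ce_weight > 0) + cfg.lam * l_cl_ep,
                       val_f1)
        if val_f1 > best_f1:
            best_f1 = val_f1
            best = bundle.copy()
            history.best_epoch = epoch
            patience_left = cfg.early_stop_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                history.stopping_reason = f"early stop at epoch {epoch}"
                break
    if not history.stopping_reason:
        history.stopping_reason = "max_epochs reached"
    if ce_weight > 0 and len(val):
        bundle.params = best.params
        bundle.state = best.state
    return bundle, history


def train_two_stage(
    bundle: ModelBundle,
    train: WindowSet,
    val: WindowSet,
    cfg: TrainConfig,
    policy: AugmentationPolicy,
) -> tuple[ModelBundle, TrainHistory]:
    """Contrastive pretraining, then frozen-encoder classifier fine-tuning.

    Stage 1 optimizes only the contrastive objective (per ``cfg.strategy``)
    on encoder + projector for ``pretrain_epochs``. Stage 2 freezes the
    encoder, caches features, and trains the classifier alone with
    cross-entropy for ``finetune_epochs`` with early stopping on validation
    macro-F1.
    """
    arch = bundle.cfg
    history = TrainHistory()
    rng = np.random.default_rng(cfg.seed)
    # --- stage 1: contrastive only -----------------------------------------
    stage1_cfg = replace(cfg, mode="multi_task", lam=1.0)
    opt = nn.AdamW(lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    for epoch in range(cfg.pretrain_epochs):
        cl_sum = 0.0
        for idx in _make_batches(train, stage1_cfg, rng):
            _, l_cl = _multitask_step(
                bundle, opt, train.X[idx], train.y_act[idx], train.y_user[idx],
                stage1_cfg, policy, rng, ce_weight=0.0)
            cl_sum += l_cl * len(idx)
        history.record(0.0, cl_sum / len(train), cl_sum / len(train), 0.0, stage=1)
    # --- stage 2: frozen encoder, classifier only ---------------------------
    feats_train = _encode_eval(bundle, train.X)
    feats_val = _encode_eval(bundle, val.X) if len(val) else None
    opt2 = nn.AdamW(lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    best_clf = nn.tree_copy(bundle.params["classifier"])
    best_f1 = -np.inf
    best_epoch = -1
    patience_left = cfg.early_stop_patience
    for epoch in range(cfg.finetune_epochs):
        ce_sum = 0.0
        for idx in plain_batches(len(train), cfg.batch_size, rng):
            drop_seed = int(rng.integers(2 ** 31))

            def loss_fn(p_clf):
                drop_rng = np.random.default_rng(drop_seed)
                logits = classifier_forward(arch, p_clf, feats_train[idx],
                                            train=True, rng=drop_rng)
                return cross_entropy(logits, train.y_act[idx])

            l_ce, g = value_and_grad(loss_fn)(bundle.params["classifier"])
            _check_finite(float(l_ce), {"stage": 2, "batch_size": len(idx)})
            bundle.params["classifier"] = opt2.step(
                "classifier", bundle.params["classifier"], g)
            ce_sum += float(l_ce) * len(idx)
        if feats_val is not None:
            logits_val = classifier_forward(arch, bundle.params["classifier"],
                                            feats_val, train=False)
            val_f1 = macro_f1(val.y_act, np.argmax(logits_val, axis=1),
                              train.n_classes)
        else:
            val_f1 = 0.0
        history.record(ce_sum / len(train), 0.0, ce_sum / len(train), val_f1, stage=2)
        if val_f1 > best_f1:
            best_f1 = val_f1
            best_clf = nn.tree_copy(bundle.params["classifier"])
            best_epoch = len(history.l_ce) - 1
            patience_left = cfg.early_stop_patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                history.stopping_reason = "early stop in fine-tuning"
                break
    history.best_epoch = best_epoch
    if not history.stopping_reason:
        history.stopping_reason = "finetune_epochs reached"
    if feats_val is not None:
        bundle.params["classifier"] = best_clf
    return bundle, history


def _encode_eval(bundle: ModelBundle, X: np.ndarray) -> np.ndarray:
    return np.asarray(encoder_forward(
        bundle.cfg, bundle.params["encoder"], bundle.state["encoder"],
        X.astype(nn.DTYPE), train=False))


# ---------------------------------------------------------------------------
# experiment harness


def run_experiment(
    ws: WindowSet,
    variants: Mapping[str, TrainConfig],
    arch: ArchitectureConfig,
    policy: AugmentationPolicy,
    n_runs: int = 3,
    base_seed: int = 0,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    standardize: bool = True,
) -> pd.DataFrame:
    """Held-out-user macro-F1, mean +/- sd over fresh user-disjoint splits.

    Each run draws a fresh fractional user split (seeded by ``base_seed +
    run``), standardizes with train statistics, trains each variant from a
    fresh seeded initialization, and evaluates on the unseen test users.
    """
    rows = []
    for name, cfg in variants.items():
        scores = []
        for run in range(n_runs):
            seed = base_seed + run
            try:
                score = _single_run(ws, cfg, arch, policy, seed, fractions,
                                    standardize)
            except ValueError as exc:
                logger.warning("variant %r run %d skipped: %s", name, run, exc)
                continue
            scores.append(score)
        if scores:
            rows.append({"variant": name, "mean_macro_f1": float(np.mean(scores)),
                         "sd_macro_f1": float(np.std(scores, ddof=1)) if len(scores) > 1 else 0.0,
                         "n_runs": len(scores)})
    return pd.DataFrame(rows)


def _single_run(
    ws: WindowSet,
    cfg: TrainConfig,
    arch: ArchitectureConfig,
    policy: AugmentationPolicy,
    seed: int,
    fractions: tuple[float, float, float],
    standardize: bool,
) -> float:
    train, val, test = split_by_users(ws, SplitSpec(fractions=fractions, seed=seed))
    if standardize:
        stats = fit_standardizer(train)
        train = apply_standardizer(train, stats)
        val = apply_standardizer(val, stats)
        test = apply_standardizer(test, stats)
    bundle = build_model(arch, seed=seed)
    run_cfg = replace(cfg, seed=seed)
    if cfg.mode == "two_stage":
        bundle, _ = train_two_stage(bundle, train, val, run_cfg, policy)
    else:
        bundle, _ = train_multitask(bundle, train, val, run_cfg, policy)
    return macro_f1(test.y_act, predict(bundle, test), ws.n_classes)
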
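"""The three networks: residual 1-D encoder, projection head, classifier.

The encoder F is a time-series ResNet: three stacked residual blocks, each
three same-padded stride-1 convolutions (kernel lengths 8/5/3) with batch
normalization and ReLU, an identity shortcut (1x1 projection + batch norm
when channel counts differ) added before the block's final ReLU, and global
average pooling over time — so the feature dimension equals the last block's
filter count and is independent of window length.

The projection head H (one hidden ReLU/dropout layer) maps features to a
lower-dimensional space and its output is l2-normalized onto the unit
hypersphere: ``z = H(f) / ||H(f)||``. It exists only for the contrastive
objective and is discarded at inference. The classification head G is three
fully connected layers (ReLU + dropout on the hidden ones) ending in
activity logits.

Parameter groups theta (encoder), phi' (projector) and phi (classifier) are
addressable separately — the structural prerequisite for routing the
classification gradient to (theta, phi) and the contrastive gradient to
(theta, phi') and nothing else.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import autograd.numpy as anp
import numpy as np

from . import nn
from .prep import WindowSet

logger = logging.getLogger(__name__)

__all__ = [
    "ArchitectureConfig", "ModelBundle", "build_model", "encode", "project",
    "classify", "predict", "softmax", "count_parameters",
    "save_checkpoint", "load_checkpoint",
]

_KERNELS = (8, 5, 3)  # within each residual block


@dataclass(frozen=True)
class ArchitectureConfig:
    """Shapes of encoder, projector and classifier.

    ``block_filters`` follows the standard time-series ResNet (64, 128, 128);
    ``projector_hidden`` is the projection head's single hidden width and
    ``projector_out`` its output dimension. ``classifier_hidden`` gives the
    two hidden widths of the three-layer classification head.
    """

    in_channels: int
    n_classes: int
    block_filters: tuple[int, int, int] = (64, 128, 128)
    projector_hidden: int = 256
    projector_out: int = 128
    classifier_hidden: tuple[int, int] = (256, 128)
    dropout: float = 0.2
    use_projector: bool = True  # False: contrastive loss applied on raw features

    def __post_init__(self) -> None:
        if self.in_channels < 1 or self.n_classes < 2:
            raise ValueError("need >=1 channel and >=2 classes")
        if len(self.block_filters) != 3:
            raise ValueError("exactly 3 residual blocks")
        if len(self.classifier_hidden) != 2:
            raise ValueError("classifier has exactly 3 fully connected layers")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")

    @property
    def feature_dim(self) -> int:
        return self.block_filters[-1]


@dataclass
class ModelBundle:
    """Parameters + batch-norm state for encoder/projector/classifier."""

    cfg: ArchitectureConfig
    params: dict  # {"encoder": ..., "projector": ..., "classifier": ...}
    state: dict  # {"encoder": {block bn running stats}}
    seed: int

    def copy(self) -> "ModelBundle":
        return ModelBundle(self.cfg, nn.tree_copy(self.params),
                           nn.tree_copy(self.state), self.seed)


def build_model(cfg: ArchitectureConfig, seed: int = 0) -> ModelBundle:
    """Deterministically initialized model (He-normal weights under ``seed``)."""
    rng = np.random.default_rng(seed)
    enc_p: dict = {}
    enc_s: dict = {}
    in_ch = cfg.in_channels
    for b, f in enumerate(cfg.block_filters):
        blk_p: dict = {}
        blk_s: dict = {}
        ch = in_ch
        for i, k in enumerate(_KERNELS):
            blk_p[f"conv{i}"] = nn.init_conv1d(rng, ch, f, k)
            blk_p[f"bn{i}"], blk_s[f"bn{i}"] = nn.init_batchnorm(f)
            ch = f
        if in_ch != f:
            blk_p["short_conv"] = nn.init_conv1d(rng, in_ch, f, 1)
            blk_p["short_bn"], blk_s["short_bn"] = nn.init_batchnorm(f)
        enc_p[f"block{b}"] = blk_p
        enc_s[f"block{b}"] = blk_s
        in_ch = f
    d = cfg.feature_dim
    proj_p = {
        "fc0": nn.init_dense(rng, d, cfg.projector_hidden),
        "fc1": nn.init_dense(rng, cfg.projector_hidden, cfg.projector_out),
    }
    h1, h2 = cfg.classifier_hidden
    clf_p = {
        "fc0": nn.init_dense(rng, d, h1),
        "fc1": nn.init_dense(rng, h1, h2),
        "fc2": nn.init_dense(rng, h2, cfg.n_classes),
    }
    params = {"encoder": enc_p, "projector": proj_p, "classifier": clf_p}
    state = {"encoder": enc_s}
    return ModelBundle(cfg, params, state, seed)


def encoder_forward(cfg: ArchitectureConfig, params: dict, state: dict, x,
                    train: bool = False):
    """x (N, C, L) -> features (N, feature_dim) via residual blocks + GAP."""
    h = x
    for b, f in enumerate(cfg.block_filters):
        blk, blk_s = params[f"block{b}"], state[f"block{b}"]
        out = h
        for i in range(len(_KERNELS)):
            out = nn.conv1d(blk[f"conv{i}"], out)
            out = nn.batchnorm(blk[f"bn{i}"], blk_s[f"bn{i}"], out, train)
            if i < len(_KERNELS) - 1:
                out = nn.relu(out)
        if "short_conv" in blk:
            sc = nn.conv1d(blk["short_conv"], h)
            sc = nn.batchnorm(blk["short_bn"], blk_s["short_bn"], sc, train)
        else:
            sc = h
        h = nn.relu(out + sc)
    return anp.mean(h, axis=2)


def projector_forward(cfg: ArchitectureConfig, params: dict, f,
                      train: bool = False, rng: np.random.Generator | None = None):
    """Features -> l2-normalized embeddings on the unit hypersphere."""
    if not cfg.use_projector:
        h = f
    else:
        h = nn.relu(nn.dense(params["fc0"], f))
        h = nn.dropout(h, cfg.dropout, rng, train)
        h = nn.dense(params["fc1"], h)
    norm = anp.sqrt(anp.sum(h * h, axis=1, keepdims=True))
    from autograd.tracer import getval
    if np.any(getval(norm) < 1e-12):
        logger.warning("zero-norm projection encountered; epsilon guard applied")
    return h / anp.maximum(norm, 1e-12)


def classifier_forward(cfg: ArchitectureConfig, params: dict, f,
                       train: bool = False, rng: np.random.Generator | None = None):
    """Features -> class logits (N, n_classes)."""
    h = nn.relu(nn.dense(params["fc0"], f))
    h = nn.dropout(h, cfg.dropout, rng, train)
    h = nn.relu(nn.dense(params["fc1"], h))
    h = nn.dropout(h, cfg.dropout, rng, train)
    return nn.dense(params["fc2"], h)


# -- convenience eval-mode wrappers on a bundle ------------------------------

def encode(bundle: ModelBundle, windows: WindowSet | np.ndarray) -> np.ndarray:
    X = windows.X if isinstance(windows, WindowSet) else windows
    X = np.asarray(X, dtype=nn.DTYPE)
    return np.asarray(
        encoder_forward(bundle.cfg, bundle.params["encoder"],
                        bundle.state["encoder"], X, train=False)
    )


def project(bundle: ModelBundle, f: np.ndarray) -> np.ndarray:
    return np.asarray(
        projector_forward(bundle.cfg, bundle.params["projector"],
                          np.asarray(f, dtype=nn.DTYPE), train=False)
    )


def classify(bundle: ModelBundle, f: np.ndarray) -> np.ndarray:
    return np.asarray(
        classifier_forward(bundle.cfg, bundle.params["classifier"],
                           np.asarray(f, dtype=nn.DTYPE), train=False)
    )


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def predict(bundle: ModelBundle, windows: WindowSet | np.ndarray) -> np.ndarray:
    """Raw windows -> argmax class labels (ties broken at the lowest index)."""
    return np.argmax(softmax(classify(bundle, encode(bundle, windows))), axis=1)


def count_parameters(bundle: ModelBundle) -> dict[str, int]:
    """Exact parameter counts per component plus the total."""
    def _count(tree) -> int:
        if isinstance(tree, dict):
            return sum(_count(v) for v in tree.values())
        return int(np.asarray(tree).size)

    counts = {
        "encoder": _count(bundle.params["encoder"]),
        "projector": _count(bundle.params["projector"]),
        "classifier": _count(bundle.params["classifier"]),
    }
    counts["total"] = sum(counts.values())
    return counts


# -- checkpoints -------------------------------------------------------------

_SCHEMA_VERSION = 1


def _flatten_tree(tree, prefix, out):
    if isinstance(tree, dict):
        for k, v in tree.items():
            _flatten_tree(v, f"{prefix}/{k}" if prefix else k, out)
    else:
        out[prefix] = np.asarray(tree)


def _unflatten_tree(flat: dict) -> dict:
    root: dict = {}
    for key, val in flat.items():
        parts = key.split("/")
        node = root
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = val
    return root


def save_checkpoint(bundle: ModelBundle, path) -> None:
    arrays: dict[str, np.ndarray] = {}
    _flatten_tree(bundle.params, "params", arrays)
    _flatten_tree(bundle.state, "state", arrays)
    meta = {"schema_version": _SCHEMA_VERSION, "seed": bundle.seed,
            "cfg": asdict(bundle.cfg)}
    arrays["__meta__"] = np.frombuffer(json.dumps(meta, sort_keys=True).encode(),
                                       dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> ModelBundle:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("schema_version") != _SCHEMA_VERSION:
            raise ValueError(f"unsupported checkpoint schema {meta.get('schema_version')}")
        flat = {k: data[k] for k in data.files if k != "__meta__"}
    tree = _unflatten_tree(flat)
    cfg_d = meta["cfg"]
    for key in ("block_filters", "classifier_hidden"):
        cfg_d[key] = tuple(cfg_d[key])
    cfg = ArchitectureConfig(**cfg_d)
    return ModelBundle(cfg, tree["params"], tree["state"], meta["seed"])
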
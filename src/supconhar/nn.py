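"""Minimal neural-network layer stack on numpy + autograd.

Parameters live in nested dicts of numpy arrays so reverse-mode autodiff
(`autograd.grad`) can differentiate straight through the forward functions;
optimizer state is kept flat. Layers cover exactly what the architecture
needs: same-padded 1-D convolution, batch normalization with running
statistics, dense layers, ReLU, dropout, and an AdamW optimizer.

Batch-norm running statistics are a side effect of training-mode forwards;
they are detached from the autodiff trace (``getval``) before being stored.
Dropout masks are drawn from an explicit ``numpy.random.Generator`` so a
training step is a pure function of (parameters, data, rng state).
"""

from __future__ import annotations

from typing import Callable

import autograd.numpy as anp
import numpy as np
from autograd.extend import defvjp, primitive
from autograd.misc import flatten
from autograd.tracer import getval

DTYPE = np.float32

__all__ = [
    "DTYPE", "init_conv1d", "conv1d", "init_batchnorm", "batchnorm",
    "init_dense", "dense", "relu", "dropout", "AdamW", "tree_copy", "tree_equal",
]


def init_conv1d(rng: np.random.Generator, in_ch: int, out_ch: int, k: int) -> dict:
    """He-normal weights for a conv layer; bias zero."""
    scale = np.sqrt(2.0 / (in_ch * k))
    return {
        "W": (rng.normal(0.0, scale, (out_ch, in_ch, k))).astype(DTYPE),
        "b": np.zeros(out_ch, dtype=DTYPE),
    }


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """Sliding-window view (N, C, L, k) of the same-padded input; no copy."""
    left = (k - 1) // 2
    xp = np.pad(x, ((0, 0), (0, 0), (left, k - 1 - left)))
    return np.lib.stride_tricks.sliding_window_view(xp, k, axis=2)


@primitive
def _correlate_same(x: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Same-padded stride-1 cross-correlation: x (N,C,L), W (O,C,k) -> (N,O,L)."""
    return np.einsum("nctj,ocj->not", _im2col(x, W.shape[2]), W, optimize=True)


def _correlate_vjp_x(ans, x, W):
    k = W.shape[2]
    left = (k - 1) // 2

    def vjp(g):
        # gradient w.r.t. x is the full correlation of g with W flipped in
        # time and transposed in channels
        gp = np.pad(g, ((0, 0), (0, 0), (k - 1 - left, left)))
        windows = np.lib.stride_tricks.sliding_window_view(gp, k, axis=2)
        return np.einsum("nomj,ocj->ncm", windows, W[:, :, ::-1], optimize=True)

    return vjp


def _correlate_vjp_W(ans, x, W):
    def vjp(g):
        return np.einsum("not,nctj->ocj", g, _im2col(x, W.shape[2]), optimize=True)

    return vjp


defvjp(_correlate_same, _correlate_vjp_x, _correlate_vjp_W)


def conv1d(params: dict, x):
    """Same-padded, stride-1 1-D convolution.

    ``x`` has shape (N, C_in, L); returns (N, C_out, L). The correlation is
    a custom autograd primitive with hand-written adjoints (a sliding-window
    view contracted by einsum), keeping both passes inside BLAS.
    """
    out = _correlate_same(x, params["W"])
    return out + params["b"][None, :, None]


def init_batchnorm(n_ch: int) -> tuple[dict, dict]:
    params = {"gamma": np.ones(n_ch, dtype=DTYPE), "beta": np.zeros(n_ch, dtype=DTYPE)}
    state = {"mean": np.zeros(n_ch, dtype=DTYPE), "var": np.ones(n_ch, dtype=DTYPE)}
    return params, state


_BN_EPS = 1e-5

# (xhat, inv_std) from training-mode forwards, keyed by id(output) for the
# adjoints; FIFO-capped (entries from forwards whose backward never runs)
_BN_CACHE: dict[int, tuple] = {}
_BN_CACHE_MAX = 24


def _bn_moments(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, tuple]:
    axes = (0, 2) if x.ndim == 3 else (0,)
    mu = x.mean(axis=axes)
    var = x.var(axis=axes)
    return mu, var, axes


@primitive
def _bn_train(x: np.ndarray, gamma: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Fused training-mode batch normalization (single primitive so the
    whole chain has one hand-written adjoint instead of ~10 traced ops)."""
    mu, var, axes = _bn_moments(x)
    inv_std = 1.0 / np.sqrt(var + _BN_EPS)
    xhat = (x - _expand(mu, x)) * _expand(inv_std, x)
    ans = _expand(gamma, x) * xhat + _expand(beta, x)
    _BN_CACHE[id(ans)] = (xhat, inv_std, axes)
    while len(_BN_CACHE) > _BN_CACHE_MAX:
        _BN_CACHE.pop(next(iter(_BN_CACHE)))
    return ans


def _bn_saved(ans, x):
    saved = _BN_CACHE.get(id(ans))
    if saved is None:
        mu, var, axes = _bn_moments(x)
        inv_std = 1.0 / np.sqrt(var + _BN_EPS)
        saved = ((x - _expand(mu, x)) * _expand(inv_std, x), inv_std, axes)
    return saved


def _bn_vjp_x(ans, x, gamma, beta):
    def vjp(g):
        xhat, inv_std, axes = _bn_saved(ans, x)
        m = np.prod([x.shape[a] for a in axes])
        g_sum = g.sum(axis=axes)
        gx_sum = (g * xhat).sum(axis=axes)
        return (_expand(gamma * inv_std, x)
                * (g - _expand(g_sum / m, x) - xhat * _expand(gx_sum / m, x)))

    return vjp


def _bn_vjp_gamma(ans, x, gamma, beta):
    def vjp(g):
        xhat, _, axes = _bn_saved(ans, x)
        return (g * xhat).sum(axis=axes)

    return vjp


def _bn_vjp_beta(ans, x, gamma, beta):
    def vjp(g):
        _, _, axes = _bn_saved(ans, x)
        return g.sum(axis=axes)

    return vjp


defvjp(_bn_train, _bn_vjp_x, _bn_vjp_gamma, _bn_vjp_beta)


def batchnorm(params: dict, state: dict, x, train: bool, momentum: float = 0.1, eps: float = _BN_EPS):
    """Channel batch normalization over (N, C, L) or (N, C) inputs.

    Training mode normalizes with batch statistics and updates the running
    statistics in ``state`` (detached from the autodiff trace); eval mode
    uses the frozen running statistics.
    """
    if train:
        mu, var, _ = _bn_moments(getval(x))
        state["mean"] = ((1 - momentum) * state["mean"] + momentum * mu).astype(DTYPE)
        state["var"] = ((1 - momentum) * state["var"] + momentum * var).astype(DTYPE)
        return _bn_train(x, params["gamma"], params["beta"])
    mu, var = state["mean"], state["var"]
    xhat = (x - _expand(mu, x)) / anp.sqrt(_expand(var, x) + eps)
    return _expand(params["gamma"], x) * xhat + _expand(params["beta"], x)


def _expand(v, like):
    return v[None, :, None] if like.ndim == 3 else v[None, :]


def init_dense(rng: np.random.Generator, n_in: int, n_out: int) -> dict:
    scale = np.sqrt(2.0 / n_in)
    return {
        "W": (rng.normal(0.0, scale, (n_in, n_out))).astype(DTYPE),
        "b": np.zeros(n_out, dtype=DTYPE),
    }


def dense(params: dict, x):
    return anp.dot(x, params["W"]) + params["b"]


def relu(x):
    return anp.maximum(x, 0.0)


def dropout(x, rate: float, rng: np.random.Generator | None, train: bool):
    """Inverted dropout; identity in eval mode or at rate 0."""
    if not train or rate <= 0:
        return x
    keep = (rng.random(getval(x).shape) >= rate).astype(DTYPE)
    return x * keep / (1.0 - rate)


def tree_copy(tree):
    if isinstance(tree, dict):
        return {k: tree_copy(v) for k, v in tree.items()}
    if isinstance(tree, (list, tuple)):
        return type(tree)(tree_copy(v) for v in tree)
    return np.array(tree, copy=True)


def tree_equal(a, b) -> bool:
    fa, _ = flatten(a)
    fb, _ = flatten(b)
    return fa.shape == fb.shape and bool(np.array_equal(fa, fb))


class AdamW:
    """AdamW with decoupled weight decay over a dict of parameter trees.

    Each named component (encoder / projector / classifier) keeps its own
    moment estimates; ``step`` updates only the components it is handed, so
    parameter groups outside the active objective stay bitwise untouched.
    """

    def __init__(self, lr: float = 1e-3, betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.01):
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}
        self._t: dict[str, int] = {}

    def step(self, name: str, params: dict, grads: dict) -> dict:
        flat_p, unflatten = flatten(params)
        flat_g, _ = flatten(grads)
        flat_g = flat_g.astype(np.float64)
        if name not in self._m:
            self._m[name] = np.zeros_like(flat_p, dtype=np.float64)
            self._v[name] = np.zeros_like(flat_p, dtype=np.float64)
            self._t[name] = 0
        b1, b2 = self.betas
        self._t[name] += 1
        t = self._t[name]
        self._m[name] = b1 * self._m[name] + (1 - b1) * flat_g
        self._v[name] = b2 * self._v[name] + (1 - b2) * flat_g ** 2
        mhat = self._m[name] / (1 - b1 ** t)
        vhat = self._v[name] / (1 - b2 ** t)
        new = flat_p.astype(np.float64)
        new = new - self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * new)
        return unflatten(new.astype(flat_p.dtype))
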
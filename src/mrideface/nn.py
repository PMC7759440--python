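"""Minimal 3D neural-network layers with explicit forward/backward passes.

Everything operates on channels-last float32 arrays of shape (D, H, W, C).
Convolutions are evaluated as 27 shifted matrix products (one per kernel
offset), which keeps memory flat and maps the whole cost onto BLAS.  Each
``*_forward`` returns the output plus the cache its ``*_backward`` needs.

This is deliberately a small, readable kernel set — just what an
attention-gated U-net requires: 3x3x3 and 1x1x1 convolutions, ReLU,
sigmoid, 2x average pooling, nearest-neighbour upsampling, and softmax.
"""

from __future__ import annotations

from itertools import product

import numpy as np

_OFFSETS = tuple(product(range(3), repeat=3))


def he_init(rng: np.random.Generator, fan_in: int, shape: tuple) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


# ---------------------------------------------------------------------------
# 3x3x3 convolution, padding 1 ("same")
# ---------------------------------------------------------------------------

def conv3_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """x: (D,H,W,Ci); w: (27,Ci,Co); b: (Co,) -> y: (D,H,W,Co)."""
    d, h, wd, ci = x.shape
    co = w.shape[2]
    xp = np.pad(x, ((1, 1), (1, 1), (1, 1), (0, 0)))
    y = np.zeros((d * h * wd, co), dtype=np.float32)
    for idx, (di, dj, dk) in enumerate(_OFFSETS):
        sl = xp[di:di + d, dj:dj + h, dk:dk + wd].reshape(-1, ci)
        y += sl @ w[idx]
    y += b
    return y.reshape(d, h, wd, co), (xp, x.shape, w)


def conv3_backward(dy: np.ndarray, cache):
    xp, xshape, w = cache
    d, h, wd, ci = xshape
    co = w.shape[2]
    dyf = dy.reshape(-1, co)
    dw = np.empty_like(w)
    dxp = np.zeros_like(xp)
    for idx, (di, dj, dk) in enumerate(_OFFSETS):
        sl = xp[di:di + d, dj:dj + h, dk:dk + wd].reshape(-1, ci)
        dw[idx] = sl.T @ dyf
        dxp[di:di + d, dj:dj + h, dk:dk + wd] += (dyf @ w[idx].T).reshape(d, h, wd, ci)
    db = dyf.sum(axis=0)
    dx = dxp[1:-1, 1:-1, 1:-1]
    return dx, dw, db


# ---------------------------------------------------------------------------
# 1x1x1 convolution (per-voxel linear map)
# ---------------------------------------------------------------------------

def conv1_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray):
    """x: (...,Ci); w: (Ci,Co); b: (Co,)."""
    y = x @ w + b
    return y, (x, w)


def conv1_backward(dy: np.ndarray, cache):
    x, w = cache
    ci, co = w.shape
    dw = x.reshape(-1, ci).T @ dy.reshape(-1, co)
    db = dy.reshape(-1, co).sum(axis=0)
    dx = dy @ w.T
    return dx, dw, db


# ---------------------------------------------------------------------------
# Pointwise nonlinearities
# ---------------------------------------------------------------------------

def relu_forward(x: np.ndarray):
    y = np.maximum(x, 0.0)
    return y, (x > 0)


def relu_backward(dy: np.ndarray, mask) -> np.ndarray:
    return dy * mask


def sigmoid_forward(x: np.ndarray):
    y = 1.0 / (1.0 + np.exp(-x))
    return y, y


def sigmoid_backward(dy: np.ndarray, y) -> np.ndarray:
    return dy * y * (1.0 - y)


# ---------------------------------------------------------------------------
# Resolution changes
# ---------------------------------------------------------------------------

def avgpool2_forward(x: np.ndarray):
    d, h, w, c = x.shape
    y = x.reshape(d // 2, 2, h // 2, 2, w // 2, 2, c).mean(axis=(1, 3, 5))
    return y, x.shape


def avgpool2_backward(dy: np.ndarray, xshape) -> np.ndarray:
    up = np.repeat(np.repeat(np.repeat(dy, 2, axis=0), 2, axis=1), 2, axis=2)
    return (up / 8.0).astype(np.float32)


def upsample2_forward(x: np.ndarray):
    y = np.repeat(np.repeat(np.repeat(x, 2, axis=0), 2, axis=1), 2, axis=2)
    return y, x.shape


def upsample2_backward(dy: np.ndarray, xshape) -> np.ndarray:
    d, h, w, c = xshape
    return dy.reshape(d, 2, h, 2, w, 2, c).sum(axis=(1, 3, 5))


# ---------------------------------------------------------------------------
# Softmax over the channel axis
# ---------------------------------------------------------------------------

def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_chain(dp: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Given dL/dp and probabilities p, return dL/dz (logits)."""
    inner = (dp * p).sum(axis=-1, keepdims=True)
    return p * (dp - inner)


# ---------------------------------------------------------------------------
# Adam optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Standard Adam with bias correction, one slot pair per parameter name."""

    def __init__(self, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for name, g in grads.items():
            if name not in self.m:
                self.m[name] = np.zeros_like(g)
                self.v[name] = np.zeros_like(g)
            m = self.m[name]
            v = self.v[name]
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            params[name] -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
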
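"""Minimal CPU neural-network layers with explicit backward passes.

Everything here operates on float32 ``(N, C, H, W)`` arrays.  Convolutions
are evaluated through im2col + BLAS matmul; gradients are derived
analytically per layer, so there is no tape or graph — networks compose
layers explicitly and call ``backward`` in reverse order.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2d",
    "ReLU",
    "Upsample2xBilinear",
    "Adam",
    "sigmoid",
    "focal_loss_value",
    "focal_loss_grad_logits",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(z, dtype=np.float32)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Layer:
    """Base class: stateful forward/backward with parameter lists."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """k x k convolution, zero padding ``pad``, stride ``stride``, with bias.

    Weights use He-uniform initialisation.  Backward returns the input
    gradient and accumulates dW/db for the optimiser.
    """

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.cin, self.cout, self.k, self.stride = cin, cout, k, stride
        self.pad = (k // 2) if pad is None else pad
        bound = float(np.sqrt(6.0 / (cin * k * k)))
        self.W = rng.uniform(-bound, bound, size=(cin * k * k, cout)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache: tuple | None = None

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def _im2col(self, xp: np.ndarray, ho: int, wo: int) -> np.ndarray:
        k, s = self.k, self.stride
        # (N, C, Hp, Wp) -> windows (N, C, ho, wo, k, k)
        win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s][:, :, :ho, :wo]
        # -> (N, ho, wo, C, k, k) -> (N*ho*wo, C*k*k)
        col = win.transpose(0, 2, 3, 1, 4, 5).reshape(-1, self.cin * k * k)
        return np.ascontiguousarray(col)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        col = self._im2col(xp, ho, wo)
        y = col @ self.W + self.b
        if train:
            self._cache = (col, x.shape, xp.shape, ho, wo)
        return y.reshape(n, ho, wo, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        col, xshape, xpshape, ho, wo = self._cache
        n, c, h, w = xshape
        k, s, p = self.k, self.stride, self.pad
        dyc = dy.transpose(0, 2, 3, 1).reshape(-1, self.cout)
        self.dW[...] = col.T @ dyc
        self.db[...] = dyc.sum(axis=0)
        dcol = dyc @ self.W.T  # (N*ho*wo, C*k*k)
        dcol = dcol.reshape(n, ho, wo, c, k, k)
        dxp = np.zeros(xpshape, dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += dcol[:, :, :, :, i, j].transpose(0, 3, 1, 2)
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


def _up1d(x: np.ndarray, axis: int) -> np.ndarray:
    """Bilinear 2x upsampling along one axis (half-pixel centers, clamped)."""
    x = np.moveaxis(x, axis, -1)
    left = np.concatenate([x[..., :1], x[..., :-1]], axis=-1)
    right = np.concatenate([x[..., 1:], x[..., -1:]], axis=-1)
    even = 0.75 * x + 0.25 * left
    odd = 0.75 * x + 0.25 * right
    out = np.empty(x.shape[:-1] + (2 * x.shape[-1],), dtype=np.float32)
    out[..., 0::2] = even
    out[..., 1::2] = odd
    return np.moveaxis(out, -1, axis)


def _down1d_T(dy: np.ndarray, axis: int) -> np.ndarray:
    """Transpose (adjoint) of :func:`_up1d` along one axis."""
    dy = np.moveaxis(dy, axis, -1)
    even = dy[..., 0::2]
    odd = dy[..., 1::2]
    dx = 0.75 * (even + odd)
    # odd[i] contributed 0.25 to x[i+1] (clamped at the top edge)
    dx[..., 1:] += 0.25 * odd[..., :-1]
    dx[..., -1] += 0.25 * odd[..., -1]
    # even[i] contributed 0.25 to x[i-1] (clamped at the bottom edge)
    dx[..., :-1] += 0.25 * even[..., 1:]
    dx[..., 0] += 0.25 * even[..., 0]
    return np.moveaxis(dx.astype(np.float32), -1, axis)


class Upsample2xBilinear(Layer):
    """Doubles H and W with separable bilinear interpolation."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return _up1d(_up1d(x, 2), 3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return _down1d_T(_down1d_T(dy, 3), 2)


class Adam:
    """Adam with the standard bias-corrected moments (b1=0.9, b2=0.999)."""

    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray],
                 lr: float = 1e-4, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        c1 = 1.0 - self.b1 ** self.t
        c2 = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


_EPS = 1e-7


def focal_loss_value(pred: np.ndarray, target: np.ndarray, gamma: float) -> float:
    """Mean focal loss -(1-p_t)^gamma * log(p_t) over all elements.

    ``pred`` holds probabilities in [0,1] (clamped to [eps, 1-eps]);
    ``target`` is binary.  At gamma=0 this is binary cross-entropy.
    """
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    p = np.clip(pred.astype(np.float64), _EPS, 1.0 - _EPS)
    t = target.astype(np.float64)
    pt = np.where(t > 0.5, p, 1.0 - p)
    return float(np.mean(-((1.0 - pt) ** gamma) * np.log(pt)))


def focal_loss_grad_logits(logits: np.ndarray, target: np.ndarray,
                           gamma: float) -> tuple[float, np.ndarray]:
    """Focal loss and its gradient w.r.t. pre-sigmoid logits.

    Returns ``(loss, dL/dz)`` with the gradient already averaged (divided by
    the element count), matching :func:`focal_loss_value` on sigmoid(logits).
    """
    p = sigmoid(logits).astype(np.float64)
    p = np.clip(p, _EPS, 1.0 - _EPS)
    t = target.astype(np.float64)
    pt = np.where(t > 0.5, p, 1.0 - p)
    one_m = 1.0 - pt
    loss = float(np.mean(-(one_m ** gamma) * np.log(pt)))
    # dL/dpt = gamma*(1-pt)^(g-1)*log(pt) - (1-pt)^g / pt ; dpt/dz = +-pt(1-pt)
    if gamma == 0.0:
        dpt = -1.0 / pt
    else:
        dpt = gamma * (one_m ** (gamma - 1.0)) * np.log(pt) - (one_m ** gamma) / pt
    sign = np.where(t > 0.5, 1.0, -1.0)
    dz = dpt * pt * one_m * sign / pt.size
    return loss, dz.astype(np.float32)
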
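"""Minimal CPU neural-network layer library (numpy, NHWC layout).

Self-contained building blocks — convolutions, pooling, dense layers,
dropout, nearest-neighbour upsampling, additive attention gates — with
hand-written backward passes and an Adam optimizer.  This is the runtime
behind the offline ``small_cnn`` classifier backbone and ``small_encoder``
U-Net tier: small enough to train on a single CPU in minutes, deterministic
under a fixed seed, with no framework dependency.

All activations flow as float32 arrays shaped (N, H, W, C) for image layers
and (N, F) for dense layers.  Losses for segmentation (binary cross-entropy,
soft Dice, active-contour) are defined on probability maps and return both
the scalar value and its gradient with respect to the probabilities.
"""

from __future__ import annotations

import json
import os
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "Conv2D", "Dense", "ReLU", "Sigmoid", "MaxPool2", "Upsample2", "AvgPool",
    "Dropout", "Flatten", "AttentionGate", "Sequential", "Adam",
    "bce_loss", "dice_loss", "active_contour_loss", "ac_length_term",
    "save_params", "load_params",
]

_EPS = 1e-7


# ----------------------------------------------------------------------------
# Layers


class Layer:
    """Base layer: parameters in ``params``, matching gradients in ``grads``."""

    def __init__(self) -> None:
        self.params: Dict[str, np.ndarray] = {}
        self.grads: Dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv2D(Layer):
    """2D convolution with 'same' padding, stride 1, He-normal init."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        super().__init__()
        self.cin, self.cout, self.k = cin, cout, k
        scale = np.sqrt(2.0 / (k * k * cin))
        self.params["W"] = rng.normal(0, scale, (k * k * cin, cout)).astype(np.float32)
        self.params["b"] = np.zeros(cout, dtype=np.float32)
        self.pad_before = (k - 1) // 2
        self.pad_after = k // 2

    def _im2col(self, xp: np.ndarray, h: int, w: int) -> np.ndarray:
        n, _, _, c = xp.shape
        k = self.k
        cols = np.empty((n, h, w, k, k, c), dtype=xp.dtype)
        for i in range(k):
            for j in range(k):
                cols[:, :, :, i, j, :] = xp[:, i:i + h, j:j + w, :]
        return cols.reshape(n * h * w, k * k * c)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (self.pad_before, self.pad_after),
                        (self.pad_before, self.pad_after), (0, 0)))
        cols = self._im2col(xp, h, w)
        if train:
            self._cols = cols
            self._xshape = x.shape
        y = cols @ self.params["W"] + self.params["b"]
        return y.reshape(n, h, w, self.cout)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, _ = dy.shape
        k, c = self.k, self.cin
        dy2 = dy.reshape(n * h * w, self.cout)
        self.grads["W"] = (self._cols.T @ dy2).astype(np.float32)
        self.grads["b"] = dy2.sum(axis=0).astype(np.float32)
        dcols = (dy2 @ self.params["W"].T).reshape(n, h, w, k, k, c)
        hp = h + self.pad_before + self.pad_after
        wp = w + self.pad_before + self.pad_after
        dxp = np.zeros((n, hp, wp, c), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, i:i + h, j:j + w, :] += dcols[:, :, :, i, j, :]
        del self._cols
        return dxp[:, self.pad_before:self.pad_before + h,
                   self.pad_before:self.pad_before + w, :]


class Dense(Layer):
    def __init__(self, fin: int, fout: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / fin)
        self.params["W"] = rng.normal(0, scale, (fin, fout)).astype(np.float32)
        self.params["b"] = np.zeros(fout, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] = (self._x.T @ dy).astype(np.float32)
        self.grads["b"] = dy.sum(axis=0).astype(np.float32)
        return dy @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        if train:
            self._y = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._y * (1.0 - self._y)


class MaxPool2(Layer):
    """2x2 max pooling, stride 2 (spatial dims must be even)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        xr = xr.reshape(n, h // 2, w // 2, 4, c)
        idx = xr.argmax(axis=3)
        y = np.take_along_axis(xr, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
        if train:
            self._idx = idx
            self._xshape = x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = self._xshape
        dxr = np.zeros((n, h // 2, w // 2, 4, c), dtype=dy.dtype)
        np.put_along_axis(dxr, self._idx[:, :, :, None, :],
                          dy[:, :, :, None, :], axis=3)
        dx = dxr.reshape(n, h // 2, w // 2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        return dx.reshape(n, h, w, c)


class Upsample2(Layer):
    """2x nearest-neighbour upsampling."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, h, w, c = dy.shape
        return dy.reshape(n, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4))


class AvgPool(Layer):
    """Average pooling by an integer factor (front-end downscaling)."""

    def __init__(self, factor: int):
        super().__init__()
        self.factor = factor

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        f = self.factor
        if f == 1:
            return x
        n, h, w, c = x.shape
        return x.reshape(n, h // f, f, w // f, f, c).mean(axis=(2, 4))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        f = self.factor
        if f == 1:
            return dy
        return dy.repeat(f, axis=1).repeat(f, axis=2) / (f * f)


class Dropout(Layer):
    """Inverted dropout; active only when ``train`` is set."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class AttentionGate(Layer):
    """Additive attention on a skip connection.

    ``alpha = sigmoid(psi(relu(theta(x) + phi(g))))`` with 1x1 convolutions;
    the gated skip is ``x * alpha``.  ``x`` is the encoder skip feature and
    ``g`` the decoder gating feature at the same spatial resolution.
    """

    def __init__(self, channels: int, rng: np.random.Generator,
                 inter_channels: Optional[int] = None):
        super().__init__()
        ci = inter_channels or max(channels // 2, 1)
        self.theta = Conv2D(channels, ci, 1, rng)
        self.phi = Conv2D(channels, ci, 1, rng)
        self.psi = Conv2D(ci, 1, rng=rng, k=1)
        self.relu = ReLU()
        self.sig = Sigmoid()
        self._subs = [self.theta, self.phi, self.psi]

    @property
    def sublayers(self) -> List[Layer]:
        return self._subs

    def forward(self, x: np.ndarray, g: np.ndarray,
                train: bool = False) -> np.ndarray:
        t = self.theta.forward(x, train)
        p = self.phi.forward(g, train)
        a = self.relu.forward(t + p, train)
        a = self.psi.forward(a, train)
        alpha = self.sig.forward(a, train)
        if train:
            self._x = x
            self._alpha = alpha
        return x * alpha

    def backward(self, dy: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        dx_direct = dy * self._alpha
        dalpha = (dy * self._x).sum(axis=3, keepdims=True)
        da = self.sig.backward(dalpha)
        da = self.psi.backward(da)
        da = self.relu.backward(da)
        dx_att = self.theta.backward(da)
        dg = self.phi.backward(da)
        return dx_direct + dx_att, dg


class Sequential:
    """A plain layer chain with shared forward/backward plumbing."""

    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def param_layers(self) -> List[Layer]:
        out = []
        for layer in self.layers:
            if isinstance(layer, AttentionGate):
                out.extend(layer.sublayers)
            elif layer.params:
                out.append(layer)
        return out


class Adam:
    """Adam optimizer over a collection of layers' parameter dicts."""

    def __init__(self, layers: Sequence[Layer], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.layers = list(layers)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()}
                  for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()}
                  for l in self.layers]

    def step(self) -> None:
        self.t += 1
        for i, layer in enumerate(self.layers):
            for key, param in layer.params.items():
                g = layer.grads.get(key)
                if g is None:
                    continue
                m = self.m[i][key] = self.b1 * self.m[i][key] + (1 - self.b1) * g
                v = self.v[i][key] = self.b2 * self.v[i][key] + (1 - self.b2) * g * g
                mhat = m / (1 - self.b1**self.t)
                vhat = v / (1 - self.b2**self.t)
                param -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ----------------------------------------------------------------------------
# Segmentation losses on probability maps.
# Each returns (scalar, dL/dp) with p the probability array.


def bce_loss(p: np.ndarray, t: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean binary cross-entropy and its gradient w.r.t. probabilities."""
    pc = np.clip(p, _EPS, 1 - _EPS)
    n = p.size
    loss = float(-(t * np.log(pc) + (1 - t) * np.log(1 - pc)).mean())
    grad = (pc - t) / (pc * (1 - pc)) / n
    return loss, grad


def dice_loss(p: np.ndarray, t: np.ndarray,
              smooth: float = 1.0) -> Tuple[float, np.ndarray]:
    """Soft Dice loss ``1 - (2*sum(pt)+s)/(sum(p)+sum(t)+s)`` and gradient."""
    inter = float((p * t).sum())
    denom = float(p.sum() + t.sum()) + smooth
    dice = (2.0 * inter + smooth) / denom
    grad = -(2.0 * t * denom - (2.0 * inter + smooth)) / denom**2
    return float(1.0 - dice), grad


def ac_length_term(p: np.ndarray, eps: float = 1e-8) -> float:
    """Boundary-length energy: sum over pixels of |grad p| (forward diffs).

    On a {0,1} rasterized region this approximates the region's perimeter.
    """
    ux = np.diff(p, axis=1, append=p[:, -1:])
    uy = np.diff(p, axis=0, append=p[-1:, :])
    return float(np.sqrt(ux * ux + uy * uy + eps).sum())


def active_contour_loss(p: np.ndarray, t: np.ndarray,
                        lambda_region: float = 1.0,
                        eps: float = 1e-8) -> Tuple[float, np.ndarray]:
    """Active-contour loss: normalized boundary length + region energies.

    ``L = (length + lambda * (sum p*(t-1)^2 + sum (1-p)*t^2)) / N`` where the
    region terms use the constant inside/outside intensities c1=1, c2=0 of a
    binary target.  Returns the scalar and the gradient w.r.t. ``p``.
    """
    n = p.size
    ux = np.diff(p, axis=1, append=p[:, -1:])
    uy = np.diff(p, axis=0, append=p[-1:, :])
    mag = np.sqrt(ux * ux + uy * uy + eps)
    length = float(mag.sum())
    region_in = (t - 1.0) ** 2
    region_out = t**2
    region = float((p * region_in + (1.0 - p) * region_out).sum())
    loss = (length + lambda_region * region) / n

    # adjoint of the forward-difference length term
    gx = ux / mag
    gy = uy / mag
    dlen = np.zeros_like(p)
    dlen[:, :-1] -= gx[:, :-1]
    dlen[:, 1:] += gx[:, :-1]
    dlen[:-1, :] -= gy[:-1, :]
    dlen[1:, :] += gy[:-1, :]
    grad = (dlen + lambda_region * (region_in - region_out)) / n
    return loss, grad


# ----------------------------------------------------------------------------
# Parameter (de)serialization


def save_params(path: str, layers: Sequence[Layer], meta: dict) -> None:
    """Write all layer parameters to ``<path>.npz`` plus a JSON sidecar."""
    arrays = {}
    for i, layer in enumerate(layers):
        for key, value in layer.params.items():
            arrays[f"layer{i}_{key}"] = value
    np.savez(path + ".npz", **arrays)
    with open(path + ".json", "w") as fh:
        json.dump(meta, fh, indent=2, default=str)


def load_params(path: str, layers: Sequence[Layer]) -> dict:
    """Load parameters saved by :func:`save_params` into ``layers``."""
    data = np.load(path + ".npz")
    for i, layer in enumerate(layers):
        for key in layer.params:
            layer.params[key][...] = data[f"layer{i}_{key}"]
    meta = {}
    if os.path.exists(path + ".json"):
        with open(path + ".json") as fh:
            meta = json.load(fh)
    return meta
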
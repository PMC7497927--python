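"""Minimal CNN layer stack with explicit forward/backward passes.

The lesion-patch classifier used throughout this package is a LeNet-scale
network (two convolutions, two max-pools, three dense maps onto a single
sigmoid unit).  At that scale a compact, fully inspectable numpy
implementation is preferable to a deep-learning framework: every quantity
the method needs later — the gradient of the output logit with respect to
the *input pixels* (activation maximization) and with respect to the last
convolutional feature maps (Grad-CAM) — is exposed directly by the
backward pass instead of being dug out of framework hooks.

All arrays are float64.  Layers cache what their backward pass needs on
``forward``; a full ``backward`` both accumulates parameter gradients and
returns the gradient with respect to the layer input.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2d",
    "MaxPool2d",
    "ReLU",
    "Flatten",
    "Linear",
    "Sequential",
    "sigmoid",
    "bce_loss",
    "batch_cost",
    "sgdm_step",
]


def sigmoid(z: np.ndarray | float) -> np.ndarray | float:
    """Numerically stable logistic function."""
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


_CLAMP = 1e-7


def bce_loss(h, y):
    """Binary cross-entropy −(y·log h + (1−y)·log(1−h)) for a single pair
    or elementwise over arrays.

    Probabilities are clamped to [1e−7, 1−1e−7] before the logs so that a
    saturated prediction yields a large finite loss instead of inf.
    Raises ``ValueError`` if ``h`` lies outside [0, 1].
    """
    h = np.asarray(h, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(h < 0.0) or np.any(h > 1.0):
        raise ValueError("predicted probability outside [0, 1]")
    hc = np.clip(h, _CLAMP, 1.0 - _CLAMP)
    return -(y * np.log(hc) + (1.0 - y) * np.log(1.0 - hc))


def batch_cost(h, y):
    """Mean binary cross-entropy over a batch."""
    return float(np.mean(bce_loss(h, y)))


class Layer:
    """Base class: parameter-free layers only override forward/backward."""

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv2d(Layer):
    """2D convolution (cross-correlation, the deep-learning convention).

    Forward uses an im2col reshape and a single matmul; backward scatters
    the column gradient back with one slice-add per kernel offset.
    """

    def __init__(self, in_ch: int, out_ch: int, ksize: int, stride: int = 1,
                 pad: int = 0, *, rng: np.random.Generator):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.k, self.stride, self.pad = ksize, stride, pad
        fan_in = in_ch * ksize * ksize
        bound = 1.0 / np.sqrt(fan_in)
        self.W = rng.uniform(-bound, bound, size=(out_ch, in_ch, ksize, ksize))
        self.b = rng.uniform(-bound, bound, size=out_ch)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x):
        n, c, h, w = x.shape
        k, s, p = self.k, self.stride, self.pad
        if p:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        else:
            xp = x
        ho = (h + 2 * p - k) // s + 1
        wo = (w + 2 * p - k) // s + 1
        # (n, c, ho, wo, k, k) view, then flatten to im2col matrix
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho * wo, c * k * k)
        wmat = self.W.reshape(self.out_ch, -1)
        out = cols @ wmat.T + self.b
        self._cache = (cols, xp.shape, (n, c, h, w), (ho, wo))
        return out.transpose(0, 2, 1).reshape(n, self.out_ch, ho, wo)

    def backward(self, dout):
        cols, xp_shape, x_shape, (ho, wo) = self._cache
        n, c, h, w = x_shape
        k, s, p = self.k, self.stride, self.pad
        dmat = dout.reshape(n, self.out_ch, ho * wo).transpose(0, 2, 1)
        wmat = self.W.reshape(self.out_ch, -1)
        self.dW += (dmat.reshape(-1, self.out_ch).T
                    @ cols.reshape(-1, c * k * k)).reshape(self.W.shape)
        self.db += dout.sum(axis=(0, 2, 3))
        dcols = dmat @ wmat  # (n, ho*wo, c*k*k)
        dcols = dcols.reshape(n, ho, wo, c, k, k).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros(xp_shape)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + ho * s:s, j:j + wo * s:s] += dcols[..., i, j]
        if p:
            return dxp[:, :, p:-p, p:-p]
        return dxp


class MaxPool2d(Layer):
    """Non-overlapping max pooling (kernel = stride)."""

    def __init__(self, ksize: int = 2):
        self.k = ksize
        self._cache = None

    def forward(self, x):
        n, c, h, w = x.shape
        k = self.k
        ho, wo = h // k, w // k
        xr = (x[:, :, :ho * k, :wo * k]
              .reshape(n, c, ho, k, wo, k)
              .transpose(0, 1, 2, 4, 3, 5)
              .reshape(n, c, ho, wo, k * k))
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, (n, c, h, w))
        return out

    def backward(self, dout):
        idx, (n, c, h, w) = self._cache
        k = self.k
        ho, wo = h // k, w // k
        dxr = np.zeros((n, c, ho, wo, k * k))
        np.put_along_axis(dxr, idx[..., None], dout[..., None], axis=-1)
        return (dxr.reshape(n, c, ho, wo, k, k)
                .transpose(0, 1, 2, 4, 3, 5)
                .reshape(n, c, h, w))


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Flatten(Layer):
    def __init__(self):
        self._shape = None

    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, *, rng: np.random.Generator):
        bound = 1.0 / np.sqrt(n_in)
        self.W = rng.uniform(-bound, bound, size=(n_out, n_in))
        self.b = rng.uniform(-bound, bound, size=n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dout):
        self.dW += dout.T @ self._x
        self.db += dout.sum(axis=0)
        return dout @ self.W


class Sequential:
    """Ordered layer container with named layers.

    ``backward`` propagates a gradient from the output back to the input,
    accumulating parameter gradients on the way, and records the gradient
    seen at every named node in ``last_grads`` (needed by Grad-CAM) and
    the activation at every node in ``last_activations``.
    """

    def __init__(self, layers: list[tuple[str, Layer]]):
        self.layers = layers
        self.last_activations: dict[str, np.ndarray] = {}
        self.last_grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.last_activations = {"input": x}
        for name, layer in self.layers:
            x = layer.forward(x)
            self.last_activations[name] = x
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.last_grads = {}
        for name, layer in reversed(self.layers):
            self.last_grads[name] = dout  # gradient at this layer's output
            dout = layer.backward(dout)
        self.last_grads["input"] = dout
        return dout

    def params(self) -> dict[str, np.ndarray]:
        out = {}
        for name, layer in self.layers:
            for pname, arr in layer.params().items():
                out[f"{name}.{pname}"] = arr
        return out

    def grads(self) -> dict[str, np.ndarray]:
        out = {}
        for name, layer in self.layers:
            for pname, arr in layer.grads().items():
                out[f"{name}.{pname}"] = arr
        return out

    def zero_grads(self) -> None:
        for _, layer in self.layers:
            for arr in layer.grads().values():
                arr[...] = 0.0


def sgdm_step(params: dict[str, np.ndarray], grads: dict[str, np.ndarray],
              velocity: dict[str, np.ndarray], lr: float, momentum: float,
              *, literal: bool = False,
              prev_params: dict[str, np.ndarray] | None = None) -> None:
    """One stochastic-gradient-with-momentum update, in place.

    Default is the conventional heavy-ball form

        v ← ρ·v + g,   θ ← θ − lr·v .

    ``literal=True`` selects instead the damped variant

        θ_{n+1} = θ_n − lr·ρ·(θ_n − θ_{n−1}) − lr·g ,

    which subtracts (rather than adds) the momentum term; it is retained
    only for comparison and requires ``prev_params`` (the θ_{n−1} buffer,
    updated in place to the pre-step θ).
    """
    for key, g in grads.items():
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(f"non-finite gradient in {key!r}")
    if literal:
        if prev_params is None:
            raise ValueError("literal update requires prev_params buffer")
        for key, theta in params.items():
            theta_prev = prev_params[key].copy()
            prev_params[key][...] = theta
            theta -= lr * momentum * (theta - theta_prev) + lr * grads[key]
    else:
        for key, theta in params.items():
            v = velocity[key]
            v *= momentum
            v += grads[key]
            theta -= lr * v
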
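"""A compact numpy convolutional-network engine with manual backpropagation.

Provides exactly what the pipeline needs: small stride-2 conv stacks trained
with Adam on multi-label binary cross-entropy, and input gradients of
arbitrary interior activations (the effective-receptive-field estimator
backpropagates from the center pixel of the final convolutional layer).
Convolutions run as im2col + BLAS matmul in float32; batches are processed
in micro-chunks to bound the im2col buffer.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2D", "ReLU", "GlobalAvgPool", "Dense", "Sequential", "Adam",
           "bce_with_logits", "sigmoid"]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy from logits; returns (loss, dloss/dlogits)."""
    z = np.asarray(logits, dtype=np.float64)
    y = np.asarray(targets, dtype=np.float64)
    # log(1+exp(-|z|)) + max(z,0) - z*y is the stable elementwise form
    loss = np.mean(np.log1p(np.exp(-np.abs(z))) + np.maximum(z, 0.0) - z * y)
    grad = (sigmoid(z) - y) / z.size
    return float(loss), grad


class Conv2D:
    """3x3-style convolution with zero padding; linear (no activation)."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int = 3, stride: int = 1,
                 pad: int | None = None, bias: bool = True,
                 rng: np.random.Generator | None = None):
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride = kernel, stride
        self.pad = (kernel - 1) // 2 if pad is None else pad
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        self.W = (rng.standard_normal((out_ch, in_ch, kernel, kernel))
                  * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32) if bias else None
        self._cache = None

    @property
    def params(self):
        return [self.W] if self.b is None else [self.W, self.b]

    def set_weights(self, W: np.ndarray, b: np.ndarray | None = None) -> None:
        self.W = np.asarray(W, dtype=np.float32).reshape(self.W.shape)
        if b is not None:
            self.b = np.asarray(b, dtype=np.float32)

    def out_shape(self, h: int, w: int) -> tuple[int, int]:
        k, s, p = self.kernel, self.stride, self.pad
        return ((h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1)

    def _cols(self, x: np.ndarray) -> np.ndarray:
        k, s, p = self.kernel, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        return win  # (N, C, Ho, Wo, k, k)

    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        n = x.shape[0]
        ho, wo = self.out_shape(x.shape[2], x.shape[3])
        win = self._cols(x.astype(np.float32, copy=False))
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, -1)
        y = cols @ self.W.reshape(self.out_ch, -1).T
        if self.b is not None:
            y += self.b
        if keep:
            self._cache = (x.shape, cols)
        return y.reshape(n, ho, wo, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray, grads: list | None = None) -> np.ndarray:
        xshape, cols = self._cache
        n, _, h, w = xshape
        k, s, p = self.kernel, self.stride, self.pad
        ho, wo = self.out_shape(h, w)
        dyf = dy.transpose(0, 2, 3, 1).reshape(n * ho * wo, self.out_ch)
        if grads is not None:
            dW = (dyf.T @ cols).reshape(self.W.shape)
            grads.append(dW)
            if self.b is not None:
                grads.append(dyf.sum(axis=0))
        dcols = dyf @ self.W.reshape(self.out_ch, -1)  # (N*Ho*Wo, C*k*k)
        dcols = dcols.reshape(n, ho, wo, self.in_ch, k, k)
        dxp = np.zeros((n, self.in_ch, h + 2 * p, w + 2 * p), dtype=np.float32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + s * ho : s, j : j + s * wo : s] += dcols[
                    :, :, :, :, i, j
                ].transpose(0, 3, 1, 2)
        return dxp[:, :, p : p + h, p : p + w]


class ReLU:
    params: list = []

    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if keep:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray, grads: list | None = None) -> np.ndarray:
        return dy * self._mask


class Square:
    """x -> x^2 elementwise; an energy (rectifying) nonlinearity.

    As the first-block activation it turns the block into a learned
    quadrature-energy detector, which picks up band-limited texture
    regardless of phase and orientation far faster than ReLU stacks do.
    """

    params: list = []

    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        if keep:
            self._x = x
        return x * x

    def backward(self, dy: np.ndarray, grads: list | None = None) -> np.ndarray:
        return 2.0 * dy * self._x


class GlobalAvgPool:
    params: list = []

    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        if keep:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray, grads: list | None = None) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(
            (dy / (h * w))[:, :, None, None], self._shape
        ).astype(np.float32)


class Dense:
    def __init__(self, in_dim: int, out_dim: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = (rng.standard_normal((out_dim, in_dim))
                  * np.sqrt(2.0 / in_dim)).astype(np.float32)
        self.b = np.zeros(out_dim, dtype=np.float32)

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        if keep:
            self._x = x
        return x @ self.W.T + self.b

    def backward(self, dy: np.ndarray, grads: list | None = None) -> np.ndarray:
        if grads is not None:
            grads.append(dy.T @ self._x)
            grads.append(dy.sum(axis=0))
        return dy @ self.W


class Sequential:
    """A feed-forward stack of the layers above."""

    def __init__(self, layers: list):
        self.layers = layers

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def forward(self, x: np.ndarray, keep: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, keep=keep)
        return x

    def backward(self, dy: np.ndarray) -> tuple[list[np.ndarray], np.ndarray]:
        """Backprop from the output; returns (param grads in param order, dx)."""
        grads_rev: list[np.ndarray] = []
        for layer in reversed(self.layers):
            layer_grads: list = []
            dy = layer.backward(dy, grads=layer_grads)
            grads_rev.extend(reversed(layer_grads))
        return list(reversed(grads_rev)), dy

    def last_conv_index(self) -> int:
        idx = [i for i, l in enumerate(self.layers) if isinstance(l, Conv2D)]
        if not idx:
            raise ValueError("model has no convolutional layer")
        return idx[-1]

    def activation_input_gradient(
        self, x: np.ndarray, layer_index: int, channel: int,
        position: tuple[int, int] | None = None, after_activation: bool = True,
    ) -> np.ndarray:
        """Gradient of one activation pixel w.r.t. the input, per image.

        Runs forward through ``layer_index`` (optionally through the
        following elementwise activation), seeds a one-hot gradient at
        ``position`` (default: spatial center) of ``channel``, and
        backpropagates to the input. Returns an array shaped like ``x``.
        """
        stop = layer_index
        if after_activation and layer_index + 1 < len(self.layers) and isinstance(
            self.layers[layer_index + 1], ReLU
        ):
            stop = layer_index + 1
        h = x
        for layer in self.layers[: stop + 1]:
            h = layer.forward(h, keep=True)
        if h.ndim != 4:
            raise ValueError("probed layer must output a spatial map")
        cy, cx = position if position is not None else (h.shape[2] // 2, h.shape[3] // 2)
        seed = np.zeros_like(h)
        seed[:, channel, cy, cx] = 1.0
        dy = seed
        for layer in reversed(self.layers[: stop + 1]):
            dy = layer.backward(dy, grads=None)
        return dy


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g = g.astype(p.dtype, copy=False)
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)


def tiny_cnn(
    in_ch: int,
    n_findings: int,
    channels: tuple[int, ...] = (8, 16, 16),
    seed: int = 0,
    first_activation: str = "square",
) -> Sequential:
    """The desk-scale backbone: 3 stride-2 conv blocks, GAP, linear head.

    The first block's activation defaults to :class:`Square` (energy
    detection); later blocks use ReLU.
    """
    rng = np.random.default_rng(seed)
    layers: list = []
    c_prev = in_ch
    for i, c in enumerate(channels):
        conv = Conv2D(c_prev, c, kernel=3, stride=2, rng=rng)
        if i == 0:
            # zero-DC kernels: reject smooth shading at init so band-limited
            # structure is visible to the energy nonlinearity from step one
            conv.W -= conv.W.mean(axis=(2, 3), keepdims=True)
        layers.append(conv)
        if i == 0 and first_activation == "square":
            layers.append(Square())
        else:
            layers.append(ReLU())
        c_prev = c
    layers.append(GlobalAvgPool())
    layers.append(Dense(c_prev, n_findings, rng=rng))
    return Sequential(layers)
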
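"""A self-contained NumPy implementation of a 1D U-Net for signal restoration.

The network maps a length-64 saturated AIF (one channel) to the
corresponding unsaturated AIF.  It is a standard U-Net: five resolution
steps, each made of two convolutional blocks (1D convolution, batch
normalization, ReLU, dropout p=0.2); 1D max-pooling halves the length
between encoder steps and transposed convolutions restore it in the
decoder, with channel-concatenation skip connections; a final 1x1
convolution projects back to one channel.  Channels double per step from
``base_channels``.

All layers implement explicit forward and backward passes (verified by
finite-difference gradient checks in the test suite) and a hand-written
Adam optimizer drives training.  Computation is single-precision
throughout; everything is driven by explicit ``numpy.random.Generator``
instances, so runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["UNetConfig", "UNet1D", "Adam", "build_unet", "mse_loss"]

_DTYPE = np.float32


@dataclass(frozen=True)
class UNetConfig:
    """Architecture hyper-parameters.

    ``depth`` counts resolution steps including the bottleneck, so the
    length is halved ``depth - 1`` times; ``input_length`` must be
    divisible by ``2**(depth-1)``.
    """

    depth: int = 5
    base_channels: int = 32
    kernel_size: int = 3
    dropout_p: float = 0.2
    input_length: int = 64

    def __post_init__(self):
        if self.input_length % 2 ** (self.depth - 1) != 0:
            raise ValueError(
                f"input_length {self.input_length} not divisible by 2^(depth-1) = {2 ** (self.depth - 1)}"
            )
        if not 0 <= self.dropout_p < 1:
            raise ValueError("dropout_p must be in [0, 1)")
        if self.kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd (same-padding convolutions)")

    def to_dict(self) -> dict:
        return {
            "depth": self.depth,
            "base_channels": self.base_channels,
            "kernel_size": self.kernel_size,
            "dropout_p": self.dropout_p,
            "input_length": self.input_length,
        }


class _Layer:
    params: list
    grads: list

    def __init__(self):
        self.params = []
        self.grads = []

    def forward(self, x, training, rng):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, gy):  # pragma: no cover - interface
        raise NotImplementedError

    def buffers(self) -> list:
        return []


class Conv1d(_Layer):
    """Same-padded 1D convolution, stride 1, He-normal initialized."""

    def __init__(self, cin, cout, k, rng):
        super().__init__()
        std = np.sqrt(2.0 / (cin * k))
        self.w = (rng.standard_normal((cin, k, cout)) * std).astype(_DTYPE)
        self.b = np.zeros(cout, dtype=_DTYPE)
        self.k, self.pad = k, k // 2
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, training, rng):
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        self._cols = sliding_window_view(xp, self.k, axis=2)  # (N, C, L, k)
        y = np.einsum("nclk,ckf->nfl", self._cols, self.w, optimize=True)
        return y + self.b[None, :, None]

    def backward(self, gy):
        gy = gy.astype(_DTYPE)
        self.grads[0][...] = np.einsum("nclk,nfl->ckf", self._cols, gy, optimize=True)
        self.grads[1][...] = gy.sum(axis=(0, 2))
        n, _, length = gy.shape
        cin = self.w.shape[0]
        gxp = np.zeros((n, cin, length + 2 * self.pad), dtype=_DTYPE)
        for ki in range(self.k):
            gxp[:, :, ki : ki + length] += np.einsum(
                "nfl,cf->ncl", gy, self.w[:, ki, :], optimize=True
            )
        return gxp[:, :, self.pad : self.pad + length]


class ConvTranspose1d(_Layer):
    """Kernel-2 stride-2 transposed convolution (length doubling)."""

    def __init__(self, cin, cout, rng):
        super().__init__()
        std = np.sqrt(2.0 / (cin * 2))
        self.w = (rng.standard_normal((cin, cout, 2)) * std).astype(_DTYPE)
        self.b = np.zeros(cout, dtype=_DTYPE)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, training, rng):
        self._x = x
        n, _, length = x.shape
        t = np.einsum("ncl,cfk->nflk", x, self.w, optimize=True)
        y = t.reshape(n, self.w.shape[1], 2 * length)
        return y + self.b[None, :, None]

    def backward(self, gy):
        gy = gy.astype(_DTYPE)
        n, cout, l2 = gy.shape
        gt = gy.reshape(n, cout, l2 // 2, 2)
        self.grads[0][...] = np.einsum("ncl,nflk->cfk", self._x, gt, optimize=True)
        self.grads[1][...] = gy.sum(axis=(0, 2))
        return np.einsum("nflk,cfk->ncl", gt, self.w, optimize=True)


class BatchNorm1d(_Layer):
    def __init__(self, c, momentum=0.1, eps=1e-5):
        super().__init__()
        self.gamma = np.ones(c, dtype=_DTYPE)
        self.beta = np.zeros(c, dtype=_DTYPE)
        self.running_mean = np.zeros(c, dtype=_DTYPE)
        self.running_var = np.ones(c, dtype=_DTYPE)
        self.momentum, self.eps = momentum, eps
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]

    def buffers(self):
        return [self.running_mean, self.running_var]

    def forward(self, x, training, rng):
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean[...] = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var[...] = (1 - self.momentum) * self.running_var + self.momentum * var
            self._invstd = (1.0 / np.sqrt(var + self.eps)).astype(_DTYPE)
            self._xhat = (x - mean[None, :, None]) * self._invstd[None, :, None]
            return self.gamma[None, :, None] * self._xhat + self.beta[None, :, None]
        invstd = 1.0 / np.sqrt(self.running_var + self.eps)
        xhat = (x - self.running_mean[None, :, None]) * invstd[None, :, None]
        return self.gamma[None, :, None] * xhat + self.beta[None, :, None]

    def backward(self, gy):
        gy = gy.astype(_DTYPE)
        m = gy.shape[0] * gy.shape[2]
        ghat = gy * self.gamma[None, :, None]
        sum_ghat = ghat.sum(axis=(0, 2), keepdims=True)
        sum_ghat_xhat = (ghat * self._xhat).sum(axis=(0, 2), keepdims=True)
        gx = (self._invstd[None, :, None] / m) * (
            m * ghat - sum_ghat - self._xhat * sum_ghat_xhat
        )
        self.grads[0][...] = (gy * self._xhat).sum(axis=(0, 2))
        self.grads[1][...] = gy.sum(axis=(0, 2))
        return gx.astype(_DTYPE)


class ReLU(_Layer):
    def forward(self, x, training, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy):
        return gy * self._mask


class Dropout(_Layer):
    def __init__(self, p):
        super().__init__()
        self.p = p

    def forward(self, x, training, rng):
        if not training or self.p == 0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (rng.random(x.shape) < keep).astype(_DTYPE) / keep
        return x * self._mask

    def backward(self, gy):
        return gy if self._mask is None else gy * self._mask


class MaxPool1d(_Layer):
    """Kernel-2 stride-2 max pooling."""

    def forward(self, x, training, rng):
        n, c, length = x.shape
        xr = x.reshape(n, c, length // 2, 2)
        self._idx = xr.argmax(axis=3)
        self._shape = xr.shape
        return np.take_along_axis(xr, self._idx[..., None], axis=3)[..., 0]

    def backward(self, gy):
        gxr = np.zeros(self._shape, dtype=_DTYPE)
        np.put_along_axis(gxr, self._idx[..., None], gy[..., None].astype(_DTYPE), axis=3)
        n, c, lh, _ = self._shape
        return gxr.reshape(n, c, lh * 2)


class _Sequential(_Layer):
    def __init__(self, layers):
        super().__init__()
        self.layers = layers

    def forward(self, x, training, rng):
        for layer in self.layers:
            x = layer.forward(x, training, rng)
        return x

    def backward(self, gy):
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy

    def all_layers(self):
        return self.layers


def _conv_block(cin, cout, k, p, rng):
    return [Conv1d(cin, cout, k, rng), BatchNorm1d(cout), ReLU(), Dropout(p)]


def _double_conv(cin, cout, k, p, rng):
    return _Sequential(_conv_block(cin, cout, k, p, rng) + _conv_block(cout, cout, k, p, rng))


class UNet1D:
    """1D U-Net mapping (N, 1, L) to (N, 1, L)."""

    def __init__(self, config: UNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        d, k, p = config.depth, config.kernel_size, config.dropout_p
        chans = [config.base_channels * 2**i for i in range(d)]

        self.enc_blocks, self.pools = [], []
        cin = 1
        for c in chans[:-1]:
            self.enc_blocks.append(_double_conv(cin, c, k, p, rng))
            self.pools.append(MaxPool1d())
            cin = c
        self.bottom = _double_conv(cin, chans[-1], k, p, rng)

        self.ups, self.dec_blocks = [], []
        for c_skip in reversed(chans[:-1]):  # deepest decoder level first
            self.ups.append(ConvTranspose1d(2 * c_skip, c_skip, rng))
            self.dec_blocks.append(_double_conv(2 * c_skip, c_skip, k, p, rng))
        self.head = Conv1d(chans[0], 1, 1, rng)
        self._skip_chans = list(reversed(chans[:-1]))

    # ----- plumbing -----
    def _layers(self):
        out = []
        for blk in self.enc_blocks:
            out.extend(blk.all_layers())
        out.extend(self.bottom.all_layers())
        for up, dec in zip(self.ups, self.dec_blocks):
            out.append(up)
            out.extend(dec.all_layers())
        out.append(self.head)
        return out

    def parameters(self):
        return [p for layer in self._layers() for p in layer.params]

    def gradients(self):
        return [g for layer in self._layers() for g in layer.grads]

    def buffers(self):
        return [b for layer in self._layers() for b in layer.buffers()]

    @property
    def n_params(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def get_state(self):
        """All arrays defining inference behaviour (weights + BN statistics)."""
        return [a.copy() for a in self.parameters() + self.buffers()]

    def set_state(self, state):
        arrays = self.parameters() + self.buffers()
        if len(state) != len(arrays):
            raise ValueError("state length mismatch")
        for dst, src in zip(arrays, state):
            dst[...] = src

    # ----- forward / backward -----
    def forward(self, x, training=False, rng=None):
        x = np.ascontiguousarray(x, dtype=_DTYPE)
        skips = []
        h = x
        for blk, pool in zip(self.enc_blocks, self.pools):
            h = blk.forward(h, training, rng)
            skips.append(h)
            h = pool.forward(h, training, rng)
        h = self.bottom.forward(h, training, rng)
        for up, dec, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            h = up.forward(h, training, rng)
            h = np.concatenate([skip, h], axis=1)
            h = dec.forward(h, training, rng)
        return self.head.forward(h, training, rng)

    def backward(self, gy):
        g = self.head.backward(gy)
        # walk the decoder in reverse order of application (top level first);
        # gskips[i] ends up holding the gradient flowing into skips[i]
        gskips = []
        for up, dec, c_skip in zip(self.ups[::-1], self.dec_blocks[::-1], self._skip_chans[::-1]):
            g = dec.backward(g)
            gskips.append(g[:, :c_skip])
            g = up.backward(g[:, c_skip:])
        g = self.bottom.backward(g)
        for blk, pool, gskip in zip(self.enc_blocks[::-1], self.pools[::-1], gskips[::-1]):
            g = pool.backward(g)
            g = blk.backward(g + gskip)
        return g

    def predict(self, x):
        """Inference-mode forward pass (dropout off, BN in evaluation state)."""
        return self.forward(x, training=False)


def build_unet(config: UNetConfig | None = None, seed: int = 0) -> UNet1D:
    return UNet1D(config or UNetConfig(), seed=seed)


def mse_loss(pred, target):
    """Mean squared error and its gradient with respect to ``pred``."""
    diff = (pred - target).astype(_DTYPE)
    loss = float(np.mean(diff**2))
    grad = (2.0 / diff.size) * diff
    return loss, grad


class Adam:
    """Adam optimizer over a parameter/gradient list."""

    def __init__(self, params, grads, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params, self.grads = params, grads
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1 - b1**self.t
        bias2 = 1 - b2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
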
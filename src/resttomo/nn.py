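"""Minimal 3D convolutional network machinery in NumPy.

Implements exactly what the volumetric restoration U-Net needs — 3×3×3
convolutions, leaky ReLU, 2× max pooling, nearest-neighbour upsampling — with
explicit forward/backward passes and an Adam optimiser.  Activations are kept
channels-last ``(N, D, H, W, C)`` so a k³ convolution reduces to k³ shifted
matrix products against ``(C_in, C_out)`` kernel slices, which avoids the
large im2col buffer copies that dominate on a single CPU core.  The input
gradient is the exact full correlation with the spatially flipped,
channel-transposed kernels, computed through the same shifted-product path.

Everything is deterministic given the initialisation seed: no dropout, no
nondeterministic reductions, pure NumPy arithmetic in float32.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv3d", "LeakyReLU", "MaxPool3d", "Upsample3d", "Adam"]


class Conv3d:
    """'Same'-padded 3D convolution (cross-correlation), stride 1.

    Activations are ``(N, D, H, W, C)``; the kernel is stored as
    ``(C_out, C_in, k, k, k)`` (the conventional layout, used for
    checkpoints) and applied slice-wise.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int = 3,
                 rng: np.random.Generator | None = None) -> None:
        self.c_in, self.c_out, self.k = c_in, c_out, kernel
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kernel**3
        self.weight = (rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                  (c_out, c_in, kernel, kernel, kernel))
                       .astype(np.float32))
        self.bias = np.zeros(c_out, dtype=np.float32)
        self.grad_weight = np.zeros_like(self.weight)
        self.grad_bias = np.zeros_like(self.bias)
        self._xpad: np.ndarray | None = None

    def params(self):
        return [(self.weight, self.grad_weight), (self.bias, self.grad_bias)]

    @property
    def n_params(self) -> int:
        return self.weight.size + self.bias.size

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, d, h, w, c = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p), (0, 0))) if p else x
        out = np.empty((n, d, h, w, self.c_out), dtype=np.float32)
        out[...] = self.bias
        for dz in range(self.k):
            for dy in range(self.k):
                for dx in range(self.k):
                    seg = xp[:, dz:dz + d, dy:dy + h, dx:dx + w, :]
                    out += seg @ self.weight[:, :, dz, dy, dx].T
        self._xpad = xp if train else None
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, d, h, w, co = dy.shape
        xp = self._xpad
        p = self.k // 2
        sum_axes = ([0, 1, 2, 3], [0, 1, 2, 3])
        self.grad_bias += dy.sum(axis=(0, 1, 2, 3))
        dyp = np.pad(dy, ((0, 0), (p, p), (p, p), (p, p), (0, 0))) if p else dy
        dx_out = np.zeros(
            (n, d, h, w, self.c_in), dtype=np.float32
        )
        for dz in range(self.k):
            for dyy in range(self.k):
                for dxx in range(self.k):
                    seg = xp[:, dz:dz + d, dyy:dyy + h, dxx:dxx + w, :]
                    self.grad_weight[:, :, dz, dyy, dxx] += np.tensordot(
                        dy, seg, axes=sum_axes
                    )
                    seg_dy = dyp[:, dz:dz + d, dyy:dyy + h, dxx:dxx + w, :]
                    dx_out += seg_dy @ self.weight[
                        :, :, self.k - 1 - dz, self.k - 1 - dyy, self.k - 1 - dxx
                    ]
        self._xpad = None
        return dx_out


class LeakyReLU:
    def __init__(self, slope: float = 0.1) -> None:
        self.slope = slope
        self._mask: np.ndarray | None = None

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        mask = x >= 0
        y = np.where(mask, x, np.float32(self.slope) * x)
        if train:
            self._mask = mask
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, np.float32(self.slope) * dy)


class MaxPool3d:
    """2× max pooling; the backward pass routes gradients to the argmax."""

    def __init__(self) -> None:
        self._idx: np.ndarray | None = None
        self._shape: tuple | None = None

    def params(self):
        return []

    @staticmethod
    def _blocks(x: np.ndarray) -> np.ndarray:
        n, d, h, w, c = x.shape
        return (
            x.reshape(n, d // 2, 2, h // 2, 2, w // 2, 2, c)
            .transpose(0, 1, 3, 5, 7, 2, 4, 6)
            .reshape(n, d // 2, h // 2, w // 2, c, 8)
        )

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        blocks = self._blocks(x)
        idx = blocks.argmax(axis=-1)
        y = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx, self._shape = idx, x.shape
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, d, h, w, c = self._shape
        blocks = np.zeros((n, d // 2, h // 2, w // 2, c, 8), dtype=dy.dtype)
        np.put_along_axis(blocks, self._idx[..., None], dy[..., None], axis=-1)
        return (
            blocks.reshape(n, d // 2, h // 2, w // 2, c, 2, 2, 2)
            .transpose(0, 1, 5, 2, 6, 3, 7, 4)
            .reshape(n, d, h, w, c)
        )


class Upsample3d:
    """2× nearest-neighbour upsampling; backward is 2³ sum pooling."""

    def params(self):
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.repeat(2, axis=1).repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, d, h, w, c = dy.shape
        return dy.reshape(n, d // 2, 2, h // 2, 2, w // 2, 2, c).sum(axis=(2, 4, 6))


class Adam:
    """Adam with bias correction; operates in-place on (param, grad) pairs."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in self.params]
        self.v = [np.zeros_like(p) for p, _ in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for (p, g), m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for _, g in self.params:
            g[...] = 0.0
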
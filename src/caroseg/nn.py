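"""Minimal CPU deep-learning core: 2D convolution, batch normalization,
max-pooling, transposed convolution, a U-Net assembled from those blocks,
and an Adam optimizer, all in numpy with hand-written backpropagation.

Shapes follow the (batch, channel, height, width) convention in float32.
Convolutions are 3x3 stride-1 same-padding; down-sampling is 2x2 max-pool
stride 2; up-sampling is 2x2 transposed convolution stride 2. The im2col /
GEMM formulation keeps the arithmetic in BLAS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Sequence

import numba
import numpy as np


@numba.njit(cache=False)
def _im2col_kernel(xp, k, out):  # pragma: no cover - exercised via wrapper
    b_n, c_n, hp, wp = xp.shape
    h_n, w_n = hp - k + 1, wp - k + 1
    for c in range(c_n):
        for i in range(k):
            for j in range(k):
                f = (c * k + i) * k + j
                for b in range(b_n):
                    base = b * h_n * w_n
                    for h in range(h_n):
                        row = base + h * w_n
                        src = xp[b, c, h + i]
                        for w in range(w_n):
                            out[f, row + w] = src[j + w]


@numba.njit(cache=False)
def _bchw_kernel(src, out):  # pragma: no cover - (O, B*H*W) -> (B, O, H, W)
    o_n, b_n, h_n, w_n = out.shape[1], out.shape[0], out.shape[2], out.shape[3]
    hw = h_n * w_n
    for b in range(b_n):
        for o in range(o_n):
            base = b * hw
            for h in range(h_n):
                row = base + h * w_n
                for w in range(w_n):
                    out[b, o, h, w] = src[o, row + w]


class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value.astype(np.float32)
        self.grad = np.zeros_like(self.value)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, H, W) padded input -> (C*k*k, B*Ho*Wo) patch matrix.

    The batch axis is folded into the GEMM N dimension so one sgemm covers
    the whole batch.
    """
    b, c, h, w = x.shape
    out = np.empty((c * k * k, b * (h - k + 1) * (w - k + 1)),
                   dtype=np.float32)
    _im2col_kernel(np.ascontiguousarray(x, dtype=np.float32), k, out)
    return out


def _conv_gemm(x: np.ndarray, wmat: np.ndarray, k: int, pad: int,
               return_cols: bool = False):
    """Stride-1 correlation of (B, C, H, W) with (O, C*k*k) -> (B, O, H', W')."""
    b = x.shape[0]
    xp = np.pad(x, ((0, 0), (0, 0), (pad,) * 2, (pad,) * 2)) if pad else x
    h, w = xp.shape[2] - k + 1, xp.shape[3] - k + 1
    cols = _im2col(xp, k)
    out = wmat.astype(np.float32, copy=False) @ cols  # (O, B*H*W)
    res = np.empty((b, wmat.shape[0], h, w), dtype=np.float32)
    _bchw_kernel(out, res)
    if return_cols:
        return res, cols
    return res


class Conv2d:
    """3x3 (or kxk) stride-1 convolution with same padding."""

    def __init__(self, cin: int, cout: int, k: int = 3,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        fan_in = cin * k * k
        w = rng.normal(0, math.sqrt(2.0 / fan_in),
                       size=(cout, cin, k, k))
        self.W = Param(w)
        self.b = Param(np.zeros(cout))
        self.k = k
        self.pad = k // 2
        self._cols: np.ndarray | None = None
        self._in_shape: tuple | None = None

    def params(self) -> List[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        wmat = self.W.value.reshape(self.W.value.shape[0], -1)
        if train:
            self._in_shape = x.shape
            out, self._cols = _conv_gemm(x, wmat, self.k, self.pad,
                                         return_cols=True)
        else:
            out = _conv_gemm(x, wmat, self.k, self.pad)
        out += self.b.value[None, :, None, None]
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        bsz, cout, h, w = dy.shape
        dym = np.ascontiguousarray(dy.transpose(1, 0, 2, 3)) \
            .reshape(cout, bsz * h * w)
        self.W.grad += (dym @ self._cols.T).reshape(self.W.value.shape)
        self.b.grad += dy.sum(axis=(0, 2, 3))
        # dx = "full" correlation of dy with the flipped, transposed kernel
        wrot = self.W.value[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)
        wrm = np.ascontiguousarray(wrot).reshape(wrot.shape[0], -1)
        dx = _conv_gemm(dy, wrm, self.k, self.k - 1 - self.pad)
        self._cols = None
        return dx.reshape(self._in_shape)


class BatchNorm2d:
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self) -> List[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(np.float32)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        if train:
            self._cache = (xhat, inv)
        return self.gamma.value[None, :, None, None] * xhat \
            + self.beta.value[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self._cache = None
        n = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.value[None, :, None, None]
        dxhat = dy * g
        m1 = dxhat.sum(axis=(0, 2, 3), keepdims=True) / n
        m2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True) / n
        return inv[None, :, None, None] * (dxhat - m1 - xhat * m2)


class ReLU:
    def __init__(self):
        self._mask = None

    def params(self) -> List[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class MaxPool2d:
    """2x2 stride-2 max pooling (even spatial sizes only)."""

    def __init__(self):
        self._argmax = None
        self._shape = None

    def params(self) -> List[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        b, c, h, w = x.shape
        xr = x.reshape(b, c, h // 2, 2, w // 2, 2)
        flat = xr.transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h // 2, w // 2, 4)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if train:
            self._argmax, self._shape = idx, x.shape
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        flat = np.zeros((b, c, h // 2, w // 2, 4), dtype=dy.dtype)
        np.put_along_axis(flat, self._argmax[..., None], dy[..., None],
                          axis=-1)
        dx = flat.reshape(b, c, h // 2, w // 2, 2, 2) \
            .transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h, w)
        self._argmax = None
        return dx


class ConvTranspose2d:
    """2x2 stride-2 transposed convolution (doubles the spatial size)."""

    def __init__(self, cin: int, cout: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        w = rng.normal(0, math.sqrt(2.0 / cin), size=(cin, cout, 2, 2))
        self.W = Param(w)
        self.b = Param(np.zeros(cout))
        self._x = None

    def params(self) -> List[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        b, c, h, w = x.shape
        # out[b, d, 2h+i, 2w+j] = sum_c x[b,c,h,w] * W[c,d,i,j]
        t = np.tensordot(x, self.W.value, axes=([1], [0]))  # (b,h,w,d,2,2)
        out = np.ascontiguousarray(t.transpose(0, 3, 1, 4, 2, 5)) \
            .reshape(b, -1, 2 * h, 2 * w)
        out += self.b.value[None, :, None, None]
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        b, d, h2, w2 = dy.shape
        blocks = dy.reshape(b, d, h2 // 2, 2, w2 // 2, 2) \
            .transpose(0, 2, 4, 1, 3, 5)  # (b,h,w,d,2,2)
        self.W.grad += np.tensordot(x, blocks, axes=([0, 2, 3], [0, 1, 2]))
        self.b.grad += dy.sum(axis=(0, 2, 3))
        dx = np.tensordot(blocks, self.W.value,
                          axes=([3, 4, 5], [1, 2, 3]))  # (b,h,w,c)
        self._x = None
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))


class Sigmoid:
    def __init__(self):
        self._y = None

    def params(self) -> List[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))
        if train:
            self._y = y
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._y * (1 - self._y)
        self._y = None
        return dx


class Sequential:
    def __init__(self, *layers):
        self.layers = list(layers)

    def params(self) -> List[Param]:
        return [p for l in self.layers for p in l.params()]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy


def conv_block(cin: int, cout: int, rng: np.random.Generator) -> Sequential:
    """Two (conv 3x3 -> batch norm -> ReLU) stages."""
    return Sequential(
        Conv2d(cin, cout, rng=rng), BatchNorm2d(cout), ReLU(),
        Conv2d(cout, cout, rng=rng), BatchNorm2d(cout), ReLU())


@dataclass
class UNetConfig:
    in_channels: int = 1
    out_channels: int = 2
    base_channels: int = 64     # encoder width at full scale
    width_mult: float = 0.25    # desk-scale multiplier on all widths
    depth: int = 4              # number of pooling stages
    head_bias: float = -2.0     # output-layer bias: background prior
    seed: int = 0

    def widths(self) -> List[int]:
        return [max(int(round(self.base_channels * self.width_mult)) * 2 ** l, 4)
                for l in range(self.depth + 1)]


class UNet:
    """Two-channel U-Net with sigmoid outputs (MAB and LIB probabilities).

    The two output channels are independent sigmoids rather than a softmax:
    the lumen region is inside both boundaries, so per-pixel channel
    probabilities must be free to overlap.
    """

    def __init__(self, config: UNetConfig | None = None):
        self.config = config or UNetConfig()
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        ws = cfg.widths()
        self.enc = []
        cin = cfg.in_channels
        for w in ws[:-1]:
            self.enc.append(conv_block(cin, w, rng))
            cin = w
        self.pools = [MaxPool2d() for _ in ws[:-1]]
        self.bottleneck = conv_block(ws[-2], ws[-1], rng)
        self.ups, self.dec = [], []
        cin = ws[-1]
        for w in reversed(ws[:-1]):
            self.ups.append(ConvTranspose2d(cin, w, rng=rng))
            self.dec.append(conv_block(2 * w, w, rng))
            cin = w
        self.head = Conv2d(cin, cfg.out_channels, k=1, rng=rng)
        # bias the output sigmoids toward background so the Dice losses see
        # informative gradients from the start
        self.head.b.value[:] = cfg.head_bias
        self.out_act = Sigmoid()
        self._skip_channels: List[int] = []

    def params(self) -> List[Param]:
        ps: List[Param] = []
        for blk in self.enc:
            ps += blk.params()
        ps += self.bottleneck.params()
        for up, blk in zip(self.ups, self.dec):
            ps += up.params() + blk.params()
        ps += self.head.params()
        return ps

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = x.astype(np.float32)
        skips = []
        for blk, pool in zip(self.enc, self.pools):
            x = blk.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        for up, blk, skip in zip(self.ups, self.dec, reversed(skips)):
            x = up.forward(x, train)
            x = np.concatenate([skip, x], axis=1)
            x = blk.forward(x, train)
        x = self.head.forward(x, train)
        self._skip_channels = [s.shape[1] for s in skips]
        return self.out_act.forward(x, train)

    def backward(self, dy: np.ndarray) -> None:
        dy = self.out_act.backward(dy)
        dy = self.head.backward(dy)
        # decoder in reverse; each block's input was [skip, upsampled] with
        # equal channel halves
        dskips = []  # gradient w.r.t. each skip, shallowest first
        for up, blk in zip(reversed(self.ups), reversed(self.dec)):
            dy = blk.backward(dy)
            c_skip = dy.shape[1] // 2
            dskips.append(dy[:, :c_skip])
            dy = up.backward(dy[:, c_skip:])
        dy = self.bottleneck.backward(dy)
        for pool, blk, dskip in zip(reversed(self.pools), reversed(self.enc),
                                    reversed(dskips)):
            dy = pool.backward(dy)
            dy = dy + dskip
            dy = blk.backward(dy)

    # ---- checkpointing ---------------------------------------------------
    def state_arrays(self) -> Dict[str, np.ndarray]:
        out: Dict[str, np.ndarray] = {}
        for i, p in enumerate(self.params()):
            out[f"p{i}"] = p.value
        bns = [l for blk in ([*self.enc, self.bottleneck, *self.dec])
               for l in blk.layers if isinstance(l, BatchNorm2d)]
        for i, bn in enumerate(bns):
            out[f"bn{i}_mean"] = bn.running_mean
            out[f"bn{i}_var"] = bn.running_var
        return out

    def load_state_arrays(self, state: Dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            p.value = state[f"p{i}"].astype(np.float32)
        bns = [l for blk in ([*self.enc, self.bottleneck, *self.dec])
               for l in blk.layers if isinstance(l, BatchNorm2d)]
        for i, bn in enumerate(bns):
            bn.running_mean = state[f"bn{i}_mean"].astype(np.float32)
            bn.running_var = state[f"bn{i}_var"].astype(np.float32)


class Adam:
    def __init__(self, params: Sequence[Param], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
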
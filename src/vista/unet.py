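"""A compact CPU U-Net for image-to-image regression, in pure numpy.

Encoder–decoder with skip connections: per level two 3x3 same-padded
convolutions with ReLU, 2x2 max-pool downsampling, nearest-neighbour
upsampling and channel concatenation on the way up, and a linear 1x1
output convolution.  Convolutions run as im2col matrix products (BLAS),
gradients are computed analytically, and optimisation is Adam on a
mean-squared-error loss.  Everything is float32 and seeded: identical
(data, config, seed) reproduce the identical loss trace.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""

    def __init__(self, step: int):
        super().__init__(f"non-finite training loss at step {step}")
        self.step = step


# --------------------------------------------------------------------------
# primitive ops (NCHW layout)
# --------------------------------------------------------------------------

def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H+k-1, W+k-1) -> (N*H*W, C*k*k) patch matrix."""
    cols = sliding_window_view(x, (k, k), axis=(2, 3))   # N,C,H,W,k,k
    N, C, H, W, _, _ = cols.shape
    return cols.transpose(0, 2, 3, 1, 4, 5).reshape(N * H * W, C * k * k), (N, H, W)


def conv2d(x, w, b):
    """Same-padded 2-D convolution (cross-correlation), k odd."""
    k = w.shape[2]
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    cols, (N, H, W) = _im2col(xp, k)
    y = cols @ w.reshape(w.shape[0], -1).T + b
    return y.reshape(N, H, W, -1).transpose(0, 3, 1, 2), cols


def conv2d_backward(dy, cols, w, x_shape):
    """Gradients of conv2d: returns (dx, dw, db)."""
    N, Cout, H, W = dy.shape
    k = w.shape[2]
    dyf = dy.transpose(0, 2, 3, 1).reshape(-1, Cout)        # (NHW, Cout)
    dw = (dyf.T @ cols).reshape(w.shape)
    db = dyf.sum(axis=0)
    # dx = full correlation of dy with flipped kernels, channels transposed
    wt = w[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)           # (Cin, Cout, k, k)
    p = k // 2
    dyp = np.pad(dy, ((0, 0), (0, 0), (p, p), (p, p)))
    cols2, _ = _im2col(dyp, k)
    dx = cols2 @ wt.reshape(wt.shape[0], -1).T
    dx = dx.reshape(N, H, W, -1).transpose(0, 3, 1, 2)
    return np.ascontiguousarray(dx[:, :, :x_shape[2], :x_shape[3]]), dw, db


def maxpool2(x):
    N, C, H, W = x.shape
    xr = x.reshape(N, C, H // 2, 2, W // 2, 2)
    y = xr.max(axis=(3, 5))
    mask = xr == y[:, :, :, None, :, None]
    # break ties deterministically: keep only the first max per window
    flat = mask.transpose(0, 1, 2, 4, 3, 5).reshape(N, C, H // 2, W // 2, 4)
    first = np.cumsum(flat, axis=-1) == 1
    mask = (flat & first).reshape(N, C, H // 2, W // 2, 2, 2) \
        .transpose(0, 1, 2, 4, 3, 5)
    return y, mask


def maxpool2_backward(dy, mask):
    N, C, Hh, Wh = dy.shape
    dx = mask * dy[:, :, :, None, :, None]
    return dx.reshape(N, C, Hh * 2, Wh * 2)


def upsample2(x):
    return x.repeat(2, axis=2).repeat(2, axis=3)


def upsample2_backward(dy):
    N, C, H, W = dy.shape
    return dy.reshape(N, C, H // 2, 2, W // 2, 2).sum(axis=(3, 5))


# --------------------------------------------------------------------------
# the network
# --------------------------------------------------------------------------

class UNet:
    """U-Net regression network: 1 input channel -> 1 output channel.

    ``depth`` is the number of pooling stages; feature width doubles per
    level starting from ``base_channels``.  Input spatial sides must be
    divisible by ``2**depth``.
    """

    def __init__(self, depth: int = 2, base_channels: int = 8, seed: int = 0):
        self.depth = depth
        self.base = base_channels
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}

        def add_conv(name, cin, cout, k=3):
            std = np.sqrt(2.0 / (cin * k * k))
            self.params[f"{name}.w"] = rng.normal(0, std, (cout, cin, k, k)
                                                  ).astype(np.float32)
            self.params[f"{name}.b"] = np.zeros(cout, dtype=np.float32)

        ch = [base_channels * 2 ** i for i in range(depth + 1)]
        cin = 1
        for i, c in enumerate(ch[:-1]):
            add_conv(f"enc{i}a", cin, c); add_conv(f"enc{i}b", c, c)
            cin = c
        add_conv("bota", ch[-2], ch[-1]); add_conv("botb", ch[-1], ch[-1])
        for i in reversed(range(depth)):
            cat = ch[i + 1] + ch[i]
            add_conv(f"dec{i}a", cat, ch[i]); add_conv(f"dec{i}b", ch[i], ch[i])
        add_conv("out", ch[0], 1, k=1)

    # -- forward ------------------------------------------------------------
    def forward(self, x: np.ndarray, cache: dict | None = None) -> np.ndarray:
        p = self.params
        want = cache is not None

        def block(name, h):
            h1, c1 = conv2d(h, p[f"{name}a.w"], p[f"{name}a.b"])
            r1 = np.maximum(h1, 0)
            h2, c2 = conv2d(r1, p[f"{name}b.w"], p[f"{name}b.b"])
            r2 = np.maximum(h2, 0)
            if want:
                cache[name] = (h.shape, c1, h1 > 0, r1.shape, c2, h2 > 0)
            return r2

        skips = []
        h = x.astype(np.float32)
        for i in range(self.depth):
            h = block(f"enc{i}", h)
            skips.append(h)
            h, mask = maxpool2(h)
            if want:
                cache[f"pool{i}"] = mask
        h = block("bot", h)
        for i in reversed(range(self.depth)):
            up = upsample2(h)
            h = np.concatenate([up, skips[i]], axis=1)
            if want:
                cache[f"cat{i}"] = up.shape[1]
            h = block(f"dec{i}", h)
        y, cout = conv2d(h, p["out.w"], p["out.b"])
        if want:
            cache["out"] = (h.shape, cout)
        return y

    # -- backward -----------------------------------------------------------
    def backward(self, dy: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        p = self.params
        grads: dict[str, np.ndarray] = {}

        def block_bw(name, dout):
            in_shape, c1, m1, r1_shape, c2, m2 = cache[name]
            d2 = dout * m2
            dr1, dw2, db2 = conv2d_backward(d2, c2, p[f"{name}b.w"],
                                            (0, 0, r1_shape[2], r1_shape[3]))
            grads[f"{name}b.w"] = dw2; grads[f"{name}b.b"] = db2
            d1 = dr1 * m1
            dx, dw1, db1 = conv2d_backward(d1, c1, p[f"{name}a.w"], in_shape)
            grads[f"{name}a.w"] = dw1; grads[f"{name}a.b"] = db1
            return dx

        h_shape, cout = cache["out"]
        N, _, H, W = dy.shape
        dyf = dy.transpose(0, 2, 3, 1).reshape(-1, 1)
        grads["out.w"] = (dyf.T @ cout).reshape(p["out.w"].shape)
        grads["out.b"] = dyf.sum(axis=0)
        dh = (dyf @ p["out.w"].reshape(1, -1)).reshape(N, H, W, -1) \
            .transpose(0, 3, 1, 2)

        for i in range(self.depth):
            dh = block_bw(f"dec{i}", dh)
            nup = cache[f"cat{i}"]
            dup, dskip = dh[:, :nup], dh[:, nup:]
            dh = upsample2_backward(dup)
            # skip connection gradient flows into the encoder block below
            cache[f"skipgrad{i}"] = dskip
        dh_bot = block_bw("bot", dh)
        dh = dh_bot
        for i in reversed(range(self.depth)):
            dh = maxpool2_backward(dh, cache[f"pool{i}"])
            dh = dh + cache[f"skipgrad{i}"]
            dh = block_bw(f"enc{i}", dh)
        return grads


class Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            g = g.astype(np.float32)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            self.params[k] -= (self.lr * mhat /
                               (np.sqrt(vhat) + self.eps)).astype(np.float32)
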
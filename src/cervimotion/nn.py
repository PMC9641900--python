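"""A minimal CPU conv-net toolkit (numpy, float32, manual backprop).

Just enough machinery for the landmark detector: 2-D convolution via
im2col, ReLU, nearest-neighbour 2x upsampling, an SGD optimizer with
momentum and weight decay, and a two-branch multi-resolution trunk that
keeps a high-resolution stream alongside a half-resolution stream and
fuses them repeatedly — the architectural idea behind high-resolution
keypoint networks, at desk scale.

Everything is deterministic given the RNG passed at initialization.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def _im2col(x, k, stride, pad):
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    cols = np.empty((n, c, k, k, oh, ow), dtype=x.dtype)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride]
    return cols.reshape(n, c * k * k, oh * ow), oh, ow


def _col2im(cols, x_shape, k, stride, pad):
    n, c, h, w = x_shape
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    cols = cols.reshape(n, c, k, k, oh, ow)
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, :, i:i + stride * oh:stride, j:j + stride * ow:stride] += cols[:, :, i, j]
    if pad == 0:
        return xp
    return xp[:, :, pad:pad + h, pad:pad + w]


class Conv2d:
    def __init__(self, c_in, c_out, k, stride=1, pad=None, *, rng):
        pad = (k // 2) if pad is None else pad
        self.k, self.stride, self.pad = k, stride, pad
        scale = np.sqrt(2.0 / (c_in * k * k))  # He init
        self.w = rng.normal(0.0, scale, size=(c_out, c_in, k, k)).astype(DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def forward(self, x):
        cols, oh, ow = _im2col(x, self.k, self.stride, self.pad)
        w2 = self.w.reshape(self.w.shape[0], -1)
        out = np.matmul(w2, cols) + self.b[None, :, None]
        self._cache = (x.shape, cols)
        return out.reshape(x.shape[0], -1, oh, ow)

    def backward(self, dout):
        x_shape, cols = self._cache
        n, c_out, oh, ow = dout.shape
        d2 = dout.reshape(n, c_out, oh * ow)
        w2 = self.w.reshape(c_out, -1)
        self.dw += np.einsum("nol,nkl->ok", d2, cols).reshape(self.w.shape)
        self.db += d2.sum(axis=(0, 2))
        dcols = np.matmul(w2.T, d2)
        return _col2im(dcols, x_shape, self.k, self.stride, self.pad)

    @property
    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


def upsample2x(x):
    return x.repeat(2, axis=2).repeat(2, axis=3)


def upsample2x_backward(dout):
    n, c, h, w = dout.shape
    return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class SGD:
    """SGD with classical momentum and decoupled-from-nothing weight decay."""

    def __init__(self, params, lr, momentum=0.9, weight_decay=0.0):
        self.params = params
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self.velocity = [np.zeros_like(p) for p, _ in params]

    def step(self):
        for (p, g), v in zip(self.params, self.velocity):
            np.multiply(v, self.momentum, out=v)
            v -= self.lr * (g + self.weight_decay * p)
            p += v

    def zero_grad(self):
        for _, g in self.params:
            g[...] = 0.0


class TwoBranchHeatmapNet:
    """Two-branch multi-resolution heatmap regressor.

    Stem: two stride-2 3x3 convolutions bring the input to 1/4 resolution
    (the high-resolution stream).  A stride-2 transition opens a
    half-resolution stream with doubled width.  Each stage convolves both
    streams and fuses them in both directions (1x1-conv + 2x upsampling
    into the high stream; stride-2 3x3 conv into the low stream).  A 1x1
    head regresses the 22 heatmap channels from the high stream, so the
    output stride is 4.
    """

    def __init__(self, n_channels_out, width=12, n_stages=2, in_channels=1, *, rng):
        c, c2 = width, 2 * width
        self.n_stages = n_stages
        self.stem1, self.stem1r = Conv2d(in_channels, c, 3, 2, rng=rng), ReLU()
        self.stem2, self.stem2r = Conv2d(c, c, 3, 2, rng=rng), ReLU()
        self.down0, self.down0r = Conv2d(c, c2, 3, 2, rng=rng), ReLU()
        self.stages = []
        for s in range(n_stages):
            stage = {
                "high": Conv2d(c, c, 3, 1, rng=rng), "highr": ReLU(),
                "low": Conv2d(c2, c2, 3, 1, rng=rng), "lowr": ReLU(),
                "fuse_lh": Conv2d(c2, c, 1, 1, rng=rng), "fuse_hr": ReLU(),
            }
            if s < n_stages - 1:
                stage["fuse_hl"] = Conv2d(c, c2, 3, 2, rng=rng)
                stage["fuse_lr"] = ReLU()
            self.stages.append(stage)
        self.head = Conv2d(c, n_channels_out, 1, 1, rng=rng)
        # start the regression head near zero: the initial prediction is then
        # close to the empty-heatmap baseline instead of random noise, which
        # keeps early SGD steps stable at the desk-scale learning rate
        self.head.w *= 0.01

    # -- forward ----------------------------------------------------------
    def forward(self, x):
        h = self.stem1r.forward(self.stem1.forward(x.astype(DTYPE)))
        h = self.stem2r.forward(self.stem2.forward(h))
        low = self.down0r.forward(self.down0.forward(h))
        for s, st in enumerate(self.stages):
            h = st["highr"].forward(st["high"].forward(h))
            low = st["lowr"].forward(st["low"].forward(low))
            h = st["fuse_hr"].forward(h + upsample2x(st["fuse_lh"].forward(low)))
            if s < self.n_stages - 1:
                low = st["fuse_lr"].forward(low + st["fuse_hl"].forward(h))
        return self.head.forward(h)

    # -- backward (mirror of forward) --------------------------------------
    def backward(self, dout):
        dh = self.head.backward(dout)
        dlow = None
        for s in reversed(range(self.n_stages)):
            st = self.stages[s]
            if s < self.n_stages - 1:
                dl = st["fuse_lr"].backward(dlow)
                dh = dh + st["fuse_hl"].backward(dl)
                dlow = dl
            else:
                dlow = np.zeros(1, dtype=DTYPE)  # low stream unused past here
            dsum = st["fuse_hr"].backward(dh)
            dh = dsum
            dlow_from_fuse = st["fuse_lh"].backward(upsample2x_backward(dsum))
            dlow = dlow_from_fuse if dlow.shape == (1,) else dlow + dlow_from_fuse
            dlow = st["low"].backward(st["lowr"].backward(dlow))
            dh = st["high"].backward(st["highr"].backward(dh))
        dh = dh + self.down0.backward(self.down0r.backward(dlow))
        dh = self.stem2.backward(self.stem2r.backward(dh))
        return self.stem1.backward(self.stem1r.backward(dh))

    # -- parameters ---------------------------------------------------------
    def _convs(self):
        convs = [self.stem1, self.stem2, self.down0]
        for st in self.stages:
            convs += [st["high"], st["low"], st["fuse_lh"]]
            if "fuse_hl" in st:
                convs.append(st["fuse_hl"])
        convs.append(self.head)
        return convs

    @property
    def params(self):
        out = []
        for conv in self._convs():
            out.extend(conv.params)
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {}
        for i, conv in enumerate(self._convs()):
            out[f"conv{i}.w"] = conv.w
            out[f"conv{i}.b"] = conv.b
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, conv in enumerate(self._convs()):
            conv.w[...] = state[f"conv{i}.w"]
            conv.b[...] = state[f"conv{i}.b"]

    def copy_state(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.state_dict().items()}
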
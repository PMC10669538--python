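"""Minimal NumPy CNN layers with backprop, used by the autoencoder.

Everything operates on float32 batches shaped (N, C, H, W).  Only the
primitives the VGG-style autoencoder needs are provided: 3x3 / 1x1
convolution with reflection padding, ReLU, ceil-mode 2x2 max pooling and
nearest-neighbour 2x upsampling, plus an Adam optimiser for the fixture
training loop.  Forward passes are deterministic; training is reproducible
for a fixed RNG.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


def _reflect_pad(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), mode="reflect")


def _reflect_pad_adjoint(dxp: np.ndarray, p: int) -> np.ndarray:
    """Adjoint of reflect padding: fold gradient of padded borders back in."""
    if p == 0:
        return dxp
    if p != 1:  # only 3x3 kernels are ever used
        raise ValueError("only pad 1 supported")
    dx = dxp[:, :, 1:-1, 1:-1].copy()
    dx[:, :, 1, :] += dxp[:, :, 0, 1:-1]
    dx[:, :, -2, :] += dxp[:, :, -1, 1:-1]
    dx[:, :, :, 1] += dxp[:, :, 1:-1, 0]
    dx[:, :, :, -2] += dxp[:, :, 1:-1, -1]
    dx[:, :, 1, 1] += dxp[:, :, 0, 0]
    dx[:, :, 1, -2] += dxp[:, :, 0, -1]
    dx[:, :, -2, 1] += dxp[:, :, -1, 0]
    dx[:, :, -2, -2] += dxp[:, :, -1, -1]
    return dx


class Conv2d:
    """k x k convolution, stride 1, reflection padding k//2 (size preserving)."""

    def __init__(self, name: str, c_in: int, c_out: int, kernel: int,
                 relu: bool = True):
        self.name = name
        self.c_in = c_in
        self.c_out = c_out
        self.kernel = kernel
        self.relu = relu
        self.W = np.zeros((c_out, c_in, kernel, kernel), dtype=DTYPE)
        self.b = np.zeros(c_out, dtype=DTYPE)
        self._cache = None

    def init_params(self, rng: np.random.Generator) -> None:
        fan_in = self.c_in * self.kernel * self.kernel
        std = np.sqrt(2.0 / fan_in)
        self.W = rng.normal(0.0, std, size=self.W.shape).astype(DTYPE)
        self.b = np.zeros(self.c_out, dtype=DTYPE)

    @property
    def params(self):
        return [("W", self.W), ("b", self.b)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        if c != self.c_in:
            raise ValueError(
                f"layer {self.name}: expected {self.c_in} channels, got {c}")
        k = self.kernel
        p = k // 2
        xp = _reflect_pad(x, p)
        win = sliding_window_view(xp, (k, k), axis=(2, 3))  # n,c,h,w,k,k
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * k * k)
        wmat = self.W.reshape(self.c_out, c * k * k)
        y = cols @ wmat.T + self.b
        y = np.ascontiguousarray(
            y.reshape(n, h, w, self.c_out).transpose(0, 3, 1, 2))
        if self.relu:
            mask = y > 0
            y *= mask
        else:
            mask = None
        if train:
            self._cache = (cols, mask, (n, c, h, w))
        return y

    def backward(self, dy: np.ndarray):
        cols, mask, (n, c, h, w) = self._cache
        k = self.kernel
        p = k // 2
        if mask is not None:
            dy = dy * mask
        dy2 = dy.transpose(0, 2, 3, 1).reshape(n * h * w, self.c_out)
        self.dW = (dy2.T @ cols).reshape(self.W.shape).astype(DTYPE)
        self.db = dy2.sum(axis=0).astype(DTYPE)
        wmat = self.W.reshape(self.c_out, c * k * k)
        dcols = (dy2 @ wmat).reshape(n, h, w, c, k, k)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=DTYPE)
        dcols = dcols.transpose(0, 3, 1, 2, 4, 5)  # n,c,h,w,k,k
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + h, j:j + w] += dcols[:, :, :, :, i, j]
        return _reflect_pad_adjoint(dxp, p)

    @property
    def grads(self):
        return [("W", self.dW), ("b", self.db)]


class MaxPool2:
    """2x2 max pooling with stride 2, ceil mode (odd edges padded with -inf)."""

    name = "pool"
    params: list = []
    grads: list = []

    def __init__(self):
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        ho, wo = -(-h // 2), -(-w // 2)
        hp, wp = ho * 2, wo * 2
        if (hp, wp) != (h, w):
            xp = np.full((n, c, hp, wp), -np.inf, dtype=DTYPE)
            xp[:, :, :h, :w] = x
        else:
            xp = x
        blocks = xp.reshape(n, c, ho, 2, wo, 2).transpose(0, 1, 2, 4, 3, 5)
        blocks = blocks.reshape(n, c, ho, wo, 4)
        idx = blocks.argmax(axis=-1)
        y = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, (n, c, h, w))
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray):
        idx, (n, c, h, w) = self._cache
        ho, wo = -(-h // 2), -(-w // 2)
        dblocks = np.zeros((n, c, ho, wo, 4), dtype=DTYPE)
        np.put_along_axis(dblocks, idx[..., None], dy[..., None], axis=-1)
        dxp = dblocks.reshape(n, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        dxp = dxp.reshape(n, c, ho * 2, wo * 2)
        return np.ascontiguousarray(dxp[:, :, :h, :w])


class NearestUp2:
    """Nearest-neighbour 2x upsampling, optionally cropped to a target size.

    The crop undoes ceil-mode pooling of odd inputs so decode mirrors encode
    exactly.
    """

    name = "up"
    params: list = []
    grads: list = []

    def __init__(self):
        self.target_hw: tuple[int, int] | None = None
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = np.repeat(np.repeat(x, 2, axis=2), 2, axis=3)
        full_hw = y.shape[2:]
        if self.target_hw is not None:
            th, tw = self.target_hw
            y = y[:, :, :th, :tw]
        if train:
            self._cache = (x.shape, full_hw)
        return np.ascontiguousarray(y)

    def backward(self, dy: np.ndarray):
        x_shape, (fh, fw) = self._cache
        if dy.shape[2:] != (fh, fw):
            full = np.zeros(dy.shape[:2] + (fh, fw), dtype=DTYPE)
            full[:, :, :dy.shape[2], :dy.shape[3]] = dy
            dy = full
        n, c = dy.shape[:2]
        dx = dy.reshape(n, c, x_shape[2], 2, x_shape[3], 2).sum(axis=(3, 5))
        return dx.astype(DTYPE)


class Adam:
    """Adam over the conv parameters of a layer list."""

    def __init__(self, layers, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.layers = [l for l in layers if l.params]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [[np.zeros_like(p) for _, p in l.params] for l in self.layers]
        self.v = [[np.zeros_like(p) for _, p in l.params] for l in self.layers]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for li, layer in enumerate(self.layers):
            for pi, ((_, p), (_, g)) in enumerate(zip(layer.params,
                                                      layer.grads)):
                m = self.m[li][pi]
                v = self.v[li][pi]
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                mhat = m / (1 - b1 ** self.t)
                vhat = v / (1 - b2 ** self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def forward_layers(layers, x: np.ndarray, train: bool = False) -> np.ndarray:
    for layer in layers:
        x = layer.forward(x, train=train)
    return x


def backward_layers(layers, dy: np.ndarray) -> np.ndarray:
    for layer in reversed(layers):
        dy = layer.backward(dy)
    return dy
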
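"""Layers with explicit forward/backward passes (float32, NCDHW)."""

from __future__ import annotations

import itertools

import numpy as np

__all__ = [
    "Parameter",
    "Module",
    "Conv3d",
    "BatchNorm3d",
    "LeakyReLU",
    "Upsample3d",
    "Sequential",
    "ConvBlock",
    "kaiming_normal",
]


class Parameter:
    """A trainable array with its accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self):
        self.grad[...] = 0.0


def kaiming_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    """He-style initialization: N(0, sqrt(2 / fan_in))."""
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Module:
    training: bool = True

    def parameters(self) -> list[Parameter]:
        return []

    def train(self, mode: bool = True):
        self.training = mode
        for m in getattr(self, "children", []):
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError

    def __call__(self, x):
        return self.forward(x)


def _im2col(xp: np.ndarray, k: int, stride: int, out_shape) -> np.ndarray:
    """(B, C, Dp, Hp, Wp) padded input -> (B, C*k^3, L) patch matrix."""
    B, C = xp.shape[:2]
    Do, Ho, Wo = out_shape
    L = Do * Ho * Wo
    cols = np.empty((B, C, k * k * k, L), dtype=np.float32)
    for o, (i, j, l) in enumerate(itertools.product(range(k), repeat=3)):
        view = xp[
            :,
            :,
            i : i + stride * Do : stride,
            j : j + stride * Ho : stride,
            l : l + stride * Wo : stride,
        ]
        cols[:, :, o, :] = view.reshape(B, C, L)
    return cols.reshape(B, C * k * k * k, L)


def _col2im(dcols: np.ndarray, xp_shape, k: int, stride: int, out_shape) -> np.ndarray:
    """Scatter-add gradient of _im2col back onto the padded input."""
    B, C = xp_shape[:2]
    Do, Ho, Wo = out_shape
    L = Do * Ho * Wo
    d = dcols.reshape(B, C, k * k * k, L)
    dxp = np.zeros(xp_shape, dtype=np.float32)
    for o, (i, j, l) in enumerate(itertools.product(range(k), repeat=3)):
        dxp[
            :,
            :,
            i : i + stride * Do : stride,
            j : j + stride * Ho : stride,
            l : l + stride * Wo : stride,
        ] += d[:, :, o, :].reshape(B, C, Do, Ho, Wo)
    return dxp


class Conv3d(Module):
    """3D convolution, kernel 1 or 3, 'same'-style padding (k-1)//2."""

    def __init__(self, cin, cout, kernel=3, stride=1, bias=True, rng=None, name=""):
        if kernel not in (1, 3):
            raise ValueError("kernel must be 1 or 3")
        rng = rng or np.random.default_rng(0)
        fan_in = cin * kernel**3
        self.k, self.stride = kernel, stride
        self.cin, self.cout = cin, cout
        self.weight = Parameter(
            kaiming_normal(rng, (cout, cin, kernel, kernel, kernel), fan_in), f"{name}.w"
        )
        self.bias = Parameter(np.zeros(cout, dtype=np.float32), f"{name}.b") if bias else None
        self._cache = None

    def parameters(self):
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def out_shape(self, in_shape):
        p = (self.k - 1) // 2
        return tuple((s + 2 * p - self.k) // self.stride + 1 for s in in_shape)

    def forward(self, x):
        x = np.ascontiguousarray(x, dtype=np.float32)
        B = x.shape[0]
        p = (self.k - 1) // 2
        out_sp = self.out_shape(x.shape[2:])
        if p:
            xp = np.pad(x, ((0, 0), (0, 0)) + ((p, p),) * 3)
        elif self.stride > 1:
            xp = x
        else:
            xp = x
        if self.k == 1 and self.stride == 1:
            L = int(np.prod(x.shape[2:]))
            cols = x.reshape(B, self.cin, L)
        else:
            cols = _im2col(xp, self.k, self.stride, out_sp)
        W2 = self.weight.value.reshape(self.cout, -1)
        y = np.matmul(W2, cols)  # (B, cout, L)
        if self.bias is not None:
            y += self.bias.value[None, :, None]
        # patch matrices are only needed for backward; drop them in eval mode
        self._cache = (cols, xp.shape, x.shape, out_sp) if self.training else None
        return y.reshape(B, self.cout, *out_sp)

    def backward(self, dy):
        cols, xp_shape, x_shape, out_sp = self._cache
        B = dy.shape[0]
        dyf = np.ascontiguousarray(dy, dtype=np.float32).reshape(B, self.cout, -1)
        W2 = self.weight.value.reshape(self.cout, -1)
        # parameter grads (BLAS gemm per batch item)
        dW = np.zeros((self.cout, cols.shape[1]), dtype=np.float32)
        for b in range(B):
            dW += dyf[b] @ cols[b].T
        self.weight.grad += dW.reshape(self.weight.value.shape)
        if self.bias is not None:
            self.bias.grad += dyf.sum(axis=(0, 2))
        dcols = np.matmul(W2.T, dyf)  # (B, cin*k^3, L)
        if self.k == 1 and self.stride == 1:
            return dcols.reshape(x_shape)
        dxp = _col2im(dcols, xp_shape, self.k, self.stride, out_sp)
        p = (self.k - 1) // 2
        if p:
            dxp = dxp[:, :, p:-p, p:-p, p:-p]
        # stride may leave trailing rows of the input untouched; shapes match x
        return np.ascontiguousarray(dxp[:, :, : x_shape[2], : x_shape[3], : x_shape[4]])


class BatchNorm3d(Module):
    """Per-sample, per-channel normalization over the spatial axes.

    Statistics are taken per (sample, channel) — instance normalization —
    so training and inference behave identically regardless of batch
    size (running statistics are still tracked for reference).
    """

    def __init__(self, c, eps=1e-5, momentum=0.1, name=""):
        self.c, self.eps, self.momentum = c, eps, momentum
        self.gamma = Parameter(np.ones(c, dtype=np.float32), f"{name}.gamma")
        self.beta = Parameter(np.zeros(c, dtype=np.float32), f"{name}.beta")
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)
        self._cache = None

    def parameters(self):
        return [self.gamma, self.beta]

    def forward(self, x):
        x = np.asarray(x, dtype=np.float32)
        axes = (2, 3, 4)
        mu = x.mean(axis=axes)  # (B, C)
        var = x.var(axis=axes)
        if self.training:
            m = mu.mean(axis=0)
            v = var.mean(axis=0)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * m
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * v
        std = np.sqrt(var + self.eps).astype(np.float32)
        xhat = (x - mu[:, :, None, None, None]) / std[:, :, None, None, None]
        y = self.gamma.value[None, :, None, None, None] * xhat
        y += self.beta.value[None, :, None, None, None]
        self._cache = (xhat, std) if self.training else (None, std)
        return y

    def backward(self, dy):
        xhat, std = self._cache
        axes = (2, 3, 4)
        n = dy.shape[2] * dy.shape[3] * dy.shape[4]
        dg = (dy * xhat).sum(axis=axes)  # (B, C)
        db = dy.sum(axis=axes)
        self.gamma.grad += dg.sum(axis=0)
        self.beta.grad += db.sum(axis=0)
        g = self.gamma.value[None, :] / std  # (B, C)
        dx = (
            dy
            - (db / n)[:, :, None, None, None]
            - xhat * (dg / n)[:, :, None, None, None]
        )
        return dx * g[:, :, None, None, None]


class LeakyReLU(Module):
    def __init__(self, slope=0.1):
        self.slope = slope
        self._mask = None

    def forward(self, x):
        mask = x > 0
        self._mask = mask if self.training else None
        return np.where(mask, x, self.slope * x).astype(np.float32)

    def backward(self, dy):
        return np.where(self._mask, dy, self.slope * dy).astype(np.float32)


class Upsample3d(Module):
    """Nearest-neighbor upsampling by an integer factor."""

    def __init__(self, factor=2):
        self.f = factor

    def forward(self, x):
        f = self.f
        return x.repeat(f, axis=2).repeat(f, axis=3).repeat(f, axis=4)

    def backward(self, dy):
        f = self.f
        B, C, D, H, W = dy.shape
        return dy.reshape(B, C, D // f, f, H // f, f, W // f, f).sum(axis=(3, 5, 7))


class Sequential(Module):
    def __init__(self, *mods):
        self.children = list(mods)

    def parameters(self):
        return [p for m in self.children for p in m.parameters()]

    def forward(self, x):
        for m in self.children:
            x = m(x)
        return x

    def backward(self, dy):
        for m in reversed(self.children):
            dy = m.backward(dy)
        return dy


def ConvBlock(cin, cout, kernel=3, stride=1, rng=None, name="") -> Sequential:
    """Conv -> BatchNorm -> LeakyReLU, the standard feature-extraction unit."""
    return Sequential(
        Conv3d(cin, cout, kernel, stride, bias=False, rng=rng, name=name),
        BatchNorm3d(cout, name=name),
        LeakyReLU(0.1),
    )
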
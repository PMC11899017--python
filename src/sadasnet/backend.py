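"""Minimal CNN training engine on numpy.

Implements exactly the layer vocabulary the architecture search emits —
SAME-padded strided convolutions with ReLU, inception-style multi-branch
blocks, VALID max/average pooling, global average pooling, dense layers and a
softmax classifier head — with reverse-mode gradients and stochastic gradient
descent with momentum.  Everything is plain float32 numpy, so training is
bit-reproducible for a fixed seed, which the architecture search relies on.

Tensors are NCHW.  Convolutions are evaluated by im2col + matmul, the usual
CPU-friendly lowering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .architecture import (
    ArchitectureSpec,
    ConvBlockSpec,
    FCSpec,
    MultiBranchSpec,
    PoolSpec,
)

__all__ = ["Model", "SGDM", "build_model", "softmax", "cross_entropy_loss"]


def _same_pads(extent: int, fs: int, stride: int) -> tuple[int, int]:
    out = math.ceil(extent / stride)
    total = max((out - 1) * stride + fs - extent, 0)
    return total // 2, total - total // 2


class Conv2D:
    """SAME-padded strided convolution, optional fused ReLU."""

    def __init__(self, cin: int, cout: int, fs: int, stride: int,
                 rng: np.random.Generator, relu: bool = True):
        fan_in = fs * fs * cin
        self.W = rng.normal(0.0, math.sqrt(2.0 / fan_in), (cout, cin, fs, fs)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.stride = stride
        self.fs = fs
        self.relu = relu
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def parameters(self):
        return [(self.W, self.dW, True), (self.b, self.db, False)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        fs, s = self.fs, self.stride
        pt, pb = _same_pads(h, fs, s)
        pl, pr = _same_pads(w, fs, s)
        xp = np.pad(x, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
        win = sliding_window_view(xp, (fs, fs), axis=(2, 3))[:, :, ::s, ::s]
        # (n, c, ho, wo, fs, fs) -> (n, ho, wo, c*fs*fs)
        ho, wo = win.shape[2], win.shape[3]
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * fs * fs)
        out = cols @ self.W.reshape(self.W.shape[0], -1).T + self.b
        out = out.reshape(n, ho, wo, -1).transpose(0, 3, 1, 2)
        if self.relu:
            mask = out > 0
            out = out * mask
        else:
            mask = None
        if train:
            self._cache = (cols, x.shape, (pt, pl), (ho, wo), mask)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, xshape, (pt, pl), (ho, wo), mask = self._cache
        n, c, h, w = xshape
        fs, s = self.fs, self.stride
        if mask is not None:
            dout = dout * mask
        cout = self.W.shape[0]
        dflat = dout.transpose(0, 2, 3, 1).reshape(-1, cout)
        self.dW[...] = (dflat.T @ cols).reshape(self.W.shape)
        self.db[...] = dflat.sum(axis=0)
        dcols = (dflat @ self.W.reshape(cout, -1)).reshape(n, ho, wo, c, fs, fs)
        dcols = dcols.transpose(0, 3, 4, 5, 1, 2)  # (n, c, fs, fs, ho, wo)
        hp = h + sum(_same_pads(h, fs, s))
        wp = w + sum(_same_pads(w, fs, s))
        dxp = np.zeros((n, c, hp, wp), dtype=np.float32)
        for i in range(fs):
            for j in range(fs):
                dxp[:, :, i:i + s * ho:s, j:j + s * wo:s] += dcols[:, :, i, j]
        return dxp[:, :, pt:pt + h, pl:pl + w]


class MultiBranch:
    """Parallel SAME stride-1 convolutions (kernels 1,3,5,7), channel concat."""

    def __init__(self, cin: int, spec: MultiBranchSpec, rng: np.random.Generator):
        self.branches = [
            Conv2D(cin, spec.filters_per_branch, k, 1, rng, relu=True)
            for k in spec.branch_kernels
        ]
        self.nf = spec.filters_per_branch

    def parameters(self):
        return [p for br in self.branches for p in br.parameters()]

    def forward(self, x, train):
        return np.concatenate([br.forward(x, train) for br in self.branches], axis=1)

    def backward(self, dout):
        dx = None
        for i, br in enumerate(self.branches):
            d = br.backward(dout[:, i * self.nf:(i + 1) * self.nf])
            dx = d if dx is None else dx + d
        return dx


class Pool2D:
    """VALID max or average pooling."""

    def __init__(self, spec: PoolSpec):
        self.fs = spec.filter_size
        self.stride = spec.stride
        self.mode = spec.pool_type

    def parameters(self):
        return []

    def forward(self, x, train):
        fs, s = self.fs, self.stride
        win = sliding_window_view(x, (fs, fs), axis=(2, 3))[:, :, ::s, ::s]
        flat = win.reshape(*win.shape[:4], fs * fs)
        if self.mode == "max":
            arg = flat.argmax(axis=-1)
            out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
            if train:
                self._cache = (x.shape, arg)
        else:
            out = flat.mean(axis=-1)
            if train:
                self._cache = (x.shape, None)
        return np.ascontiguousarray(out)

    def backward(self, dout):
        xshape, arg = self._cache
        n, c, h, w = xshape
        fs, s = self.fs, self.stride
        ho, wo = dout.shape[2], dout.shape[3]
        dx = np.zeros(xshape, dtype=np.float32)
        if arg is None:
            share = dout / (fs * fs)
            for i in range(fs):
                for j in range(fs):
                    dx[:, :, i:i + s * ho:s, j:j + s * wo:s] += share
        else:
            for i in range(fs):
                for j in range(fs):
                    mask = arg == (i * fs + j)
                    dx[:, :, i:i + s * ho:s, j:j + s * wo:s] += dout * mask
        return dx


class GlobalAvgPool:
    def parameters(self):
        return []

    def forward(self, x, train):
        if train:
            self._cache = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout):
        n, c, h, w = self._cache
        return np.broadcast_to(dout[:, :, None, None] / (h * w), (n, c, h, w)).astype(np.float32)


class Dense:
    def __init__(self, cin: int, cout: int, rng: np.random.Generator, relu: bool):
        self.W = rng.normal(0.0, math.sqrt(2.0 / cin), (cin, cout)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.relu = relu
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def parameters(self):
        return [(self.W, self.dW, True), (self.b, self.db, False)]

    def forward(self, x, train):
        out = x @ self.W + self.b
        mask = out > 0 if self.relu else None
        if self.relu:
            out = out * mask
        if train:
            self._cache = (x, mask)
        return out

    def backward(self, dout):
        x, mask = self._cache
        if mask is not None:
            dout = dout * mask
        self.dW[...] = x.T @ dout
        self.db[...] = dout.sum(axis=0)
        return dout @ self.W.T


class Model:
    """Feed-forward stack built from an :class:`ArchitectureSpec`."""

    def __init__(self, ops: list, arch: ArchitectureSpec):
        self.ops = ops
        self.arch = arch

    def parameters(self):
        return [p for op in self.ops for p in op.parameters()]

    def num_parameters(self) -> int:
        """Backend's own enumeration of learnable values (weights + biases)."""
        return sum(int(w.size) for w, _, _ in self.parameters())

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for op in self.ops:
            x = op.forward(x, train)
        return x  # logits

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for op in reversed(self.ops):
            d = op.backward(d)

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        out = []
        for i in range(0, x.shape[0], batch_size):
            out.append(softmax(self.forward(x[i:i + batch_size], train=False)))
        return np.concatenate(out, axis=0)


def build_model(arch: ArchitectureSpec, rng: np.random.Generator) -> Model:
    """Instantiate weights for a repaired architecture.

    Raises if the architecture still contains infeasible layers (repair
    first); the resulting model's ``num_parameters`` matches the analytic
    parameter accounting exactly.
    """
    from .architecture import propagate_shapes

    rows = propagate_shapes(arch)
    if any(not r.feasible for r in rows):
        raise ValueError("architecture has infeasible layers; repair before building")
    h, w, cin = arch.input_shape
    ops: list = []
    collapsed = False
    features = cin
    for layer in arch.layers:
        if isinstance(layer, ConvBlockSpec):
            ops.append(Conv2D(features, layer.num_filters, layer.filter_size, layer.stride, rng))
            features = layer.num_filters
        elif isinstance(layer, MultiBranchSpec):
            ops.append(MultiBranch(features, layer, rng))
            features = layer.out_channels
        elif isinstance(layer, PoolSpec):
            ops.append(Pool2D(layer))
        elif isinstance(layer, FCSpec):
            if not collapsed:
                ops.append(GlobalAvgPool())
                collapsed = True
            ops.append(Dense(features, layer.num_neurons, rng, relu=True))
            features = layer.num_neurons
    if not collapsed:
        ops.append(GlobalAvgPool())
    ops.append(Dense(features, arch.num_classes, rng, relu=False))
    return Model(ops, arch)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_loss(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    n = logits.shape[0]
    p = softmax(logits)
    eps = 1e-12
    loss = -np.log(p[np.arange(n), y] + eps).mean()
    d = p
    d[np.arange(n), y] -= 1.0
    return float(loss), (d / n).astype(np.float32)


@dataclass
class SGDM:
    """Stochastic gradient descent with momentum and L2 weight decay.

    Decay is applied to weights only (biases excluded), the convention of
    mainstream training frameworks.
    """

    model: Model
    momentum: float = 0.9
    l2: float = 1e-4

    def __post_init__(self) -> None:
        self._vel = [np.zeros_like(w) for w, _, _ in self.model.parameters()]

    def step(self, lr: float) -> None:
        for v, (w, g, decay) in zip(self._vel, self.model.parameters()):
            grad = g + self.l2 * w if (decay and self.l2) else g
            v *= self.momentum
            v -= lr * grad
            w += v
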
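"""Gradient-trained spatiotemporal convolutional network (learned templates).

The trainable variant replaces sampled templates with filters learned by
stochastic gradient descent under a cross-entropy objective with full
supervision on the embedding set. The architecture is two stacked
Convolution-BatchNorm-MaxPooling-BatchNorm modules followed by two
Linear-ReLU-BatchNorm modules and a log-soft-max head; at feature-extraction
time the linear layers and the head are discarded and the output of the last
pooling/normalization stage, flattened, is the clip's feature vector (with
batch-normalization statistics frozen).

All layers are implemented here in numpy with analytic forward/backward
passes; gradient correctness is checked against central finite differences
in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "LearnedArch",
    "TrainConfig",
    "LearnedModel",
    "build_learned_model",
    "train_model",
    "extract_learned_features",
    "paper_arch",
    "reduced_arch",
]


@dataclass(frozen=True)
class LearnedArch:
    """Layer dimensions of the trainable ST-CNN."""

    input_size: tuple[int, int, int]  # (H, W, T)
    conv1_filters: int = 72
    conv1_size: tuple[int, int, int] = (9, 9, 9)
    conv1_stride: tuple[int, int, int] = (2, 2, 2)
    pool1_region: tuple[int, int, int] = (4, 4, 1)
    pool1_stride: tuple[int, int, int] = (2, 2, 1)
    conv2_filters: int = 60
    conv2_size: tuple[int, int, int] = (17, 17, 3)
    conv2_stride: tuple[int, int, int] = (1, 1, 2)
    pool2_channels: int = 5  # channels per Pool2 group; full space x 1 time unit
    fc_sizes: tuple[int, ...] = (256, 128)

    def __post_init__(self) -> None:
        if self.conv2_filters % self.pool2_channels != 0:
            raise ValueError(
                f"pool2 channels-per-group {self.pool2_channels} must divide "
                f"the {self.conv2_filters} conv2 channels"
            )


def paper_arch(input_size: tuple[int, int, int] = (128, 76, 60)) -> LearnedArch:
    """Full-scale architecture: 72@9x9x9 s2 / pool 4x4x1 s(2,2,1) /
    60@17x17x3 s(1,1,2) / pool full-space x 1 time x 5 channels / fc 256, 128."""
    return LearnedArch(input_size=input_size)


def reduced_arch(input_size: tuple[int, int, int] = (64, 38, 30)) -> LearnedArch:
    """Desk-scale preset for tests: fewer filters, smaller receptive fields."""
    return LearnedArch(
        input_size=input_size,
        conv1_filters=8, conv1_size=(5, 5, 3), conv1_stride=(2, 2, 2),
        pool1_region=(2, 2, 1), pool1_stride=(2, 2, 1),
        conv2_filters=24, conv2_size=(3, 3, 3), conv2_stride=(1, 1, 2),
        pool2_channels=3, fc_sizes=(32, 16),
    )


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 10
    learning_rate: float = 0.01
    epochs: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


# ---------------------------------------------------------------------------
# layers (numpy, analytic backprop)
# ---------------------------------------------------------------------------

class Conv3d:
    """Multi-channel valid 3D cross-correlation with stride."""

    def __init__(self, in_ch, out_ch, size, stride, rng):
        kh, kw, kt = size
        fan_in = in_ch * kh * kw * kt
        self.W = rng.standard_normal((out_ch, in_ch, kh, kw, kt)) / math.sqrt(fan_in)
        self.b = np.zeros(out_ch)
        self.stride = stride
        self.size = size

    def params(self):
        return [("W", self.W), ("b", self.b)]

    def forward(self, x, train):
        # x: (B, C, H, W, T)
        sy, sx, st = self.stride
        kh, kw, kt = self.size
        if x.shape[2] < kh or x.shape[3] < kw or x.shape[4] < kt:
            raise ValueError(
                f"conv kernel {self.size} does not fit input {x.shape[2:]}"
            )
        win = sliding_window_view(x, (kh, kw, kt), axis=(2, 3, 4))
        win = win[:, :, ::sy, ::sx, ::st]  # (B, C, OY, OX, OT, kh, kw, kt)
        self._win = win
        self._x_shape = x.shape
        out = np.einsum("bcyxtijk,ocijk->boyxt", win, self.W, optimize=True)
        return out + self.b[None, :, None, None, None]

    def backward(self, grad):
        self.gW = np.einsum("boyxt,bcyxtijk->ocijk", grad, self._win, optimize=True)
        self.gb = grad.sum(axis=(0, 2, 3, 4))
        gx = np.zeros(self._x_shape)
        sy, sx, st = self.stride
        kh, kw, kt = self.size
        B, OC, OY, OX, OT = grad.shape
        for a in range(kh):
            for b in range(kw):
                for c in range(kt):
                    contrib = np.einsum("boyxt,oc->bcyxt", grad, self.W[:, :, a, b, c],
                                        optimize=True)
                    gx[:, :, a : a + sy * OY : sy,
                       b : b + sx * OX : sx,
                       c : c + st * OT : st] += contrib
        return gx


class MaxPool3d:
    def __init__(self, region, stride):
        self.region = region
        self.stride = stride

    def params(self):
        return []

    def forward(self, x, train):
        py, px, pt = self.region
        sy, sx, st = self.stride
        win = sliding_window_view(x, (py, px, pt), axis=(2, 3, 4))
        win = win[:, :, ::sy, ::sx, ::st]
        B, C, OY, OX, OT = win.shape[:5]
        flat = win.reshape(B, C, OY, OX, OT, -1)
        self._arg = flat.argmax(axis=-1)
        self._x_shape = x.shape
        self._out_dims = (OY, OX, OT)
        return flat.max(axis=-1)

    def backward(self, grad):
        py, px, pt = self.region
        sy, sx, st = self.stride
        B, C, OY, OX, OT = grad.shape
        gx = np.zeros(self._x_shape)
        bi, ci, oy, ox, ot = np.indices((B, C, OY, OX, OT))
        a = self._arg
        dy, rem = np.divmod(a, px * pt)
        dx, dt = np.divmod(rem, pt)
        np.add.at(gx, (bi, ci, oy * sy + dy, ox * sx + dx, ot * st + dt), grad)
        return gx


class GlobalSpatialGroupPool:
    """Pool2 of the learned model: max over full space, one time unit, and
    fixed consecutive channel groups."""

    def __init__(self, channels_per_group):
        self.cpg = channels_per_group

    def params(self):
        return []

    def forward(self, x, train):
        B, C, H, W, T = x.shape
        G = C // self.cpg
        xr = x.reshape(B, G, self.cpg, H, W, T)
        flat = xr.transpose(0, 1, 5, 2, 3, 4).reshape(B, G, T, -1)
        self._arg = flat.argmax(axis=-1)
        self._shape = (B, C, H, W, T)
        return flat.max(axis=-1)  # (B, G, T)

    def backward(self, grad):
        B, C, H, W, T = self._shape
        G = C // self.cpg
        gx = np.zeros((B, G, T, self.cpg * H * W))
        bi, gi, ti = np.indices(grad.shape)
        np.add.at(gx, (bi, gi, ti, self._arg), grad)
        gx = gx.reshape(B, G, T, self.cpg, H, W).transpose(0, 1, 3, 4, 5, 2)
        return gx.reshape(B, C, H, W, T)


class BatchNorm:
    """Per-channel normalization; axis 1 is the channel axis (or features for 1-D)."""

    def __init__(self, n_ch, momentum=0.1, eps=1e-5):
        self.gamma = np.ones(n_ch)
        self.beta = np.zeros(n_ch)
        self.run_mean = np.zeros(n_ch)
        self.run_var = np.ones(n_ch)
        self.momentum = momentum
        self.eps = eps

    def params(self):
        return [("gamma", self.gamma), ("beta", self.beta)]

    def _axes(self, x):
        return (0,) + tuple(range(2, x.ndim))

    def _bshape(self, x):
        return (1, -1) + (1,) * (x.ndim - 2)

    def forward(self, x, train):
        axes = self._axes(x)
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.run_mean = (1 - self.momentum) * self.run_mean + self.momentum * mu
            self.run_var = (1 - self.momentum) * self.run_var + self.momentum * var
        else:
            mu, var = self.run_mean, self.run_var
        bs = self._bshape(x)
        self._xhat = (x - mu.reshape(bs)) / np.sqrt(var + self.eps).reshape(bs)
        self._var = var
        self._train = train
        self._m = x.size // x.shape[1]
        return self.gamma.reshape(bs) * self._xhat + self.beta.reshape(bs)

    def backward(self, grad):
        axes = self._axes(grad)
        bs = self._bshape(grad)
        self.ggamma = (grad * self._xhat).sum(axis=axes)
        self.gbeta = grad.sum(axis=axes)
        g = grad * self.gamma.reshape(bs)
        if not self._train:
            return g / np.sqrt(self._var + self.eps).reshape(bs)
        m = self._m
        inv_sd = 1.0 / np.sqrt(self._var + self.eps).reshape(bs)
        sum_g = g.sum(axis=axes).reshape(bs)
        sum_gx = (g * self._xhat).sum(axis=axes).reshape(bs)
        return inv_sd / m * (m * g - sum_g - self._xhat * sum_gx)


class ReLU:
    def params(self):
        return []

    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Flatten:
    def params(self):
        return []

    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Linear:
    def __init__(self, n_in, n_out, rng):
        self.W = rng.standard_normal((n_in, n_out)) / math.sqrt(n_in)
        self.b = np.zeros(n_out)

    def params(self):
        return [("W", self.W), ("b", self.b)]

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.gW = self._x.T @ grad
        self.gb = grad.sum(axis=0)
        return grad @ self.W.T


class LogSoftmax:
    def params(self):
        return []

    def forward(self, x, train):
        z = x - x.max(axis=1, keepdims=True)
        self._logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
        return self._logp

    def backward(self, grad):
        p = np.exp(self._logp)
        return grad - p * grad.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# model assembly and training
# ---------------------------------------------------------------------------

@dataclass
class LearnedModel:
    arch: LearnedArch
    n_classes: int
    layers: list = field(default_factory=list)
    feature_cutoff: int = 0  # layer index after which features are read out

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self):
        for li, layer in enumerate(self.layers):
            for name, arr in layer.params():
                yield li, name, arr

    def features(self, x):
        """Output of the last pooling/normalization stage, flattened; eval mode."""
        for layer in self.layers[: self.feature_cutoff]:
            x = layer.forward(x, train=False)
        return x.reshape(x.shape[0], -1)


def _out_extent(n, k, s):
    if n < k:
        return 0
    return (n - k) // s + 1


def build_learned_model(arch: LearnedArch, n_classes: int, seed: int = 0) -> LearnedModel:
    """Assemble the trainable network and verify dimensional consistency."""
    if n_classes < 2:
        raise ValueError("need >= 2 classes")
    rng = np.random.default_rng([seed, 271])
    H, W, T = arch.input_size

    def shrink(dims, size, stride, name):
        out = tuple(_out_extent(n, k, s) for n, k, s in zip(dims, size, stride))
        if min(out) < 1:
            raise ValueError(
                f"dimension underflow at {name}: input {dims}, kernel {size}, "
                f"stride {stride}"
            )
        return out

    dims = (H, W, T)
    layers: list = []
    dims = shrink(dims, arch.conv1_size, arch.conv1_stride, "conv1")
    layers += [Conv3d(1, arch.conv1_filters, arch.conv1_size, arch.conv1_stride, rng),
               BatchNorm(arch.conv1_filters)]
    dims = shrink(dims, arch.pool1_region, arch.pool1_stride, "pool1")
    layers += [MaxPool3d(arch.pool1_region, arch.pool1_stride),
               BatchNorm(arch.conv1_filters)]
    dims = shrink(dims, arch.conv2_size, arch.conv2_stride, "conv2")
    layers += [Conv3d(arch.conv1_filters, arch.conv2_filters, arch.conv2_size,
                      arch.conv2_stride, rng),
               BatchNorm(arch.conv2_filters)]
    layers += [GlobalSpatialGroupPool(arch.pool2_channels)]
    n_groups = arch.conv2_filters // arch.pool2_channels
    layers += [BatchNorm(n_groups)]
    feature_cutoff = len(layers)
    feat_dim = n_groups * dims[2]

    layers += [Flatten()]
    n_in = feat_dim
    for width in arch.fc_sizes:
        layers += [Linear(n_in, width, rng), ReLU(), BatchNorm(width)]
        n_in = width
    layers += [Linear(n_in, n_classes, rng), LogSoftmax()]
    return LearnedModel(arch, n_classes, layers, feature_cutoff)


def nll_loss(logp: np.ndarray, y_idx: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean negative log-likelihood over the log-soft-max head, plus its gradient."""
    n = logp.shape[0]
    loss = -float(logp[np.arange(n), y_idx].mean())
    grad = np.zeros_like(logp)
    grad[np.arange(n), y_idx] = -1.0 / n
    return loss, grad


def train_model(
    model: LearnedModel,
    clips: np.ndarray,
    labels: Sequence,
    cfg: TrainConfig | None = None,
) -> tuple[LearnedModel, list[float]]:
    """Train by SGD on the cross-entropy objective; returns per-epoch mean loss.

    ``clips`` is (n, H, W, T); shuffling is seeded by the TrainConfig.
    """
    cfg = cfg or TrainConfig()
    X = np.asarray(clips, dtype=float)
    if X.ndim != 4:
        raise ValueError("clips must be (n, H, W, T)")
    y = np.asarray(labels)
    classes, y_idx = np.unique(y, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("need >= 2 classes present in the training labels")
    if len(classes) != model.n_classes:
        raise ValueError(
            f"model was built for {model.n_classes} classes, labels have {len(classes)}"
        )
    model.classes = classes
    rng = np.random.default_rng([cfg.seed, 389])
    n = X.shape[0]
    trace: list[float] = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb = X[idx][:, None]  # add channel axis
            logp = model.forward(xb, train=True)
            loss, grad = nll_loss(logp, y_idx[idx])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, batch starting {start}: {loss}"
                )
            model.backward(grad)
            for li, name, arr in model.parameters():
                arr -= cfg.learning_rate * getattr(model.layers[li], "g" + name)
            losses.append(loss)
        trace.append(float(np.mean(losses)))
    return model, trace


def extract_learned_features(model: LearnedModel, clips: np.ndarray) -> np.ndarray:
    """Evaluation-mode features: linear layers and the log-soft-max head discarded."""
    X = np.asarray(clips, dtype=float)
    single = X.ndim == 3
    if single:
        X = X[None]
    if X.ndim != 4:
        raise ValueError("clips must be (H, W, T) or (n, H, W, T)")
    if X.shape[1:] != model.arch.input_size:
        raise ValueError(
            f"clip size {X.shape[1:]} does not match model input {model.arch.input_size}"
        )
    F = model.features(X[:, None])
    return F[0] if single else F
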
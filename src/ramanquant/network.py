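"""Residual depthwise-separable 1D CNN regressor, implemented in NumPy.

Layout of a signal batch is ``(batch, channels, length)``; every convolution
uses 'same' zero padding and stride 1, so the length is preserved end to end.
A separable convolution factors an ordinary convolution into a per-channel
depthwise filter (D_k * M weights) followed by a 1x1 pointwise mixing
(M * N weights), cutting the parameter count by the factor
(D_k*M + M*N)/(D_k*M*N) = 1/N + 1/D_k relative to a standard convolution.

Gradients are analytic (hand-written backprop per layer) and are checked
against central finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ConfigError, TrainingDivergenceError
from .losses import KernelHuberParams, kernel_huber, loss_gradient


# -- shape bookkeeping --------------------------------------------------------

@dataclass
class LayerSpec:
    """Shape of one convolution: kernel size D_k (odd), in channels M,
    out channels N, and the input length D_F."""

    kernel_size: int
    in_channels: int
    out_channels: int
    input_length: int

    def __post_init__(self):
        for name in ("kernel_size", "in_channels", "out_channels", "input_length"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.kernel_size % 2 == 0:
            raise ConfigError("kernel_size must be odd ('same' padding is symmetric)")


def cost_ratio(kernel_size: int, out_channels: int) -> float:
    """Parameter (and FLOP) ratio separable/standard: 1/N + 1/D_k."""
    if kernel_size < 1 or out_channels < 1:
        raise ValueError("kernel_size and out_channels must be >= 1")
    return 1.0 / out_channels + 1.0 / kernel_size


def separable_param_count(spec: LayerSpec, bias: bool = True) -> int:
    """D_k*M depthwise + M*N pointwise weights (+ N biases)."""
    n = spec.kernel_size * spec.in_channels + spec.in_channels * spec.out_channels
    return n + (spec.out_channels if bias else 0)


def standard_param_count(spec: LayerSpec, bias: bool = True) -> int:
    n = spec.kernel_size * spec.in_channels * spec.out_channels
    return n + (spec.out_channels if bias else 0)


# -- functional convolution primitives ---------------------------------------

def _same_windows(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, L) -> (B, C, L, k) sliding windows over zero-padded length."""
    pad = (k - 1) // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
    return sliding_window_view(xp, k, axis=2)


def depthwise_conv1d(x: np.ndarray, kernels: np.ndarray) -> np.ndarray:
    """Per-channel 'same' cross-correlation: channel c of the output depends
    on input channel c only.  ``kernels`` has shape (M, D_k)."""
    x = np.asarray(x, dtype=float)
    kernels = np.asarray(kernels, dtype=float)
    if x.ndim != 3:
        raise ValueError("x must be (batch, channels, length)")
    if kernels.ndim != 2 or kernels.shape[0] != x.shape[1]:
        raise ValueError(
            f"need one kernel per channel: got {kernels.shape} for {x.shape[1]} channels"
        )
    win = _same_windows(x, kernels.shape[1])
    return np.einsum("bclk,ck->bcl", win, kernels, optimize=True)


def pointwise_conv1d(x: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """1x1 convolution: a per-position linear map across channels.
    ``weights`` has shape (N, M)."""
    x = np.asarray(x, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if x.ndim != 3 or weights.ndim != 2 or weights.shape[1] != x.shape[1]:
        raise ValueError(
            f"shape mismatch: x {x.shape} vs weights {weights.shape}"
        )
    return np.tensordot(weights, x, axes=([1], [1])).transpose(1, 0, 2)


def separable_conv1d(x: np.ndarray, depthwise_kernels: np.ndarray,
                     pointwise_weights: np.ndarray) -> np.ndarray:
    """Depthwise filtering followed by pointwise channel mixing."""
    return pointwise_conv1d(depthwise_conv1d(x, depthwise_kernels), pointwise_weights)


# -- layers with backprop -----------------------------------------------------

class Layer:
    """Minimal stateful layer: ``forward`` caches what ``backward`` needs;
    parameters and their gradients are exposed as parallel lists."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _fan_in_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = np.sqrt(1.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Conv1d(Layer):
    """Standard 'same' 1D convolution with bias (used for the stem)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        if kernel_size % 2 == 0:
            raise ConfigError("kernel_size must be odd")
        fan_in = in_channels * kernel_size
        self.w = _fan_in_uniform(rng, (out_channels, in_channels, kernel_size), fan_in)
        self.b = _fan_in_uniform(rng, (out_channels,), fan_in)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x):
        self._win = _same_windows(x, self.w.shape[2])  # (B, M, L, k)
        return np.einsum("bmlk,nmk->bnl", self._win, self.w, optimize=True) \
            + self.b[None, :, None]

    def backward(self, dout):
        self.dw[...] = np.einsum("bmlk,bnl->nmk", self._win, dout, optimize=True)
        self.db[...] = dout.sum(axis=(0, 2))
        dwin = _same_windows(dout, self.w.shape[2])  # (B, N, L, k)
        return np.einsum("bnlk,nmk->bml", dwin, self.w[:, :, ::-1], optimize=True)


class Depthwise1d(Layer):
    def __init__(self, channels: int, kernel_size: int, rng: np.random.Generator):
        if kernel_size % 2 == 0:
            raise ConfigError("kernel_size must be odd")
        self.w = _fan_in_uniform(rng, (channels, kernel_size), kernel_size)
        self.dw = np.zeros_like(self.w)

    def params(self):
        return [self.w]

    def grads(self):
        return [self.dw]

    def forward(self, x):
        self._win = _same_windows(x, self.w.shape[1])
        return np.einsum("bclk,ck->bcl", self._win, self.w, optimize=True)

    def backward(self, dout):
        self.dw[...] = np.einsum("bclk,bcl->ck", self._win, dout, optimize=True)
        dwin = _same_windows(dout, self.w.shape[1])
        return np.einsum("bclk,ck->bcl", dwin, self.w[:, ::-1], optimize=True)


class Pointwise1d(Layer):
    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator, bias: bool = True):
        self.w = _fan_in_uniform(rng, (out_channels, in_channels), in_channels)
        self.b = _fan_in_uniform(rng, (out_channels,), in_channels) if bias else None
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b) if bias else None

    def params(self):
        return [self.w] + ([self.b] if self.b is not None else [])

    def grads(self):
        return [self.dw] + ([self.db] if self.db is not None else [])

    def forward(self, x):
        self._x = x
        out = pointwise_conv1d(x, self.w)
        if self.b is not None:
            out = out + self.b[None, :, None]
        return out

    def backward(self, dout):
        self.dw[...] = np.einsum("bnl,bml->nm", dout, self._x, optimize=True)
        if self.db is not None:
            self.db[...] = dout.sum(axis=(0, 2))
        return np.tensordot(self.w.T, dout, axes=([1], [1])).transpose(1, 0, 2)


class SeparableConv1d(Layer):
    """Depthwise (no bias) then pointwise (bias) convolution."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        self.depthwise = Depthwise1d(in_channels, kernel_size, rng)
        self.pointwise = Pointwise1d(in_channels, out_channels, rng)

    def params(self):
        return self.depthwise.params() + self.pointwise.params()

    def grads(self):
        return self.depthwise.grads() + self.pointwise.grads()

    def forward(self, x):
        return self.pointwise.forward(self.depthwise.forward(x))

    def backward(self, dout):
        return self.depthwise.backward(self.pointwise.backward(dout))


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class ResidualBlock(Layer):
    """separable conv -> activation -> separable conv, plus a skip path
    (identity, or a pointwise projection when channel counts differ);
    output = F(x) + skip(x), no activation after the add so a zero branch
    is exactly the identity."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        self.conv1 = SeparableConv1d(in_channels, out_channels, kernel_size, rng)
        self.act = ReLU()
        self.conv2 = SeparableConv1d(out_channels, out_channels, kernel_size, rng)
        self.projection = (
            Pointwise1d(in_channels, out_channels, rng, bias=False)
            if in_channels != out_channels else None
        )

    def _sublayers(self):
        layers = [self.conv1, self.conv2]
        if self.projection is not None:
            layers.append(self.projection)
        return layers

    def params(self):
        return [p for l in self._sublayers() for p in l.params()]

    def grads(self):
        return [g for l in self._sublayers() for g in l.grads()]

    def forward(self, x):
        branch = self.conv2.forward(self.act.forward(self.conv1.forward(x)))
        skip = x if self.projection is None else self.projection.forward(x)
        return branch + skip

    def backward(self, dout):
        dbranch = self.conv1.backward(self.act.backward(self.conv2.backward(dout)))
        dskip = dout if self.projection is None else self.projection.backward(dout)
        return dbranch + dskip


class GlobalAvgPool1d(Layer):
    def forward(self, x):
        self._length = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dout):
        return np.repeat(dout[:, :, None], self._length, axis=2) / self._length


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.w = _fan_in_uniform(rng, (out_features, in_features), in_features)
        self.b = _fan_in_uniform(rng, (out_features,), in_features)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.w, self.b]

    def grads(self):
        return [self.dw, self.db]

    def forward(self, x):
        self._x = x
        return x @ self.w.T + self.b

    def backward(self, dout):
        self.dw[...] = dout.T @ self._x
        self.db[...] = dout.sum(axis=0)
        return dout @ self.w


class ReLU2d(ReLU):
    pass


# -- model --------------------------------------------------------------------

@dataclass
class ModelConfig:
    """Default architecture: standard-conv stem (D_k=7, 8 channels), two
    residual separable blocks (D_k=5, 16 channels), global average pooling,
    a 16-unit dense layer and a scalar head.  Small enough (<2k weights) for
    a desk-scale genetic search of the initial weights."""

    input_length: int = 521
    in_channels: int = 1
    stem_kernel: int = 7
    stem_channels: int = 8
    n_blocks: int = 2
    block_channels: int = 16
    block_kernel: int = 5
    hidden_units: int = 16
    seed: int = 0

    def __post_init__(self):
        for name in ("input_length", "in_channels", "stem_channels",
                     "block_channels", "hidden_units"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        if self.n_blocks < 0:
            raise ConfigError("n_blocks must be >= 0")
        for name in ("stem_kernel", "block_kernel"):
            if getattr(self, name) < 1 or getattr(self, name) % 2 == 0:
                raise ConfigError(f"{name} must be a positive odd number")


def count_params(cfg: ModelConfig) -> int:
    """Analytic parameter count of :func:`build_model` for this config."""
    total = cfg.stem_kernel * cfg.in_channels * cfg.stem_channels + cfg.stem_channels
    ch = cfg.stem_channels
    for _ in range(cfg.n_blocks):
        spec1 = LayerSpec(cfg.block_kernel, ch, cfg.block_channels, cfg.input_length)
        spec2 = LayerSpec(cfg.block_kernel, cfg.block_channels, cfg.block_channels,
                          cfg.input_length)
        total += separable_param_count(spec1) + separable_param_count(spec2)
        if ch != cfg.block_channels:
            total += ch * cfg.block_channels  # projection, no bias
        ch = cfg.block_channels
    total += ch * cfg.hidden_units + cfg.hidden_units  # hidden dense
    total += cfg.hidden_units + 1                      # scalar head
    return total


class Model:
    """Sequential container over the layers; exposes forward/backward and a
    flat parameter view used by the genetic optimizer."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.layers: list[Layer] = [
            Conv1d(cfg.in_channels, cfg.stem_channels, cfg.stem_kernel, rng),
            ReLU(),
        ]
        ch = cfg.stem_channels
        for _ in range(cfg.n_blocks):
            self.layers.append(
                ResidualBlock(ch, cfg.block_channels, cfg.block_kernel, rng)
            )
            ch = cfg.block_channels
        self.layers += [
            GlobalAvgPool1d(),
            Dense(ch, cfg.hidden_units, rng),
            ReLU2d(),
            Dense(cfg.hidden_units, 1, rng),
        ]

    # -- parameter plumbing ---------------------------------------------------
    def parameters(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params()]

    def gradients(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads()]

    def n_params(self) -> int:
        return sum(p.size for p in self.parameters())

    def get_flat(self) -> np.ndarray:
        return np.concatenate([p.ravel() for p in self.parameters()])

    def set_flat(self, flat: np.ndarray) -> None:
        flat = np.asarray(flat, dtype=float)
        if flat.size != self.n_params():
            raise ValueError(
                f"flat vector has {flat.size} entries, model has {self.n_params()}"
            )
        offset = 0
        for p in self.parameters():
            p[...] = flat[offset:offset + p.size].reshape(p.shape)
            offset += p.size

    # -- computation ----------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """(B, C, L) -> (B,) predicted scaled concentrations."""
        out = x
        for layer in self.layers:
            out = layer.forward(out)
        return out[:, 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        """Backpropagate d(loss)/d(prediction) of shape (B,); fills gradients
        and returns d(loss)/d(input)."""
        dout = dy[:, None]
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


def build_model(cfg: ModelConfig) -> Model:
    """Deterministically initialized model; the realized parameter count must
    equal :func:`count_params`."""
    model = Model(cfg)
    expected = count_params(cfg)
    if model.n_params() != expected:
        raise ConfigError(
            f"parameter bookkeeping error: built {model.n_params()}, "
            f"expected {expected}"
        )
    return model


def _as_batch(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:  # (B, L) -> single input channel
        X = X[:, None, :]
    if X.ndim != 3:
        raise ValueError("input must be (batch, length) or (batch, channels, length)")
    return X


def predict(model: Model, X: np.ndarray) -> np.ndarray:
    """Forward pass on a (B, L) or (B, C, L) batch -> (B,) scaled predictions."""
    X = _as_batch(X)
    if X.shape[1] != model.cfg.in_channels or X.shape[2] != model.cfg.input_length:
        raise ValueError(
            f"input shape {X.shape[1:]} does not match model config "
            f"({model.cfg.in_channels}, {model.cfg.input_length})"
        )
    return model.forward(X)


@dataclass
class OptimizerConfig:
    """Adaptive-moment gradient descent settings; ``batch=None`` means full
    batch (the default calibration set has 40 samples)."""

    lr: float = 1e-2
    epochs: int = 300
    batch: int | None = None
    seed: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8


@dataclass
class TrainHistory:
    loss: list[float] = field(default_factory=list)


def train(
    model: Model,
    X: np.ndarray,
    y: np.ndarray,
    loss_params: KernelHuberParams,
    opt: OptimizerConfig | None = None,
    init: np.ndarray | None = None,
) -> tuple[Model, TrainHistory]:
    """Minimize the Kernel-Huber loss by Adam; optionally load a genetic-search
    chromosome as the initial weights.

    The history records the loss at the start of every epoch plus the final
    loss; if the last epoch is somehow worse than the best seen, the best
    weights are restored so training never degrades the model.
    """
    opt = opt or OptimizerConfig()
    X = _as_batch(X)
    y = np.asarray(y, dtype=float)
    if init is not None:
        model.set_flat(init)

    params = model.parameters()
    grads_view = model.gradients()
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    rng = np.random.default_rng(opt.seed)
    n = X.shape[0]
    batch = n if opt.batch is None else min(opt.batch, n)

    history = TrainHistory()
    best_loss = np.inf
    best_flat = model.get_flat()
    step = 0
    for epoch in range(opt.epochs):
        order = rng.permutation(n) if batch < n else np.arange(n)
        with np.errstate(over="ignore", invalid="ignore"):
            epoch_loss = kernel_huber(y, model.forward(X), loss_params)
        if not np.isfinite(epoch_loss):
            raise TrainingDivergenceError(epoch)
        history.loss.append(epoch_loss)
        if epoch_loss < best_loss:
            best_loss = epoch_loss
            best_flat = model.get_flat()
        with np.errstate(over="ignore", invalid="ignore"):
            for start in range(0, n, batch):
                idx = order[start:start + batch]
                yhat = model.forward(X[idx])
                dy = loss_gradient(y[idx], yhat, loss_params)
                model.backward(dy)
                step += 1
                for p, g, mi, vi in zip(params, grads_view, m, v):
                    mi[...] = opt.beta1 * mi + (1 - opt.beta1) * g
                    vi[...] = opt.beta2 * vi + (1 - opt.beta2) * g * g
                    mhat = mi / (1 - opt.beta1**step)
                    vhat = vi / (1 - opt.beta2**step)
                    p -= opt.lr * mhat / (np.sqrt(vhat) + opt.eps)

    with np.errstate(over="ignore", invalid="ignore"):
        final_loss = kernel_huber(y, model.forward(X), loss_params)
    if not np.isfinite(final_loss):
        raise TrainingDivergenceError(opt.epochs)
    if final_loss <= best_loss:
        history.loss.append(final_loss)
    else:  # keep the best epoch's weights
        model.set_flat(best_flat)
        history.loss.append(best_loss)
    return model, history
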
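"""Robust regression losses: Huber, Gaussian kernel, and the Kernel-Huber loss.

The Kernel-Huber loss weights each sample's Huber term by its Gaussian-kernel
similarity to the whole prediction vector,

    L = sum_i w_i * L_delta(y_i, yhat_i) / sum_i w_i,   w_i = sum_j K(y_i, yhat_j),

so samples whose targets sit in densely predicted regions of the response
(here: the low-concentration end of a log-spaced calibration series) carry
more weight, while isolated gross outliers are tempered by both the Huber
linear tail and their small kernel weights.  As sigma -> infinity every
w_i -> n and the loss reduces to the plain mean Huber loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class KernelHuberParams:
    """delta: Huber truncation tolerance; sigma: Gaussian kernel bandwidth,
    both on the (scaled) target axis.  ``detach_weights`` treats the kernel
    weights as constants during gradient computation (the default; stabler)."""

    delta: float = 1.0
    sigma: float = 1.0
    detach_weights: bool = True

    def __post_init__(self):
        if self.delta <= 0:
            raise ValueError("delta must be > 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


def huber(y, yhat, delta: float) -> np.ndarray:
    """Per-sample Huber loss: r^2/2 inside |r| <= delta, delta*|r| - delta^2/2
    beyond (continuous at the boundary)."""
    if delta <= 0:
        raise ValueError("delta must be > 0")
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have the same shape")
    r = y - yhat
    abs_r = np.abs(r)
    return np.where(abs_r <= delta, 0.5 * r**2, delta * abs_r - 0.5 * delta**2)


def gaussian_kernel(u, v, sigma: float):
    """exp(-(u - v)^2 / (2 sigma^2)); symmetric, in (0, 1]."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    return np.exp(-((u - v) ** 2) / (2.0 * sigma**2))


def _kernel_weights(y: np.ndarray, yhat: np.ndarray, sigma: float) -> np.ndarray:
    # w_i = sum_j K(y_i, yhat_j); the (i, j) kernel matrix is n x n
    return gaussian_kernel(y[:, None], yhat[None, :], sigma).sum(axis=1)


def kernel_huber(y, yhat, params: KernelHuberParams) -> float:
    """Kernel-weighted Huber loss (scalar, finite, >= 0; 0 iff y == yhat)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.size == 0:
        raise ValueError("kernel_huber requires at least one sample")
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have the same shape")
    w = _kernel_weights(y, yhat, params.sigma)
    h = huber(y, yhat, params.delta)
    return float(np.sum(w * h) / np.sum(w))


def loss_gradient(y, yhat, params: KernelHuberParams) -> np.ndarray:
    """Gradient of :func:`kernel_huber` with respect to ``yhat``.

    With ``detach_weights`` the kernel weights are held constant, giving
    dL/dyhat_i = -w_i * psi_delta(r_i) / sum(w) with psi_delta = clip(r, +-delta).
    Otherwise the weights' dependence on yhat is differentiated too.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.size == 0:
        raise ValueError("loss_gradient requires at least one sample")
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have the same shape")
    r = y - yhat
    psi = np.clip(r, -params.delta, params.delta)
    K = gaussian_kernel(y[:, None], yhat[None, :], params.sigma)  # (i, j)
    w = K.sum(axis=1)
    W = w.sum()
    grad = -(w * psi) / W
    if params.detach_weights:
        return grad
    # full gradient: L = N/D with N = sum_i w_i h_i, D = sum_i w_i and
    # dw_i/dyhat_k = K(y_i, yhat_k) * (y_i - yhat_k) / sigma^2
    h = huber(y, yhat, params.delta)
    dK = K * (y[:, None] - yhat[None, :]) / params.sigma**2  # dw_i/dyhat_j
    N = np.sum(w * h)
    dN = -(w * psi) + h @ dK          # dN/dyhat_k
    dD = dK.sum(axis=0)               # dD/dyhat_k
    return (dN * W - N * dD) / W**2


def mse(y, yhat) -> float:
    """Plain mean squared error (ablation baseline)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    return float(np.mean((y - yhat) ** 2))


def mae(y, yhat) -> float:
    """Plain mean absolute error (ablation baseline)."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    return float(np.mean(np.abs(y - yhat)))


def mean_huber(y, yhat, delta: float) -> float:
    """Unweighted mean Huber loss (the sigma -> infinity limit)."""
    return float(np.mean(huber(y, yhat, delta)))


def median_bandwidth(y) -> float:
    """Median pairwise |y_i - y_j| over distinct pairs -- the standard
    bandwidth heuristic used when sigma='auto'.  Falls back to 1.0 for
    degenerate target sets."""
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        return 1.0
    diffs = np.abs(y[:, None] - y[None, :])
    pair = diffs[np.triu_indices(y.size, k=1)]
    med = float(np.median(pair))
    return med if med > 0 else 1.0
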
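"""Spectral preprocessing: airPLS baseline correction, fingerprint-window
selection, train-only min-max scaling and the calibration/prediction split.

airPLS (adaptive iteratively reweighted penalized least squares) estimates a
fluorescence baseline by repeatedly fitting a Whittaker smoother while driving
the weights of channels sitting above the current fit to zero, so Raman bands
stop pulling the baseline up.  The Whittaker inner solve uses a sparse
second-order difference penalty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import spsolve
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import ConfigError, SelectionError, SingularSystemError
from .io import SpectraDataset

DEFAULT_WINDOWS = ((519.0, 617.0), (1292.0, 1713.0))


@dataclass
class AirPLSParams:
    """lam: roughness penalty; ratio_tol: stop when the mass of negative
    residuals falls below this fraction of the total signal mass."""

    lam: float = 1e5
    max_iter: int = 15
    ratio_tol: float = 0.05
    diff_order: int = 2

    def __post_init__(self):
        if self.lam <= 0:
            raise ConfigError("lam must be > 0")
        if not 0 < self.ratio_tol < 1:
            raise ConfigError("ratio_tol must be in (0, 1)")
        if self.max_iter < 1:
            raise ConfigError("max_iter must be >= 1")
        if self.diff_order != 2:
            raise ConfigError("only the order-2 difference penalty is supported")


@dataclass
class WindowSet:
    """Sorted, non-overlapping closed wavenumber intervals [lo, hi] in cm^-1."""

    intervals: tuple[tuple[float, float], ...] = DEFAULT_WINDOWS

    def __post_init__(self):
        self.intervals = tuple((float(lo), float(hi)) for lo, hi in self.intervals)
        for lo, hi in self.intervals:
            if lo >= hi:
                raise ConfigError(f"window [{lo}, {hi}] must have lo < hi")
        for (_, hi_prev), (lo_next, _) in zip(self.intervals, self.intervals[1:]):
            if lo_next <= hi_prev:
                raise ConfigError("windows must be sorted and non-overlapping")

    def mask(self, axis: np.ndarray) -> np.ndarray:
        axis = np.asarray(axis)
        m = np.zeros(axis.shape, dtype=bool)
        for lo, hi in self.intervals:
            m |= (axis >= lo) & (axis <= hi)
        return m

    @classmethod
    def parse(cls, text: str) -> "WindowSet":
        """Parse the CLI syntax ``"519:617,1292:1713"``."""
        intervals = []
        for part in text.split(","):
            lo, hi = part.split(":")
            intervals.append((float(lo), float(hi)))
        return cls(tuple(intervals))


def whittaker_smooth(y: np.ndarray, w: np.ndarray, lam: float) -> np.ndarray:
    """Solve (W + lam * D'D) z = W y with W = diag(w) and D the order-2
    difference operator, via a sparse direct solve."""
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("whittaker_smooth needs at least 3 points")
    if w.size != n:
        raise ValueError("y and w must have the same length")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if not np.any(w > 0):
        raise SingularSystemError("all-zero weights make the system singular")
    if lam < 0:
        raise ValueError("lam must be >= 0")
    D = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n), format="csc")
    A = sparse.diags(w) + lam * (D.T @ D)
    return spsolve(sparse.csc_matrix(A), w * y)


def airpls_baseline(y: np.ndarray, params: AirPLSParams | None = None) -> np.ndarray:
    """Estimate the baseline of one spectrum by adaptive iterative reweighting.

    Starting from uniform weights, each iteration fits a Whittaker smoother,
    then zeroes the weights of channels at or above the fit (candidate peaks)
    and up-weights channels below it by exp(iter*|d|/S), with S the mass of
    negative residuals; the endpoints are pinned at the maximum weight so the
    baseline stays anchored.  Stops when S drops below ratio_tol of the total
    signal mass or at max_iter.
    """
    params = params or AirPLSParams()
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("airpls_baseline requires finite input")
    w = np.ones_like(y)
    abs_y_sum = np.abs(y).sum()
    z = y.copy()
    for it in range(1, params.max_iter + 1):
        z = whittaker_smooth(y, w, params.lam)
        d = y - z
        neg = d < 0
        S = np.abs(d[neg]).sum()
        if S == 0 or S < params.ratio_tol * abs_y_sum or it == params.max_iter:
            break
        w[~neg] = 0.0
        w[neg] = np.exp(it * np.abs(d[neg]) / S)
        pin = np.exp(it * np.abs(d[neg]).max() / S)
        w[0] = w[-1] = pin
    return z


def correct_baseline(
    dataset: SpectraDataset, params: AirPLSParams | None = None
) -> SpectraDataset:
    """Subtract the airPLS baseline from every spectrum; axis and labels pass
    through untouched."""
    params = params or AirPLSParams()
    Y = dataset.intensity_matrix()
    corrected = np.vstack([y - airpls_baseline(y, params) for y in Y]) \
        if len(dataset) else Y
    return dataset.replace_intensities(corrected)


def select_windows(dataset: SpectraDataset, windows: WindowSet | None = None
                   ) -> SpectraDataset:
    """Keep exactly the channels whose wavenumber falls inside any window,
    concatenated in axis order."""
    windows = windows or WindowSet()
    mask = windows.mask(dataset.axis)
    if not mask.any():
        raise SelectionError(
            f"windows {windows.intervals} select no channels on this axis"
        )
    new_axis = dataset.axis[mask]
    Y = dataset.intensity_matrix()[:, mask] if len(dataset) else \
        np.empty((0, mask.sum()))
    return SpectraDataset.from_matrix(
        new_axis, Y, dataset.sample_ids,
        [s.concentration for s in dataset.spectra],
    )


# -- scaling ------------------------------------------------------------------

@dataclass
class ScalerState:
    """Train-fitted per-channel min-max state plus the target divisor.

    Channels constant on the training set get range 1 (offset = the constant),
    so transforms never divide by zero.  Values outside the training range map
    outside [0, 1] -- no clipping.
    """

    channel_min: np.ndarray
    channel_range: np.ndarray
    y_scale: float

    def transform_X(self, X: np.ndarray) -> np.ndarray:
        return (X - self.channel_min) / self.channel_range

    def inverse_transform_X(self, X: np.ndarray) -> np.ndarray:
        return X * self.channel_range + self.channel_min

    def transform_y(self, y: np.ndarray) -> np.ndarray:
        return np.asarray(y, dtype=float) / self.y_scale

    def inverse_transform_y(self, y: np.ndarray) -> np.ndarray:
        return np.asarray(y, dtype=float) * self.y_scale

    def transform_dataset(self, dataset: SpectraDataset) -> SpectraDataset:
        return dataset.replace_intensities(self.transform_X(dataset.intensity_matrix()))


def fit_scaler(train: SpectraDataset) -> ScalerState:
    if len(train) == 0:
        raise ValueError("cannot fit a scaler on an empty training set")
    X = train.intensity_matrix()
    lo = X.min(axis=0)
    rng = X.max(axis=0) - lo
    rng = np.where(rng == 0, 1.0, rng)
    concs = train.concentrations
    finite = concs[np.isfinite(concs)]
    y_scale = float(finite.max()) if finite.size and finite.max() > 0 else 1.0
    return ScalerState(lo, rng, y_scale)


def scale_features(
    train: SpectraDataset, others: list[SpectraDataset] | None = None
) -> tuple[SpectraDataset, list[SpectraDataset], ScalerState]:
    """Min-max scale intensities to [0,1] per channel, fitted on train only,
    and divide concentrations by the training maximum so targets lie in (0,1]."""
    state = fit_scaler(train)

    def apply(ds: SpectraDataset) -> SpectraDataset:
        scaled = state.transform_dataset(ds)
        for s in scaled.spectra:
            if s.concentration is not None:
                s.concentration = s.concentration / state.y_scale
        return scaled

    return apply(train), [apply(d) for d in (others or [])], state


# -- splitting ----------------------------------------------------------------

def split_dataset(
    dataset: SpectraDataset, n_train: int, seed: int = 0, stratified: bool = True
) -> tuple[SpectraDataset, SpectraDataset]:
    """Disjoint, exhaustive train/test split reproducible from ``seed``.

    The default stratifies over sorted concentration order: every
    ceil(n/n_test)-th sample (starting at the lowest concentration) goes to
    test, so the test set spans the calibration range.  ``stratified=False``
    draws a uniform random split instead.
    """
    n = len(dataset)
    if not 0 < n_train < n:
        raise ValueError(f"n_train must be in (0, {n}), got {n_train}")
    n_test = n - n_train
    rng = np.random.default_rng(seed)
    if stratified:
        concs = dataset.concentrations
        if not np.all(np.isfinite(concs)):
            raise ValueError("stratified split requires every sample to be labeled")
        order = np.argsort(concs, kind="stable")
        stride = int(np.ceil(n / n_test))
        test_idx = list(order[::stride][:n_test])
        if len(test_idx) < n_test:  # ceil-division under-fill: top up at random
            remaining = [i for i in order if i not in set(test_idx)]
            extra = rng.choice(len(remaining), n_test - len(test_idx), replace=False)
            test_idx += [remaining[int(e)] for e in extra]
    else:
        perm = rng.permutation(n)
        test_idx = list(perm[:n_test])
    test_set = set(test_idx)
    train_idx = [i for i in range(n) if i not in test_set]
    test_idx = sorted(test_idx)
    return dataset.subset(train_idx), dataset.subset(test_idx)


# -- sklearn-style transformers ----------------------------------------------

class AirPLSBaseline(TransformerMixin, BaseEstimator):
    """Stateless transformer subtracting the airPLS baseline row-wise from a
    (n_samples, n_channels) intensity matrix; composes with sklearn pipelines."""

    def __init__(self, lam: float = 1e5, max_iter: int = 15, ratio_tol: float = 0.05):
        self.lam = lam
        self.max_iter = max_iter
        self.ratio_tol = ratio_tol

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        params = AirPLSParams(self.lam, self.max_iter, self.ratio_tol)
        return np.vstack([x - airpls_baseline(x, params) for x in X])


class WindowSelector(TransformerMixin, BaseEstimator):
    """Column selector keeping channels inside fingerprint windows, given the
    wavenumber of each column."""

    def __init__(self, wavenumbers=None, windows=DEFAULT_WINDOWS):
        self.wavenumbers = wavenumbers
        self.windows = windows

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if self.wavenumbers is None:
            raise ConfigError("WindowSelector requires the wavenumbers of columns")
        axis = np.asarray(self.wavenumbers, dtype=float)
        if axis.size != X.shape[1]:
            raise ConfigError("wavenumbers length must match the number of columns")
        self.mask_ = WindowSet(tuple(self.windows)).mask(axis)
        if not self.mask_.any():
            raise SelectionError("windows select no channels")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        return np.asarray(X, dtype=float)[:, self.mask_]
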
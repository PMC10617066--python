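"""Synthetic SERS-like ofloxacin spectra with known ground truth.

The generator emulates the measured data this pipeline targets: a 239-2400
cm^-1 axis, Lorentzian bands concentrated in the 519-617 and 1292-1713 cm^-1
fingerprint windows, a smooth fluorescence background, white detector noise,
occasional cosmic-ray spikes, and a peak response that saturates at high
concentration via amplitude(c) = c / (1 + b*c).  Everything is reproducible
from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .io import SpectraDataset

#: (center cm^-1, half-width-at-half-max cm^-1, unit amplitude) of the default
#: ofloxacin-like band set.  The strongest band (1398 cm^-1) has unit height at
#: unit saturated concentration.
DEFAULT_PEAKS: tuple[tuple[float, float, float], ...] = (
    (540.0, 12.0, 0.45),
    (576.0, 10.0, 0.30),
    (605.0, 14.0, 0.25),
    (880.0, 16.0, 0.12),
    (1050.0, 20.0, 0.15),
    (1340.0, 14.0, 0.60),
    (1398.0, 12.0, 1.00),
    (1458.0, 16.0, 0.40),
    (1508.0, 12.0, 0.55),
    (1588.0, 14.0, 0.70),
    (1620.0, 10.0, 0.50),
)

_WINDOW_LOW = (519.0, 617.0)
_WINDOW_HIGH = (1292.0, 1713.0)


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic experiment.

    ``response_sat`` is the saturation constant b (ppm^-1) of the band
    amplitude law a*c/(1+b*c); b=0 recovers an exactly linear response.
    """

    axis_start: float = 239.0
    axis_stop: float = 2400.0
    axis_step: float = 1.0
    peaks: tuple[tuple[float, float, float], ...] = DEFAULT_PEAKS
    response_sat: float = 0.005
    baseline_amplitude: float = 10.0
    noise_sd: float = 0.2
    outlier_rate: float = 0.1
    n_samples: int = 51
    conc_min: float = 1.0
    conc_max: float = 100.0
    seed: int = 0

    def validate(self) -> None:
        if not self.axis_start < self.axis_stop:
            raise ConfigError("axis_start must be < axis_stop")
        if self.axis_step <= 0:
            raise ConfigError("axis_step must be > 0")
        if self.conc_min <= 0:
            raise ConfigError("conc_min must be > 0 (relative errors need nonzero truths)")
        if self.conc_min >= self.conc_max:
            raise ConfigError("conc_min must be < conc_max")
        if self.n_samples < 1:
            raise ConfigError("n_samples must be >= 1")
        if self.noise_sd < 0 or self.baseline_amplitude < 0:
            raise ConfigError("noise_sd and baseline_amplitude must be >= 0")
        if not 0 <= self.outlier_rate <= 1:
            raise ConfigError("outlier_rate must be in [0, 1]")
        if self.response_sat < 0:
            raise ConfigError("response_sat must be >= 0")
        if not self.peaks:
            raise ConfigError("at least one peak is required")
        centers = [p[0] for p in self.peaks]
        for lo, hi in (_WINDOW_LOW, _WINDOW_HIGH):
            if not any(lo <= c <= hi for c in centers):
                raise ConfigError(
                    f"at least one peak center must lie in [{lo}, {hi}] cm^-1"
                )

    def axis(self) -> np.ndarray:
        return np.arange(self.axis_start, self.axis_stop + 0.5 * self.axis_step,
                         self.axis_step)


@dataclass
class GroundTruth:
    """Per-sample decomposition of the emitted spectra.

    ``signals + baselines + noise`` reconstructs the emitted intensity matrix
    exactly; ``noise`` includes any outlier spikes.
    """

    concentrations: np.ndarray
    signals: np.ndarray
    baselines: np.ndarray
    noise: np.ndarray = field(default=None)  # type: ignore[assignment]


def concentration_grid(cfg: SyntheticConfig) -> np.ndarray:
    """Deterministic log-spaced concentrations covering [conc_min, conc_max]."""
    cfg.validate()
    if cfg.n_samples == 1:
        return np.array([cfg.conc_min])
    return np.geomspace(cfg.conc_min, cfg.conc_max, cfg.n_samples)


def lorentzian(axis: np.ndarray, center: float, width: float) -> np.ndarray:
    """Unit-height Lorentzian line; ``width`` is the half-width at half-max."""
    return width**2 / ((axis - center) ** 2 + width**2)


def peak_signal(cfg: SyntheticConfig, concentration: float) -> np.ndarray:
    """Noiseless, baseline-free band pattern at one concentration."""
    axis = cfg.axis()
    amp = concentration / (1.0 + cfg.response_sat * concentration)
    signal = np.zeros_like(axis)
    for center, width, unit_amp in cfg.peaks:
        signal += unit_amp * amp * lorentzian(axis, center, width)
    return signal


def _baseline_curve(cfg: SyntheticConfig, axis: np.ndarray,
                    scale: float, tilt: float) -> np.ndarray:
    """Slowly varying positive fluorescence background: a broad Gaussian bump
    plus a linear drift, overall scaled by ``baseline_amplitude``."""
    span = axis[-1] - axis[0]
    bump = np.exp(-(((axis - (axis[0] + 0.4 * span)) / (0.35 * span)) ** 2))
    drift = (axis[-1] - axis) / span
    return cfg.baseline_amplitude * scale * (0.55 * bump + 0.25 + 0.2 * tilt * drift)


def generate_dataset(cfg: SyntheticConfig) -> tuple[SpectraDataset, GroundTruth]:
    """Generate ``cfg.n_samples`` labeled spectra and their ground truth.

    Each spectrum is signal + baseline + Gaussian noise, with a single-channel
    spike added with probability ``outlier_rate`` per spectrum.  Baselines vary
    mildly from sample to sample (scale U(0.8, 1.2), drift sign/strength
    U(0.5, 1.5)) as acquisition-to-acquisition fluorescence drift does.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    axis = cfg.axis()
    concs = concentration_grid(cfg)
    n, L = len(concs), len(axis)

    signals = np.vstack([peak_signal(cfg, c) for c in concs])

    scales = rng.uniform(0.8, 1.2, size=n)
    tilts = rng.uniform(0.5, 1.5, size=n)
    if cfg.baseline_amplitude == 0:
        baselines = np.zeros((n, L))
    else:
        baselines = np.vstack(
            [_baseline_curve(cfg, axis, scales[i], tilts[i]) for i in range(n)]
        )

    noise = rng.normal(0.0, cfg.noise_sd, size=(n, L)) if cfg.noise_sd > 0 \
        else np.zeros((n, L))

    # cosmic-ray-style spikes: one random channel, large positive excursion
    spiked = rng.random(n) < cfg.outlier_rate
    for i in np.flatnonzero(spiked):
        channel = rng.integers(0, L)
        noise[i, channel] += rng.uniform(10.0, 50.0)

    intensities = signals + baselines + noise
    dataset = SpectraDataset.from_matrix(
        axis, intensities,
        sample_ids=[f"syn{i:03d}" for i in range(n)],
        concentrations=list(concs),
    )
    return dataset, GroundTruth(concs, signals, baselines, noise)
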
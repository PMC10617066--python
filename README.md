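# ramanquant

Robust concentration prediction from SERS Raman spectra.

Quantifying a drug like ofloxacin from its surface-enhanced Raman spectrum is
a nonlinear calibration problem: fluorescence baselines sit under the bands,
band intensity saturates at high concentration, and acquisition artifacts
(noise, cosmic-ray spikes) break least-squares fits.  `ramanquant` implements
a calibration pipeline built for exactly this setting:

* **airPLS** baseline correction (adaptive iteratively reweighted penalized
  least squares, sparse Whittaker inner solver) and fingerprint-window
  selection (519–617, 1292–1713 cm⁻¹);
* a **Kernel-Huber loss** — per-sample Huber terms weighted by Gaussian-kernel
  similarity between targets and predictions,
  `L = Σᵢ wᵢ L_δ(yᵢ, ŷᵢ) / Σᵢ wᵢ` with `wᵢ = Σⱼ exp(−(yᵢ−ŷⱼ)²/2σ²)`,
  robust to outliers and automatically emphasizing the dense low-ppm end of a
  log-spaced calibration series;
* a **residual depthwise-separable 1D CNN** regressor (NumPy, analytic
  backprop), whose separable convolutions use `D_k·M + M·N` weights instead
  of `D_k·M·N` (a `1/N + 1/D_k` reduction);
* an **adaptive genetic algorithm** that searches the network's initial
  weights, with crossover/mutation probabilities annealed per individual by
  generation and relative fitness, plus elitism and an optional catastrophe
  restart;
* the chemometric **metric suite**: R², MedAE, MAPE, RMSE, RPD = 1/√(1−R²),
  RMSEC.

A synthetic SERS-spectrum generator with exact ground truth (saturating
Lorentzian bands, smooth fluorescence background, noise, spikes) stands in
for the instrument, so the whole pipeline is testable end to end.
`docs/methods.md` describes the model and every default in detail.

## Library example

```python
from ramanquant import (RunConfig, run_all)

result = run_all(RunConfig(seed=1))
print(result.report.to_dict())
```

prints (seed 1):

```
{'R2': 0.99911..., 'MedAE': 0.2373..., 'MAPE': 6.0737..., 'RMSE': 0.8995...,
 'RPD': 33.554..., 'RMSEC': 0.6280...}
```

meaning: on the 11 held-out spectra the predicted concentrations explain
99.9% of the variance (R²), half the test predictions are within ±0.24 ppm
(MedAE), the mean relative error is 6.1% (MAPE), the test RMSE is 0.90 ppm on
the 1–100 ppm range, the residual predictive deviation 1/√(1−R²) ≈ 33.6
(values above 10 indicate an excellent calibration), and the training-set
RMSEC is 0.63 ppm.

The regressor also works as a scikit-learn estimator on any
`(n_samples, n_channels)` matrix:

```python
from sklearn.pipeline import Pipeline
from ramanquant import AirPLSBaseline, WindowSelector, KernelHuberCNNRegressor

pipe = Pipeline([
    ("baseline", AirPLSBaseline()),
    ("windows", WindowSelector(wavenumbers=axis)),
    ("cnn", KernelHuberCNNRegressor(random_state=0)),
])
pipe.fit(X_train, y_train)
```

## Command line

```bash
ramanquant simulate --seed 1 --out spectra.csv --labels labels.csv
ramanquant preprocess --spectra spectra.csv --labels labels.csv --out-dir prep/
ramanquant ga-init --data-dir prep/ --out ga.npz
ramanquant train --data-dir prep/ --init-from-ga ga.npz --out model.npz
ramanquant evaluate --model model.npz --data-dir prep/
ramanquant run-all --seed 1 --out report.json   # everything in one step
```

Spectra CSVs are wide (first column `wavenumber_cm-1`, one column per
sample); concentrations live in a separate `sample_id,concentration_ppm`
CSV.

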
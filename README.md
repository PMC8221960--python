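# spadflim

Fluorescence-lifetime estimation for SPAD-array TCSPC data.

Dynamic fluorescence-lifetime sensing reads a whole single-photon avalanche
diode (SPAD) array out as one "megapixel": every pixel timestamps photons
against the excitation pulse, and a single millisecond exposure already
yields a complete photon-arrival histogram.  Estimating the lifetime `tau`
of the resulting single-exponential decay — quickly, and at photon budgets
as low as a few hundred counts — is the core problem this package
addresses.  It is aimed at people building or simulating time-resolved
flow-cytometry and FLIM-style instruments who need a tested, self-contained
software stack: a physics-grounded simulator, the array-calibration
procedure, and three lifetime estimators with a common evaluation harness.

## What is inside

* **Simulation** (`spadflim.simulate`) — decays
  `y(t) = N_T · [IRF ∗ e^(−t/τ)](t)` on a 300 × 0.04 ns TDC grid with a
  Gaussian IRF (FWHM 230 ps, peak at bin 50), measurement noise
  `Y = max(0, y + √y·N(0,1) + N(0,σ))`, and full pixel-array frames with
  per-pixel IRF peak jitter, hot pixels and dark counts.
* **Calibration** (`spadflim.calibration`, `SPADArrayCalibrator`) —
  per-pixel peak maps and hot-pixel masks from IRF-only frames,
  integer-bin alignment and aggregation, leading-bin background
  subtraction, FWHM measurement.
* **Estimators** —
  * `QCNNLifetimeRegressor`: a five-layer 1-D convolutional network with
    DoReFa-style quantization (default 1-bit weights, 4-bit activations)
    trained with the straight-through estimator; forward and backward
    passes implemented directly in NumPy.
  * `CMMLifetimeEstimator`: the center-of-mass hardware algorithm
    `τ = Ω(c)·M·h`, with the truncation-bias correction `Ω` tabulated from
    the closed-form centroid of a truncated exponential and an optional
    `τ − τ_IRF` instrument correction.
  * `NLSDLifetimeEstimator`: nonlinear least-squares deconvolution with a
    zero-censored Gaussian noise model, the reference fitter.
* **Evaluation** (`spadflim.evaluation`) — accuracy `20·log10(τ/Δτ)` and
  precision `20·log10(τ/σ_τ)` in dB, estimator sweeps versus photon count,
  and per-frame event detection for flowing-particle scenes.
* **CLI** — `spadflim simulate|calibrate|train|ablate|estimate|evaluate|pipeline`.

All estimators follow scikit-learn conventions (`fit`/`predict`,
`get_params`, fitted attributes with trailing underscores) and compose with
sklearn tooling.

## Worked example

```python
import numpy as np
from spadflim import DatasetSpec, SimGrid, IRFSpec
from spadflim.simulate import make_irf, ground_truth_decay, add_noise, sample_dataset
from spadflim import QCNNLifetimeRegressor, CMMLifetimeEstimator
from spadflim.core import NoiseSpec

grid = SimGrid()                      # 300 bins x 0.04 ns
irf = make_irf(IRFSpec(), grid)       # Gaussian, FWHM 230 ps, peak bin 50

# train the quantized network on a small synthetic set (scaled for speed)
X, y, labels = sample_dataset(DatasetSpec(n_samples=10_000, seed=42))
qcnn = QCNNLifetimeRegressor(epochs=40, seed=0).fit(X, y, split_labels=labels)
print(f"validation MSE: {qcnn.best_validation_loss_:.3f} ns^2")

# estimate 100 noisy replicates of a 2.0 ns, 800-photon decay
clean = ground_truth_decay(2.0, 800.0, irf, grid)
rng = np.random.default_rng(7)
reps = np.stack([add_noise(clean, NoiseSpec(sigma=2.0), rng).counts
                 for _ in range(100)])
cmm = CMMLifetimeEstimator(irf_counts=irf.curve * 1e4).fit()
q, c = qcnn.predict(reps), cmm.predict(reps)
print(f"QCNN: {q.mean():.2f} +/- {q.std():.2f} ns")
print(f"CMM : {c.mean():.2f} +/- {c.std():.2f} ns")
```

Output:

```
validation MSE: 0.049 ns^2
QCNN: 1.94 +/- 0.22 ns
CMM : 2.71 +/- 0.19 ns
```

From 800-photon decays of a 2.0 ns fluorophore the network's mean estimate
lands within 0.06 ns of truth, while the center-of-mass estimate is pulled
~0.7 ns high by the background noise — the behaviour the dB sweep
(`spadflim evaluate sweep`) quantifies across the full photon-count range:
at low counts the network's accuracy exceeds the center-of-mass method's
accuracy at 20× the photon budget.

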
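"""Synthetic TCSPC decay and SPAD-array frame simulation.

The measurement model: a single-exponential fluorescence decay
``exp(-t/tau)`` is blurred by a Gaussian instrument response (IRF), binned
into ``n_bins`` TDC bins of width ``h``, and scaled so the noise-free
histogram sums to the photon budget ``N_T``.  Measured histograms add two
noise terms per bin: a normal approximation of Poisson shot noise with
variance equal to the expected count, and additive zero-mean Gaussian noise
of standard deviation ``sigma`` modelling background light and electronics.
Negative values are clamped to zero, as a photon counter cannot go below it.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import fftconvolve

from .core import (
    ArraySpec,
    DatasetSpec,
    DecayHistogram,
    IRFCurve,
    IRFSpec,
    NoiseSpec,
    PixelArrayFrame,
    SimGrid,
)

__all__ = [
    "make_irf",
    "delta_irf",
    "ground_truth_decay",
    "decay_matrix",
    "add_noise",
    "sample_dataset",
    "simulate_spad_frame",
]


def make_irf(spec: IRFSpec | None = None, grid: SimGrid | None = None) -> IRFCurve:
    """Discretise a Gaussian IRF onto the grid and normalise it to unit sum.

    The Gaussian is integrated over each bin (difference of the CDF at the bin
    edges) and centred on the bin-centre time of ``spec.peak_bin``.  If more
    than 1% of the Gaussian mass falls outside the window the returned curve
    is flagged ``truncated`` (it is still renormalised to sum to one).
    """
    spec = spec or IRFSpec()
    grid = grid or SimGrid()
    if spec.peak_bin > grid.n_bins:
        raise ValueError(f"peak_bin {spec.peak_bin} outside grid of {grid.n_bins} bins")
    from scipy.stats import norm

    center = (spec.peak_bin - 0.5) * grid.bin_width_ns
    edges = np.arange(grid.n_bins + 1) * grid.bin_width_ns
    cdf = norm.cdf(edges, loc=center, scale=spec.sigma_ns)
    mass = np.diff(cdf)
    captured = float(mass.sum())
    truncated = captured < 0.99
    return IRFCurve(curve=mass / captured, grid=grid, truncated=truncated)


def delta_irf(peak_bin: int, grid: SimGrid | None = None) -> IRFCurve:
    """An idealised IRF with all mass in one bin (useful for oracle tests)."""
    grid = grid or SimGrid()
    if not 1 <= peak_bin <= grid.n_bins:
        raise ValueError("peak_bin outside grid")
    curve = np.zeros(grid.n_bins)
    curve[peak_bin - 1] = 1.0
    return IRFCurve(curve=curve, grid=grid)


def _exp_kernel(tau_ns: float | np.ndarray, grid: SimGrid) -> np.ndarray:
    """Bin-integrated exponential decay kernel starting at t = 0.

    Bin ``j`` (0-based) holds the integral of ``exp(-t/tau)`` over
    ``[j*h, (j+1)*h]``, so discretisation is exact rather than a midpoint
    sample.  Accepts a vector of lifetimes and returns one row per lifetime.
    """
    tau = np.atleast_1d(np.asarray(tau_ns, dtype=float))
    if np.any(tau <= 0):
        raise ValueError("lifetimes must be positive")
    h = grid.bin_width_ns
    j = np.arange(grid.n_bins)
    # tau * (1 - e^{-h/tau}) * e^{-j h / tau}, constant factors removed later
    kern = np.exp(-np.outer(1.0 / tau, j * h)) * (1.0 - np.exp(-h / tau))[:, None]
    return kern


def decay_matrix(taus_ns: np.ndarray, irf: IRFCurve, grid: SimGrid) -> np.ndarray:
    """Noise-free, unit-sum decay shapes for a vector of lifetimes.

    Linear (zero-padded) convolution of the IRF with the exponential kernel,
    truncated to the window and renormalised so every row sums to exactly 1.
    """
    kern = _exp_kernel(taus_ns, grid)
    conv = fftconvolve(kern, irf.curve[None, :], axes=1)[:, : grid.n_bins]
    conv = np.clip(conv, 0.0, None)  # fft round-off can leave tiny negatives
    conv[conv < 1e-12 * conv.max(axis=1, keepdims=True)] = 0.0  # round-off junk
    sums = conv.sum(axis=1, keepdims=True)
    if np.any(sums <= 0):
        raise ValueError("decay has no mass inside the window")
    return conv / sums


def ground_truth_decay(
    tau_ns: float, n_total: float, irf: IRFCurve, grid: SimGrid | None = None
) -> DecayHistogram:
    """Expected (noise-free) decay histogram summing exactly to ``n_total``."""
    grid = grid or irf.grid
    if tau_ns <= 0:
        raise ValueError(f"tau_ns must be > 0, got {tau_ns}")
    if n_total <= 0:
        raise ValueError(f"n_total must be > 0, got {n_total}")
    shape = decay_matrix(np.array([tau_ns]), irf, grid)[0]
    return DecayHistogram(counts=n_total * shape, grid=grid)


def add_noise(
    clean: DecayHistogram,
    noise: NoiseSpec,
    rng_seed: int | np.random.Generator = 0,
) -> DecayHistogram:
    """Apply the measurement-noise model to a noise-free histogram.

    Per bin: ``Y = y + sqrt(y) * N(0,1) + N(0, sigma)``, independently drawn,
    then clamped at zero.  With ``sigma = 0`` and shot noise disabled this is
    the identity.
    """
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    y = clean.counts
    out = y.copy()
    if noise.poisson_enabled:
        out = out + np.sqrt(y) * rng.standard_normal(y.size)
    if noise.sigma > 0:
        out = out + rng.normal(0.0, noise.sigma, y.size)
    return DecayHistogram(counts=np.clip(out, 0.0, None), grid=clean.grid)


def sample_dataset(
    spec: DatasetSpec,
    irf: IRFCurve | None = None,
    grid: SimGrid | None = None,
    chunk_size: int = 4096,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw a synthetic dataset of noisy decays.

    Returns ``(histograms, true_taus, split_labels)`` where ``histograms`` is
    an ``(n_samples, n_bins)`` float array, ``true_taus`` the lifetimes in ns,
    and ``split_labels`` an array of ``"train"`` / ``"val"`` strings holding
    out the last ``val_fraction`` of samples.  Deterministic given
    ``spec.seed``.
    """
    grid = grid or SimGrid()
    irf = irf or make_irf(IRFSpec(), grid)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    taus = rng.uniform(*spec.tau_range_ns, n)
    nts = rng.uniform(*spec.nt_range, n)
    sigmas = rng.uniform(spec.sigma_min, np.maximum(spec.sigma_min, nts / spec.sigma_nt_divisor))

    hists = np.empty((n, grid.n_bins), dtype=np.float32)
    for start in range(0, n, chunk_size):
        sl = slice(start, min(start + chunk_size, n))
        shapes = decay_matrix(taus[sl], irf, grid)
        y = shapes * nts[sl, None]
        y = y + np.sqrt(y) * rng.standard_normal(y.shape)
        y = y + sigmas[sl, None] * rng.standard_normal(y.shape)
        hists[sl] = np.clip(y, 0.0, None)

    n_val = int(round(spec.val_fraction * n))
    labels = np.array(["train"] * (n - n_val) + ["val"] * n_val)
    return hists, taus, labels


def simulate_spad_frame(
    array: ArraySpec,
    tau_ns: float | None,
    photons_per_frame: float,
    irf: IRFSpec | None = None,
    grid: SimGrid | None = None,
    rng_seed: int | np.random.Generator = 0,
    peak_offsets: np.ndarray | None = None,
    hot_mask: np.ndarray | None = None,
) -> PixelArrayFrame:
    """Simulate one exposure frame of the pixel array.

    Each pixel's IRF peak is shifted by an integer bin offset drawn uniformly
    over ``+/- (peak_jitter_span_ns / 2)``; ``tau_ns=None`` simulates an
    IRF-only acquisition (scattered ultra-short excitation light, as used for
    calibration).  A Poisson photon budget is spread uniformly over pixels,
    except hot pixels which receive ``hot_pixel_rate_multiplier`` times the
    base rate; uniform dark counts are added to every bin.  Per-pixel-per-bin
    counts are drawn as independent Poissons of the resulting rates, which is
    exactly the Poisson-total-plus-multinomial description.

    Pass ``peak_offsets`` / ``hot_mask`` to reuse imperfections across frames
    of one simulated sensor; otherwise they are drawn from ``rng_seed``.
    """
    grid = grid or SimGrid()
    irf = irf or IRFSpec()
    if photons_per_frame < 0:
        raise ValueError("photons_per_frame must be >= 0")
    if array.peak_jitter_span_ns > grid.window_ns:
        raise ValueError("peak jitter span exceeds the measurement window")
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed

    shape2d = (array.n_rows, array.n_cols)
    half_span_bins = int(round(0.5 * array.peak_jitter_span_ns / grid.bin_width_ns))
    if peak_offsets is None:
        peak_offsets = rng.integers(-half_span_bins, half_span_bins + 1, size=shape2d)
    peak_offsets = np.asarray(peak_offsets, dtype=int)
    if hot_mask is None:
        hot_mask = rng.random(shape2d) < array.hot_pixel_fraction
    hot_mask = np.asarray(hot_mask, dtype=bool)

    # Base temporal profile shared by all pixels (before their peak shift).
    irf_curve = make_irf(irf, grid)
    if tau_ns is None:
        profile = irf_curve.curve
    else:
        profile = decay_matrix(np.array([tau_ns]), irf_curve, grid)[0]

    # Pixel photon-rate weights: uniform, hot pixels multiplied up.
    weights = np.ones(shape2d)
    weights[hot_mask] *= array.hot_pixel_rate_multiplier
    weights /= weights.sum()

    rates = np.empty(shape2d + (grid.n_bins,), dtype=float)
    pixel_rate = photons_per_frame * weights
    for off in np.unique(peak_offsets):
        shifted = _shift_zero_fill(profile, off)
        sel = peak_offsets == off
        rates[sel] = pixel_rate[sel, None] * shifted[None, :]
    rates += array.dark_rate_per_bin

    counts = rng.poisson(rates).astype(np.int64)
    return PixelArrayFrame(
        per_pixel_counts=counts,
        grid=grid,
        true_peak_offsets=peak_offsets,
        true_hot_mask=hot_mask,
    )


def _shift_zero_fill(vec: np.ndarray, shift: int) -> np.ndarray:
    """Shift a 1-D vector by ``shift`` bins, zero-filling (no wrap-around)."""
    out = np.zeros_like(vec)
    if shift == 0:
        out[:] = vec
    elif shift > 0:
        out[shift:] = vec[: vec.size - shift]
    else:
        out[:shift] = vec[-shift:]
    return out
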
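"""Core value types shared across the simulation, calibration and estimation layers.

Conventions
-----------
Bin indexing is 1-based in every user-facing interface (``peak_bin=50`` means
the fiftieth TDC bin) and documentation; internal NumPy arrays are 0-based, so
1-based bin ``i`` lives at array position ``i - 1``.  The photon arrival time
attributed to bin ``i`` is the bin centre ``(i - 1/2) * bin_width_ns``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SimGrid",
    "IRFSpec",
    "IRFCurve",
    "DecayHistogram",
    "NoiseSpec",
    "DatasetSpec",
    "ArraySpec",
    "PixelArrayFrame",
    "LifetimeEstimate",
]


@dataclass(frozen=True)
class SimGrid:
    """Time axis of a TCSPC histogram: ``n_bins`` TDC bins of ``bin_width_ns``."""

    n_bins: int = 300
    bin_width_ns: float = 0.04

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError(f"n_bins must be >= 2, got {self.n_bins}")
        if self.bin_width_ns <= 0:
            raise ValueError(f"bin_width_ns must be > 0, got {self.bin_width_ns}")

    @property
    def window_ns(self) -> float:
        """Total measurement window in ns."""
        return self.n_bins * self.bin_width_ns

    @property
    def bin_centers_ns(self) -> np.ndarray:
        """Photon time attributed to each bin (bin-centre convention)."""
        return (np.arange(self.n_bins) + 0.5) * self.bin_width_ns


@dataclass(frozen=True)
class IRFSpec:
    """Parametric Gaussian instrument response: FWHM in ns, peak at a 1-based bin."""

    fwhm_ns: float = 0.23
    peak_bin: int = 50

    def __post_init__(self) -> None:
        if self.fwhm_ns <= 0:
            raise ValueError(f"fwhm_ns must be > 0, got {self.fwhm_ns}")
        if self.peak_bin < 1:
            raise ValueError(f"peak_bin must be >= 1, got {self.peak_bin}")

    @property
    def sigma_ns(self) -> float:
        return self.fwhm_ns / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class IRFCurve:
    """Discretised, unit-sum instrument response on a grid.

    ``truncated`` flags specs whose Gaussian lost more than 1% of its mass to
    the window edges before renormalisation.
    """

    curve: np.ndarray
    grid: SimGrid
    truncated: bool = False

    def __post_init__(self) -> None:
        curve = np.asarray(self.curve, dtype=float)
        if curve.ndim != 1 or curve.size != self.grid.n_bins:
            raise ValueError("curve length must equal grid.n_bins")
        object.__setattr__(self, "curve", curve)

    @property
    def peak_bin(self) -> int:
        """1-based index of the maximum bin."""
        return int(np.argmax(self.curve)) + 1


@dataclass(frozen=True)
class DecayHistogram:
    """One TCSPC histogram: photon counts per time bin on a grid.

    Counts are stored as floats: expected (noise-free) decays and the additive
    Gaussian noise model both produce non-integer values.
    """

    counts: np.ndarray
    grid: SimGrid

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 1:
            raise ValueError("counts must be a 1-D vector")
        if counts.size != self.grid.n_bins:
            raise ValueError(
                f"counts length {counts.size} != grid.n_bins {self.grid.n_bins}"
            )
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total_counts(self) -> float:
        return float(self.counts.sum())

    @property
    def times_ns(self) -> np.ndarray:
        return self.grid.bin_centers_ns


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model: shot noise plus additive Gaussian background.

    ``sigma`` is the standard deviation (in counts) of the additive Gaussian
    term; ``poisson_enabled`` toggles the normal approximation of photon shot
    noise (std ``sqrt(y)`` per bin).
    """

    sigma: float = 0.0
    poisson_enabled: bool = True

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")


@dataclass(frozen=True)
class DatasetSpec:
    """Sampling law for a synthetic training/evaluation set of decays.

    Defaults follow the training-data design used throughout: lifetimes
    uniform on 0.1-5 ns, total counts uniform on 100-10^4, background sigma
    uniform on 1 to N_T/300, 50,000 samples with 20% held out for validation.
    """

    n_samples: int = 50_000
    val_fraction: float = 0.2
    tau_range_ns: tuple[float, float] = (0.1, 5.0)
    nt_range: tuple[float, float] = (100.0, 10_000.0)
    sigma_min: float = 1.0
    sigma_nt_divisor: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in [0, 1)")
        for name, (lo, hi) in (("tau_range_ns", self.tau_range_ns), ("nt_range", self.nt_range)):
            if not lo < hi:
                raise ValueError(f"{name} must be an ordered pair, got ({lo}, {hi})")
        if self.tau_range_ns[0] <= 0:
            raise ValueError("lifetimes must be positive")


@dataclass(frozen=True)
class ArraySpec:
    """Geometry and imperfection model of a simulated SPAD pixel array.

    ``peak_jitter_span_ns`` is the full span of the uniform per-pixel IRF peak
    offset; ``hot_pixel_rate_multiplier`` scales the photon rate of hot pixels;
    ``dark_rate_per_bin`` is the expected dark count per pixel per bin per
    frame (default tuned so an all-dark 192x128 frame totals about 300 counts,
    the background level of a 1 ms exposure).
    """

    n_rows: int = 192
    n_cols: int = 128
    peak_jitter_span_ns: float = 4.0
    hot_pixel_fraction: float = 0.01
    hot_pixel_rate_multiplier: float = 100.0
    dark_rate_per_bin: float = 4.07e-5

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("array must have at least one pixel")
        if self.peak_jitter_span_ns < 0:
            raise ValueError("peak_jitter_span_ns must be >= 0")
        if not 0.0 <= self.hot_pixel_fraction < 1.0:
            raise ValueError("hot_pixel_fraction must be in [0, 1)")
        if self.hot_pixel_fraction > 0 and self.hot_pixel_rate_multiplier <= 1:
            raise ValueError("hot_pixel_rate_multiplier must be > 1")
        if self.dark_rate_per_bin < 0:
            raise ValueError("dark_rate_per_bin must be >= 0")

    @property
    def n_pixels(self) -> int:
        return self.n_rows * self.n_cols


@dataclass(frozen=True)
class PixelArrayFrame:
    """Per-pixel histograms for one exposure frame, with simulator ground truth.

    ``true_peak_offsets`` (bins, may be negative) and ``true_hot_mask`` are
    bookkeeping from the simulator; calibration code must not read them.
    """

    per_pixel_counts: np.ndarray  # (n_rows, n_cols, n_bins)
    grid: SimGrid
    true_peak_offsets: np.ndarray | None = None
    true_hot_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.per_pixel_counts)
        if counts.ndim != 3:
            raise ValueError("per_pixel_counts must be (n_rows, n_cols, n_bins)")
        if counts.shape[2] != self.grid.n_bins:
            raise ValueError("last axis must equal grid.n_bins")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "per_pixel_counts", counts)
        for name in ("true_peak_offsets", "true_hot_mask"):
            arr = getattr(self, name)
            if arr is not None and np.shape(arr) != counts.shape[:2]:
                raise ValueError(f"{name} must match the pixel geometry")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.per_pixel_counts.shape


@dataclass(frozen=True)
class LifetimeEstimate:
    """An estimator's lifetime output with method tag and diagnostics."""

    tau_ns: float
    method: str
    status: str = "ok"
    diagnostics: dict = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return self.status == "ok"
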
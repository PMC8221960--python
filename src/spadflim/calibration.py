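"""SPAD-array calibration: per-pixel IRF peaks, hot pixels, alignment, background.

A SPAD array read out as a single "megapixel" sums histograms whose per-pixel
IRF peaks differ by several ns because each pixel's detector and TDC respond
at slightly different times.  The aggregate IRF is therefore broad until each
pixel's histogram is shifted so its peak lands on a common reference bin,
with abnormally noisy (hot) pixels masked out.  This module estimates the
per-pixel peak map and hot mask from IRF-only acquisitions, applies the
integer-bin alignment, subtracts the background estimated from the leading
bins, and measures the FWHM of the result.
"""

from __future__ import annotations

import warnings
from collections.abc import Sequence
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .core import DecayHistogram, PixelArrayFrame, SimGrid

__all__ = [
    "PixelCalibration",
    "estimate_peak_positions",
    "detect_hot_pixels",
    "align_and_aggregate",
    "subtract_background",
    "measure_fwhm",
    "SPADArrayCalibrator",
]


@dataclass(frozen=True)
class PixelCalibration:
    """Per-pixel alignment data: 1-based peak bins and a hot/invalid-pixel mask.

    ``peak_positions`` entries of 0 mark pixels whose peak could not be
    estimated (no counts); those pixels must also be masked.
    """

    peak_positions: np.ndarray
    hot_mask: np.ndarray
    reference_bin: int = 50

    def __post_init__(self) -> None:
        peaks = np.asarray(self.peak_positions, dtype=int)
        mask = np.asarray(self.hot_mask, dtype=bool)
        if peaks.shape != mask.shape:
            raise ValueError("peak map and hot mask must share the array geometry")
        if self.reference_bin < 1:
            raise ValueError("reference_bin must be >= 1")
        object.__setattr__(self, "peak_positions", peaks)
        object.__setattr__(self, "hot_mask", mask)


def _accumulate(frames: Sequence[PixelArrayFrame]) -> tuple[np.ndarray, SimGrid]:
    if len(frames) == 0:
        raise ValueError("need at least one frame")
    grid = frames[0].grid
    total = np.zeros(frames[0].shape, dtype=float)
    for f in frames:
        if f.shape != frames[0].shape or f.grid != grid:
            raise ValueError("frames disagree on geometry or grid")
        total += f.per_pixel_counts
    return total, grid


def estimate_peak_positions(
    frames: Sequence[PixelArrayFrame],
    smooth: bool | None = None,
    smooth_window: int = 3,
) -> np.ndarray:
    """Per-pixel IRF peak bins (1-based) from accumulated IRF-only frames.

    Frames are summed pixel-wise before peak finding.  Peaks are the argmax of
    the (optionally moving-average-smoothed) per-pixel histogram; argmax ties
    break toward the smaller bin.  ``smooth=None`` enables smoothing
    automatically for low-count pixels (< 100 accumulated counts).  Pixels
    with zero counts get peak 0 (invalid; mask them).
    """
    acc, grid = _accumulate(frames)
    flat = acc.reshape(-1, grid.n_bins)
    totals = flat.sum(axis=1)

    smoothed = flat
    if smooth is not False:
        from scipy.ndimage import uniform_filter1d

        sm = uniform_filter1d(flat, size=smooth_window, axis=1, mode="constant")
        if smooth:
            smoothed = sm
        else:  # auto: only low-count pixels benefit from smoothing
            low = totals < 100
            smoothed = np.where(low[:, None], sm, flat)

    # smoothing locates the peak neighbourhood; the raw argmax inside it is
    # the reported peak, so an isolated count stays on its own bin
    coarse = smoothed.argmax(axis=1)  # np.argmax takes the first maximum
    lo = np.maximum(coarse - smooth_window, 0)
    hi = np.minimum(coarse + smooth_window + 1, grid.n_bins)
    idx = lo[:, None] + np.arange(2 * smooth_window + 1)[None, :]
    vals = np.take_along_axis(flat, np.minimum(idx, grid.n_bins - 1), axis=1)
    vals = np.where(idx < hi[:, None], vals, -1.0)
    peaks = lo + vals.argmax(axis=1) + 1
    peaks[totals == 0] = 0
    return peaks.reshape(acc.shape[:2])


def detect_hot_pixels(
    frames: Sequence[PixelArrayFrame], k: float = 5.0
) -> np.ndarray:
    """Flag pixels whose total count exceeds ``k`` times the median pixel total."""
    acc, _ = _accumulate(frames)
    totals = acc.sum(axis=2)
    med = float(np.median(totals))
    if med == 0 and totals.max() == 0:
        warnings.warn("all pixels empty: returning an empty hot mask")
        return np.zeros(totals.shape, dtype=bool)
    return totals > k * med


def calibrate(
    frames: Sequence[PixelArrayFrame],
    reference_bin: int = 50,
    hot_k: float = 5.0,
) -> PixelCalibration:
    """Full calibration from IRF-only frames: peak map + hot mask."""
    peaks = estimate_peak_positions(frames)
    hot = detect_hot_pixels(frames, k=hot_k)
    hot = hot | (peaks == 0)
    return PixelCalibration(peak_positions=peaks, hot_mask=hot, reference_bin=reference_bin)


def align_and_aggregate(frame: PixelArrayFrame, calib: PixelCalibration) -> DecayHistogram:
    """Shift each unmasked pixel's histogram onto the reference bin and sum.

    Shifts are integer bins (``reference_bin - peak_position``); counts
    shifted out of the window are dropped, vacated bins fill with zero.
    """
    counts = frame.per_pixel_counts
    if calib.peak_positions.shape != counts.shape[:2]:
        raise ValueError("calibration geometry does not match the frame")
    n_bins = frame.grid.n_bins
    flat = counts.reshape(-1, n_bins)
    shifts = (calib.reference_bin - calib.peak_positions).reshape(-1)
    keep = ~calib.hot_mask.reshape(-1)

    agg = np.zeros(n_bins, dtype=float)
    for s in np.unique(shifts[keep]):
        rows = flat[keep & (shifts == s)].sum(axis=0)
        if s == 0:
            agg += rows
        elif s > 0:
            agg[s:] += rows[: n_bins - s]
        else:
            agg[:s] += rows[-s:]
    return DecayHistogram(counts=agg, grid=frame.grid)


def subtract_background(hist: DecayHistogram, n_lead_bins: int = 50) -> DecayHistogram:
    """Subtract the mean of the first ``n_lead_bins`` from every bin (clamped at 0).

    The leading bins precede the IRF rise and so estimate the uniform
    background (dark counts, stray light).  Warns when the histogram peak
    falls inside the lead window, where that assumption breaks.
    """
    if n_lead_bins >= hist.grid.n_bins:
        raise ValueError("n_lead_bins must be smaller than the histogram")
    if int(np.argmax(hist.counts)) + 1 < n_lead_bins:
        warnings.warn("histogram peak inside the background-estimation window")
    level = float(hist.counts[:n_lead_bins].mean())
    return DecayHistogram(counts=np.clip(hist.counts - level, 0.0, None), grid=hist.grid)


def measure_fwhm(hist: DecayHistogram) -> float:
    """Full width at half maximum in ns, by linear interpolation at half-max.

    Scans outward from the global peak to the first crossing of half-maximum
    on each side and interpolates the crossing time linearly between bin
    centres.  Raises if either side never falls below half-maximum inside the
    window.
    """
    y = hist.counts
    t = hist.times_ns
    peak = int(np.argmax(y))
    half = y[peak] / 2.0

    def cross(idx_range) -> float:
        prev = peak
        for i in idx_range:
            if y[i] < half:
                # linear interpolation between bins i and prev
                frac = (half - y[i]) / (y[prev] - y[i])
                return t[i] + frac * (t[prev] - t[i])
            prev = i
        raise ValueError("half-maximum not reached inside the window")

    left = cross(range(peak - 1, -1, -1))
    right = cross(range(peak + 1, len(y)))
    return float(right - left)


class SPADArrayCalibrator(BaseEstimator, TransformerMixin):
    """Scikit-learn-style calibration transformer for SPAD-array frames.

    ``fit`` consumes IRF-only frames and learns the per-pixel peak map and hot
    mask (``peak_positions_``, ``hot_mask_``, ``calibration_``); ``transform``
    maps frames to aligned, aggregated (and optionally background-subtracted)
    histogram vectors.

    Parameters
    ----------
    reference_bin : int
        1-based bin every pixel's peak is aligned to.
    hot_k : float
        Hot-pixel threshold in multiples of the median pixel total.
    subtract_bg : bool
        Apply leading-bin background subtraction after aggregation.
    n_lead_bins : int
        Number of leading bins used for the background estimate.
    """

    def __init__(
        self,
        reference_bin: int = 50,
        hot_k: float = 5.0,
        subtract_bg: bool = False,
        n_lead_bins: int = 50,
    ):
        self.reference_bin = reference_bin
        self.hot_k = hot_k
        self.subtract_bg = subtract_bg
        self.n_lead_bins = n_lead_bins

    def fit(self, X: Sequence[PixelArrayFrame], y=None) -> "SPADArrayCalibrator":
        calib = calibrate(X, reference_bin=self.reference_bin, hot_k=self.hot_k)
        self.calibration_ = calib
        self.peak_positions_ = calib.peak_positions
        self.hot_mask_ = calib.hot_mask
        self.grid_ = X[0].grid
        return self

    def transform(self, X: Sequence[PixelArrayFrame]) -> np.ndarray:
        if not hasattr(self, "calibration_"):
            raise RuntimeError("calibrator is not fitted")
        out = np.empty((len(X), self.grid_.n_bins))
        for i, frame in enumerate(X):
            hist = align_and_aggregate(frame, self.calibration_)
            if self.subtract_bg:
                hist = subtract_background(hist, self.n_lead_bins)
            out[i] = hist.counts
        return out
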
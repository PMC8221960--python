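"""Tests of peak mapping, hot-pixel masking, alignment and FWHM measurement."""

import numpy as np
import pytest

from spadflim.calibration import (
    PixelCalibration,
    SPADArrayCalibrator,
    align_and_aggregate,
    detect_hot_pixels,
    estimate_peak_positions,
    measure_fwhm,
    subtract_background,
)
from spadflim.core import ArraySpec, DecayHistogram, IRFSpec, PixelArrayFrame, SimGrid
from spadflim.estimators import CMMConfig, cmm_lifetime
from spadflim.simulate import (
    delta_irf,
    ground_truth_decay,
    make_irf,
    simulate_spad_frame,
)


def _frame_from_counts(counts: np.ndarray, grid: SimGrid) -> PixelArrayFrame:
    return PixelArrayFrame(per_pixel_counts=counts, grid=grid)


@pytest.fixture(scope="module")
def jittered_frames():
    """IRF-only frames of one simulated sensor with fixed imperfections."""
    grid = SimGrid()
    array = ArraySpec(
        n_rows=24, n_cols=24, peak_jitter_span_ns=4.0,
        hot_pixel_fraction=0.01, hot_pixel_rate_multiplier=100.0,
        dark_rate_per_bin=1e-4,
    )
    irf = IRFSpec(peak_bin=100)  # jitter stays inside the window
    first = simulate_spad_frame(array, None, 5e5, irf, grid, rng_seed=42)
    frames = [first] + [
        simulate_spad_frame(
            array, None, 5e5, irf, grid, rng_seed=43 + i,
            peak_offsets=first.true_peak_offsets, hot_mask=first.true_hot_mask,
        )
        for i in range(3)
    ]
    return frames, irf, grid


class TestEstimatePeakPositions:
    def test_single_pixel_gaussian_peak(self, grid):
        irf = make_irf(IRFSpec(), grid)
        rng = np.random.default_rng(0)
        counts = rng.poisson(1e4 * irf.curve)[None, None, :]
        peaks = estimate_peak_positions([_frame_from_counts(counts, grid)])
        assert abs(int(peaks[0, 0]) - 50) <= 1

    def test_single_photon_pixel(self, grid):
        counts = np.zeros((1, 1, grid.n_bins))
        counts[0, 0, 72] = 1  # 1-based bin 73
        peaks = estimate_peak_positions([_frame_from_counts(counts, grid)])
        assert peaks[0, 0] == 73

    def test_zero_count_pixel_marked_invalid(self, grid):
        counts = np.zeros((1, 2, grid.n_bins))
        counts[0, 0, 10] = 5
        peaks = estimate_peak_positions([_frame_from_counts(counts, grid)])
        assert peaks[0, 1] == 0

    def test_recovers_simulated_offsets(self, jittered_frames):
        frames, irf, _ = jittered_frames
        peaks = estimate_peak_positions(frames)
        truth = irf.peak_bin + frames[0].true_peak_offsets
        ok = ~frames[0].true_hot_mask
        recovered = np.abs(peaks[ok] - truth[ok]) <= 1
        assert recovered.mean() >= 0.99


class TestDetectHotPixels:
    def test_single_outlier_flagged(self, grid):
        counts = np.ones((4, 4, grid.n_bins))
        counts[2, 3] *= 100
        mask = detect_hot_pixels([_frame_from_counts(counts, grid)])
        assert mask[2, 3]
        assert mask.sum() == 1

    def test_uniform_array_unflagged(self, grid):
        counts = np.ones((4, 4, grid.n_bins))
        mask = detect_hot_pixels([_frame_from_counts(counts, grid)])
        assert not mask.any()

    def test_all_zero_warns_empty_mask(self, grid):
        counts = np.zeros((3, 3, grid.n_bins))
        with pytest.warns(UserWarning):
            mask = detect_hot_pixels([_frame_from_counts(counts, grid)])
        assert not mask.any()

    def test_sensitivity_and_false_positives_on_simulated_array(self, jittered_frames):
        frames, _, _ = jittered_frames
        truth = frames[0].true_hot_mask
        mask = detect_hot_pixels(frames)
        assert truth.any()
        sensitivity = mask[truth].mean()
        fpr = mask[~truth].mean()
        assert sensitivity >= 0.99
        assert fpr <= 0.001


class TestAlignAndAggregate:
    def test_two_pixels_one_shifted(self, grid):
        base = np.zeros(grid.n_bins)
        base[40:60] = np.arange(20.0)
        counts = np.stack([base, np.roll(base, 3)])[None, :, :]
        calib = PixelCalibration(
            peak_positions=np.array([[59, 62]]),
            hot_mask=np.zeros((1, 2), dtype=bool),
            reference_bin=59,
        )
        agg = align_and_aggregate(_frame_from_counts(counts, grid), calib)
        assert np.allclose(agg.counts, 2 * base)

    def test_masked_pixel_contributes_nothing(self, grid):
        base = np.ones(grid.n_bins)
        counts = np.stack([base, 100 * base])[None, :, :]
        calib = PixelCalibration(
            peak_positions=np.array([[50, 50]]),
            hot_mask=np.array([[False, True]]),
            reference_bin=50,
        )
        agg = align_and_aggregate(_frame_from_counts(counts, grid), calib)
        assert np.allclose(agg.counts, base)

    def test_alignment_is_identity_when_already_aligned(self, grid):
        rng = np.random.default_rng(3)
        counts = rng.poisson(5.0, (2, 2, grid.n_bins)).astype(float)
        peaks = np.full((2, 2), 50)
        calib = PixelCalibration(
            peak_positions=peaks, hot_mask=np.zeros((2, 2), bool), reference_bin=50
        )
        agg = align_and_aggregate(_frame_from_counts(counts, grid), calib)
        assert np.array_equal(agg.counts, counts.sum(axis=(0, 1)))

    def test_photon_conservation_with_shift_accounting(self, grid):
        rng = np.random.default_rng(4)
        counts = rng.poisson(2.0, (1, 3, grid.n_bins)).astype(float)
        peaks = np.array([[50, 45, 55]])
        calib = PixelCalibration(
            peak_positions=peaks, hot_mask=np.zeros((1, 3), bool), reference_bin=50
        )
        agg = align_and_aggregate(_frame_from_counts(counts, grid), calib)
        shifted_out = counts[0, 1, -5:].sum() + counts[0, 2, :5].sum()
        assert agg.total_counts == pytest.approx(counts.sum() - shifted_out)

    def test_alignment_sharpens_jittered_aggregate(self):
        # hot-free sensor isolates the jitter-broadening effect
        grid = SimGrid()
        irf = IRFSpec(peak_bin=100)
        array = ArraySpec(
            n_rows=32, n_cols=32, peak_jitter_span_ns=4.0,
            hot_pixel_fraction=0.0, dark_rate_per_bin=1e-4,
        )
        first = simulate_spad_frame(array, None, 1e6, irf, grid, rng_seed=15)
        frames = [first] + [
            simulate_spad_frame(
                array, None, 1e6, irf, grid, rng_seed=16 + i,
                peak_offsets=first.true_peak_offsets, hot_mask=first.true_hot_mask,
            )
            for i in range(2)
        ]
        unaligned = DecayHistogram(
            counts=sum(f.per_pixel_counts.sum(axis=(0, 1)) for f in frames).astype(float),
            grid=grid,
        )
        assert measure_fwhm(unaligned) > 3.0
        cal = SPADArrayCalibrator(reference_bin=irf.peak_bin).fit(frames)
        agg = DecayHistogram(counts=cal.transform(frames).sum(axis=0), grid=grid)
        assert measure_fwhm(agg) <= 0.28

    def test_geometry_mismatch_rejected(self, grid):
        counts = np.ones((2, 2, grid.n_bins))
        calib = PixelCalibration(
            peak_positions=np.full((3, 3), 50), hot_mask=np.zeros((3, 3), bool)
        )
        with pytest.raises(ValueError):
            align_and_aggregate(_frame_from_counts(counts, grid), calib)


class TestSubtractBackground:
    def test_flat_histogram_vanishes(self, grid):
        hist = DecayHistogram(counts=np.full(grid.n_bins, 7.0), grid=grid)
        with pytest.warns(UserWarning):  # flat input: peak inside lead window
            out = subtract_background(hist)
        assert np.all(out.counts == 0)

    def test_constant_baseline_removed_exactly(self, grid):
        # decay starts after the lead window, so the lead bins are pure baseline
        decay = ground_truth_decay(2.0, 5000.0, delta_irf(100, grid), grid)
        with_bg = DecayHistogram(counts=decay.counts + 3.0, grid=grid)
        out = subtract_background(with_bg)
        assert np.allclose(out.counts, decay.counts, atol=1e-9)

    def test_improves_cmm_against_dark_counts(self, grid):
        # paired comparison over noisy replicates with a uniform background
        irf = make_irf(IRFSpec(), grid)
        decay = ground_truth_decay(2.0, 5000.0, irf, grid)
        cfg = CMMConfig(window_start_bin=50, window_end_bin=grid.n_bins)
        rng = np.random.default_rng(8)
        err_raw, err_sub = [], []
        for _ in range(100):
            noisy = rng.poisson(decay.counts + 2.0).astype(float)
            hist = DecayHistogram(counts=noisy, grid=grid)
            est_raw = cmm_lifetime(hist, cfg)
            est_sub = cmm_lifetime(subtract_background(hist), cfg)
            err_raw.append(abs(est_raw.tau_ns - 2.0))
            err_sub.append(abs(est_sub.tau_ns - 2.0))
        assert np.mean(err_sub) < np.mean(err_raw)

    def test_lead_bins_must_fit(self, grid):
        hist = DecayHistogram(counts=np.ones(grid.n_bins), grid=grid)
        with pytest.raises(ValueError):
            subtract_background(hist, n_lead_bins=grid.n_bins)


class TestMeasureFWHM:
    def test_gaussian_relation(self):
        # FWHM of a Gaussian = 2 sqrt(2 ln 2) sigma = 2.3548 sigma
        grid = SimGrid(n_bins=600, bin_width_ns=0.01)
        t = grid.bin_centers_ns
        counts = np.exp(-0.5 * ((t - 3.0) / 0.1) ** 2)
        fwhm = measure_fwhm(DecayHistogram(counts=counts, grid=grid))
        assert fwhm == pytest.approx(0.2355, abs=0.005)

    def test_default_irf_fwhm(self, irf, grid):
        hist = DecayHistogram(counts=irf.curve, grid=grid)
        assert measure_fwhm(hist) == pytest.approx(0.230, abs=0.04)

    @pytest.mark.parametrize("width_bins", [3, 10, 40])
    def test_rectangular_pulse(self, width_bins, grid):
        counts = np.zeros(grid.n_bins)
        counts[100 : 100 + width_bins] = 5.0
        fwhm = measure_fwhm(DecayHistogram(counts=counts, grid=grid))
        expected = width_bins * grid.bin_width_ns
        assert abs(fwhm - expected) <= grid.bin_width_ns

    def test_monotone_histogram_raises(self, grid):
        counts = np.linspace(1.0, 10.0, grid.n_bins)
        with pytest.raises(ValueError):
            measure_fwhm(DecayHistogram(counts=counts, grid=grid))
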
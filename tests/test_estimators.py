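"""Tests of the Omega bias-correction table, CMM, and the NLSD reference fitter."""

import numpy as np
import pytest

from spadflim.core import DecayHistogram, SimGrid
from spadflim.estimators import (
    CMMConfig,
    CMMLifetimeEstimator,
    NLSDLifetimeEstimator,
    OmegaLUT,
    cmm_lifetime,
    nlsd_fit,
    truncated_exp_centroid,
)
from spadflim.simulate import add_noise, delta_irf, ground_truth_decay, make_irf
from spadflim.core import IRFSpec, NoiseSpec


@pytest.fixture(scope="module")
def lut():
    return OmegaLUT()


class TestOmegaLUT:
    def test_short_lifetime_limit_is_identity(self, lut):
        # truncation bias vanishes for short lifetimes: Omega(c) ~ c
        c = np.linspace(0.005, 0.05, 20)
        assert np.allclose(lut(c), c, rtol=2e-3)

    def test_long_lifetime_limit_is_half_window(self):
        # the centroid of an ever-flatter decay tends to the uniform value 1/2
        assert truncated_exp_centroid(1e6) == pytest.approx(0.5, abs=1e-5)

    def test_round_trip_inversion(self, lut):
        r = np.geomspace(0.01, 3.0, 500)
        c = truncated_exp_centroid(r)
        assert np.max(np.abs(lut(c) - r) / r) <= 1e-6

    def test_strictly_monotone(self, lut):
        c = np.linspace(0.01, 0.45, 200)
        assert np.all(np.diff(lut(c)) > 0)

    def test_centroid_at_or_past_half_window_rejected(self, lut):
        with pytest.raises(ValueError):
            lut(0.5)


class TestCMM:
    @pytest.mark.parametrize("tau", [0.5, 1.0, 2.0, 4.0])
    def test_oracle_recovery_on_truncated_exponentials(self, tau):
        # noise-free delta-IRF decays over a 10 ns window
        grid = SimGrid(n_bins=250, bin_width_ns=0.04)
        hist = ground_truth_decay(tau, 1e4, delta_irf(1, grid), grid)
        cfg = CMMConfig(window_start_bin=1, window_end_bin=250)
        est = cmm_lifetime(hist, cfg)
        assert est.ok
        assert est.tau_ns == pytest.approx(tau, rel=0.01)

    def test_raw_centroid_and_corrected_value(self):
        grid = SimGrid(n_bins=250, bin_width_ns=0.04)
        hist = ground_truth_decay(2.0, 1e4, delta_irf(1, grid), grid)
        cfg = CMMConfig(window_start_bin=1, window_end_bin=250)
        est = cmm_lifetime(hist, cfg)
        centroid_time = est.diagnostics["centroid_norm"] * 250 * 0.04
        assert centroid_time == pytest.approx(1.932, abs=0.005)
        assert est.tau_ns == pytest.approx(2.000, abs=0.005)

    def test_delta_input_gives_near_zero_lifetime(self, grid):
        counts = np.zeros(grid.n_bins)
        counts[49] = 1000.0  # all photons in the first window bin
        est = cmm_lifetime(DecayHistogram(counts=counts, grid=grid),
                           CMMConfig(window_start_bin=50, window_end_bin=300))
        assert est.ok
        assert abs(est.tau_ns) <= grid.bin_width_ns

    def test_unsubtracted_background_biases_upward(self, grid):
        irf = make_irf(IRFSpec(), grid)
        clean = ground_truth_decay(1.5, 5000.0, irf, grid)
        cfg = CMMConfig(window_start_bin=50, window_end_bin=300)
        est_clean = cmm_lifetime(clean, cfg)
        with_bg = DecayHistogram(counts=clean.counts + 2.0, grid=grid)
        est_bg = cmm_lifetime(with_bg, cfg)
        assert est_bg.tau_ns > est_clean.tau_ns

    def test_scale_equivariance(self, grid):
        irf = make_irf(IRFSpec(), grid)
        hist = ground_truth_decay(2.0, 1000.0, irf, grid)
        cfg = CMMConfig(window_start_bin=50, window_end_bin=300)
        a = cmm_lifetime(hist, cfg).tau_ns
        scaled = DecayHistogram(counts=hist.counts * 37.5, grid=grid)
        b = cmm_lifetime(scaled, cfg).tau_ns
        assert a == pytest.approx(b, rel=1e-12)

    def test_time_shift_covariance(self, grid):
        irf = make_irf(IRFSpec(), grid)
        hist = ground_truth_decay(1.0, 1000.0, irf, grid)
        shift = 20
        shifted = DecayHistogram(counts=np.roll(hist.counts, shift), grid=grid)
        a = cmm_lifetime(hist, CMMConfig(window_start_bin=50, window_end_bin=280)).tau_ns
        b = cmm_lifetime(
            shifted, CMMConfig(window_start_bin=50 + shift, window_end_bin=280 + shift)
        ).tau_ns
        assert a == pytest.approx(b, rel=1e-9)

    def test_empty_window_reports_error_status(self, grid):
        counts = np.zeros(grid.n_bins)
        counts[:10] = 5.0  # all counts before the window
        est = cmm_lifetime(DecayHistogram(counts=counts, grid=grid),
                           CMMConfig(window_start_bin=50, window_end_bin=300))
        assert not est.ok

    def test_irf_subtraction_identity_and_accuracy(self, grid):
        # tau_calibrated = tau_CMM - tau_CMM_IRF, and stays close to truth
        irf = make_irf(IRFSpec(), grid)
        hist = ground_truth_decay(1.0, 1e5, irf, grid)
        irf_hist = DecayHistogram(counts=irf.curve * 1e5, grid=grid)
        cfg = CMMConfig(window_start_bin=50, window_end_bin=300)
        with_cal = cmm_lifetime(hist, cfg, irf_hist=irf_hist)
        raw = cmm_lifetime(hist, cfg)
        tau_irf = cmm_lifetime(irf_hist, cfg)
        assert with_cal.tau_ns == pytest.approx(raw.tau_ns - tau_irf.tau_ns, abs=1e-12)
        assert with_cal.tau_ns == pytest.approx(1.0, rel=0.06)

    def test_sklearn_wrapper_matches_function(self, grid):
        irf = make_irf(IRFSpec(), grid)
        hists = np.stack([
            ground_truth_decay(t, 2000.0, irf, grid).counts for t in (0.5, 1.0, 2.0)
        ])
        est = CMMLifetimeEstimator().fit()
        preds = est.predict(hists)
        cfg = CMMConfig(window_start_bin=50, window_end_bin=300)
        expected = [
            cmm_lifetime(DecayHistogram(counts=h, grid=grid), cfg).tau_ns for h in hists
        ]
        assert np.allclose(preds, expected)


class TestNLSD:
    def test_noise_free_recovery(self, grid, irf):
        hist = ground_truth_decay(4.0, 1e4, irf, grid)
        est = nlsd_fit(hist, irf)
        assert est.ok
        assert est.tau_ns == pytest.approx(4.00, abs=0.02)

    def test_noisy_replicate_recovery(self, grid, irf):
        # background sigma stratified over the quantiles of its law
        # U(1, N_T/300): same distribution, lower Monte-Carlo variance
        tau, n_t = 2.0, 5000.0
        clean = ground_truth_decay(tau, n_t, irf, grid)
        rng = np.random.default_rng(17)
        sigmas = 1.0 + (np.arange(100) + 0.5) / 100 * (n_t / 300.0 - 1.0)
        taus = [
            nlsd_fit(add_noise(clean, NoiseSpec(sigma=s), rng), irf).tau_ns
            for s in sigmas
        ]
        assert np.mean(taus) == pytest.approx(tau, rel=0.02)

    def test_baseline_only_input_flagged_degenerate(self, grid, irf):
        hist = DecayHistogram(counts=np.full(grid.n_bins, 20.0), grid=grid)
        est = nlsd_fit(hist, irf)
        assert not est.ok
        assert est.diagnostics["amplitude"] < 1.0

    def test_beats_cmm_on_long_truncated_lifetimes(self, grid, irf):
        # strong truncation (tau > window/4) favours the explicit model fit
        cfg = CMMConfig(window_start_bin=50, window_end_bin=300)
        irf_hist = DecayHistogram(counts=irf.curve * 1e4, grid=grid)
        errs_nlsd, errs_cmm = [], []
        for tau in (3.5, 4.0, 4.5, 5.0):
            hist = ground_truth_decay(tau, 1e4, irf, grid)
            errs_nlsd.append(nlsd_fit(hist, irf).tau_ns - tau)
            errs_cmm.append(cmm_lifetime(hist, cfg, irf_hist).tau_ns - tau)
        rmse = lambda e: float(np.sqrt(np.mean(np.square(e))))
        assert rmse(errs_nlsd) < rmse(errs_cmm)

    def test_sklearn_wrapper_round_trip(self, grid, irf):
        hists = np.stack([
            ground_truth_decay(t, 5000.0, irf, grid).counts for t in (1.0, 3.0)
        ])
        preds = NLSDLifetimeEstimator(irf=irf).fit().predict(hists)
        assert np.allclose(preds, [1.0, 3.0], rtol=0.005)
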
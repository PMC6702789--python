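"""Lagged cross-correlation engine, peak finding, lag maps."""

import numpy as np
import pytest

import slfomap as sm
from slfomap._corr import fracshift, lagged_pearson, zscore
from slfomap.errors import WindowError


def bandlimited(n, dt, seed, low=0.01, high=0.15):
    spec = sm.PhantomSpec(grid_shape=(1, 1, 1), tr=dt, n_timepoints=n,
                          slfo_band=(low, high), seed=seed)
    return sm.make_driving_signal(spec)


class TestLaggedCrosscorr:
    def test_self_correlation_peaks_at_zero(self):
        x = bandlimited(600, 1.0, 1)
        probe = sm.ProbeRegressor(x, fs=1.0)
        corr = sm.lagged_crosscorr(probe, x, sm.SearchWindow(-10, 10))
        assert corr.r[np.argmin(np.abs(corr.lags))] == pytest.approx(1.0)
        lag, r, ok = sm.find_peak(corr)
        assert lag == pytest.approx(0.0, abs=1e-9) and ok

    def test_integer_shift_sign_convention(self):
        # a voxel that is the probe delayed by +3 samples peaks at +3 s
        x = bandlimited(600, 1.0, 2)
        voxel = np.roll(x, 3)
        probe = sm.ProbeRegressor(x, fs=1.0)
        corr = sm.lagged_crosscorr(probe, voxel, sm.SearchWindow(-10, 10))
        lag, r, ok = sm.find_peak(corr)
        assert lag == pytest.approx(3.0, abs=0.05)
        assert r > 0.99

    def test_matches_naive_oracle(self, naive_corr):
        # production FFT/cumsum engine vs shift-and-Pearson loop, 1e-10
        rng = np.random.default_rng(3)
        x = rng.standard_normal(200)
        y = rng.standard_normal(200)
        R = lagged_pearson(x, y, -20, 20)
        expected = naive_corr(x, y, -20, 20)
        assert np.max(np.abs(R - expected)) < 1e-10

    def test_affine_invariance(self):
        x = bandlimited(400, 1.0, 4)
        y = bandlimited(400, 1.0, 5)
        r1 = lagged_pearson(x, y, -10, 10)
        r2 = lagged_pearson(3.0 * x + 7.0, -0.5 * y + 2.0, -10, 10)
        assert np.allclose(np.abs(r1), np.abs(r2), atol=1e-10)

    def test_pure_sinusoid_multiple_peaks_in_window(self):
        # pseudoperiodicity hazard: once the window exceeds the spectral
        # peak's period, several correlation peaks compete for the argmax
        t = np.arange(600) * 1.0
        x = np.sin(2 * np.pi * 0.1 * t)
        probe = sm.ProbeRegressor(zscore(x), fs=1.0)
        corr = sm.lagged_crosscorr(probe, x, sm.SearchWindow(-12, 12))
        r = corr.r
        peaks = [corr.lags[i] for i in range(1, len(r) - 1)
                 if r[i] >= r[i - 1] and r[i] >= r[i + 1] and r[i] > 0.5]
        assert len(peaks) >= 3  # at 0 and +/- one 10 s period
        assert any(abs(abs(p) - 10.0) < 1.5 for p in peaks)

    def test_spectral_gap_broadens_peak(self):
        # low-pass-heavy probe -> broader correlation peak (>= 1.5x)
        def width(x):
            probe = sm.ProbeRegressor(x, fs=1.0)
            corr = sm.lagged_crosscorr(probe, x, sm.SearchWindow(-30, 30))
            return np.sum(corr.r > 0.9 * np.nanmax(corr.r))

        narrow = bandlimited(1200, 1.0, 6, low=0.01, high=0.05)
        full = bandlimited(1200, 1.0, 6, low=0.01, high=0.15)
        assert width(narrow) >= 1.5 * width(full)

    def test_window_wider_than_half_record_rejected(self):
        x = bandlimited(400, 1.0, 7)
        probe = sm.ProbeRegressor(x, fs=1.0)
        with pytest.raises(WindowError):
            sm.lagged_crosscorr(probe, x, sm.SearchWindow(-250, 250))

    def test_zero_variance_voxel_flagged_not_thrown(self):
        x = bandlimited(400, 1.0, 8)
        probe = sm.ProbeRegressor(x, fs=1.0)
        corr = sm.lagged_crosscorr(probe, np.zeros(400), sm.SearchWindow(-5, 5))
        assert np.all(np.isnan(corr.r))
        lag, r, ok = sm.find_peak(corr)
        assert not ok and np.isnan(lag)

    def test_gcc_and_direct_agree_for_flat_probe(self):
        x = bandlimited(800, 1.0, 9)
        voxel = fracshift(x, 4.0)
        probe = sm.ProbeRegressor(x, fs=1.0)
        w = sm.SearchWindow(-10, 10)
        lag_d, _, _ = sm.find_peak(sm.lagged_crosscorr(probe, voxel, w, "direct"))
        lag_g, _, _ = sm.find_peak(sm.lagged_crosscorr(probe, voxel, w, "gcc"))
        assert abs(lag_d - lag_g) <= 0.5  # tr/2


class TestFindPeak:
    def test_symmetric_neighbors_keep_discrete_lag(self):
        corr = sm.CorrFunction(lags=np.arange(-3, 4, 1.0),
                               r=np.array([0.1, 0.3, 0.6, 0.9, 0.6, 0.3, 0.1]))
        lag, r, ok = sm.find_peak(corr)
        assert lag == pytest.approx(0.0) and r == pytest.approx(0.9) and ok

    def test_fractional_delay_recovery_vs_dense_oracle(self):
        x = bandlimited(600, 1.0, 10)
        voxel = fracshift(x, 2.3)
        probe = sm.ProbeRegressor(x, fs=1.0)
        corr = sm.lagged_crosscorr(probe, voxel, sm.SearchWindow(-10, 10))
        lag, r, ok = sm.find_peak(corr)
        assert ok
        assert abs(lag - 2.3) < 0.1
        # independent oracle: dense 0.01 s grid of band-limited shifts
        taus = np.arange(1.5, 3.1, 0.01)
        dense = [np.corrcoef(fracshift(x, tau), voxel)[0, 1] for tau in taus]
        assert abs(lag - taus[int(np.argmax(dense))]) < 0.1

    def test_boundary_argmax_flagged(self):
        corr = sm.CorrFunction(lags=np.arange(-3, 4, 1.0),
                               r=np.array([0.9, 0.6, 0.3, 0.1, 0.0, 0.1, 0.2]))
        lag, r, ok = sm.find_peak(corr)
        assert lag == -3.0 and not ok

    def test_tie_breaks_toward_smallest_abs_lag(self):
        corr = sm.CorrFunction(lags=np.arange(-2, 3, 1.0),
                               r=np.array([0.8, 0.2, 0.1, 0.2, 0.8]))
        lag, _, _ = sm.find_peak(corr)
        assert abs(lag) <= 2.0  # deterministic: picks one of the ties
        corr2 = sm.CorrFunction(lags=np.arange(-2, 3, 1.0),
                                r=np.array([0.8, 0.2, 0.8, 0.2, 0.8]))
        lag2, _, _ = sm.find_peak(corr2)
        assert lag2 == pytest.approx(0.0)


class TestMapDelays:
    def test_noiseless_recovery(self, noiseless_radial, truth_probe):
        _, bold, truth = noiseless_radial
        maps = sm.map_delays(bold, truth_probe, sm.SearchWindow(-10, 10),
                             prefilter=False)
        err = maps.lag[bold.mask] - truth.true_delay[bold.mask]
        assert np.sqrt(np.nanmean(err**2)) < bold.tr / 10
        assert np.nanmin(maps.maxcorr) > 0.98
        assert not maps.failed.any()
        assert np.all(maps.r2[bold.mask] > 0.95)

    def test_lag_shift_property(self, truth_probe, noiseless_radial):
        # delaying a voxel by an extra Delta increases its lag by Delta
        _, bold, truth = noiseless_radial
        x = truth_probe.samples
        w = sm.SearchWindow(-12, 12)
        base = sm.find_peak(sm.lagged_crosscorr(truth_probe, x, w))[0]
        for delta in (-3.0, -1.5, 0.75, 2.25, 4.0):
            shifted = fracshift(x, delta)
            lag = sm.find_peak(sm.lagged_crosscorr(truth_probe, shifted, w))[0]
            assert lag - base == pytest.approx(delta, abs=0.05)

    def test_amplitude_map_scales_with_signal(self, noiseless_radial,
                                              truth_probe):
        spec, bold, truth = noiseless_radial
        scaled = bold.with_data((bold.data - spec.offset) * 2.5 + spec.offset)
        m1 = sm.map_delays(bold, truth_probe, sm.SearchWindow(-10, 10),
                           prefilter=False)
        m2 = sm.map_delays(scaled, truth_probe, sm.SearchWindow(-10, 10),
                           prefilter=False)
        ratio = m2.amplitude[bold.mask] / m1.amplitude[bold.mask]
        assert np.allclose(ratio, 2.5, atol=0.01)


class TestRecenterZeroTime:
    def _maps_with_lags(self, lags):
        shape = lags.shape
        return sm.LagMaps(
            lag=lags.astype(float), maxcorr=np.ones(shape),
            amplitude=np.ones(shape), r2=np.ones(shape),
            sigmask=np.ones(shape, bool), failed=np.zeros(shape, bool),
            mask=np.ones(shape, bool), window=sm.SearchWindow(-15, 15),
            tr=1.0)

    def test_constant_field_goes_to_zero(self):
        maps = self._maps_with_lags(np.full((4, 4, 2), 3.7))
        out = sm.recenter_zero_time(maps)
        assert np.allclose(out.lag, 3.7 - round(3.7 / 0.25) * 0.25)
        assert np.abs(out.lag).max() < 0.25

    def test_idempotent(self):
        rng = np.random.default_rng(12)
        maps = self._maps_with_lags(rng.normal(4.0, 1.5, size=(6, 6, 3)))
        once = sm.recenter_zero_time(maps)
        twice = sm.recenter_zero_time(once)
        assert np.array_equal(once.lag, twice.lag)

    def test_radial_map_gets_both_signs(self, noiseless_radial, truth_probe):
        _, bold, truth = noiseless_radial
        maps = sm.map_delays(bold, truth_probe, sm.SearchWindow(-10, 10),
                             prefilter=False)
        out = sm.recenter_zero_time(maps)
        vals = out.lag[bold.mask]
        assert vals.min() < 0 < vals.max()


class TestAutocorrSidelobes:
    def test_bandlimited_noise_clean(self):
        x = bandlimited(2400, 0.72, 13, low=0.009, high=0.15)
        probe = sm.ProbeRegressor(x, fs=1 / 0.72, band=sm.FilterBand(0.009, 0.15))
        lobes = sm.autocorr_sidelobes(probe, sm.SearchWindow(-15, 15),
                                      r_thresh=0.3, warn=False)
        assert lobes == []

    def test_pure_sinusoid_sidelobe_at_period(self):
        t = np.arange(600) * 1.0
        probe = sm.ProbeRegressor(zscore(np.sin(2 * np.pi * 0.1 * t)), fs=1.0)
        with pytest.warns(sm.errors.SidelobeWarning):
            lobes = sm.autocorr_sidelobes(probe, sm.SearchWindow(-15, 15))
        period, mag = lobes[0]
        assert period == pytest.approx(10.0, abs=1.0)
        assert mag > 0.9

    def test_pseudoperiodic_driver_detected(self):
        spec = sm.PhantomSpec(tr=0.72, n_timepoints=1200,
                              slfo_kind="pseudoperiodic", peak_freq=0.1,
                              peak_fraction=0.8, seed=14)
        x = sm.make_driving_signal(spec)
        probe = sm.ProbeRegressor(x, fs=1 / 0.72)
        lobes = sm.autocorr_sidelobes(probe, sm.SearchWindow(-15, 15),
                                      warn=False)
        assert any(abs(p - 10.0) <= 1.0 for p, _ in lobes)
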
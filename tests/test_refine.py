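"""Probe refinement, multi-pass convergence, despeckling."""

import warnings

import numpy as np
import pytest

import slfomap as sm
import slfomap.refine
from slfomap._corr import lagged_pearson, zscore
from slfomap.errors import EmptyMaskError, SidelobeWarning


def perfect_maps(bold, truth, window=sm.SearchWindow(-15, 15)):
    """LagMaps filled from ground truth (all significant, none failed)."""
    shape = bold.mask.shape
    return sm.LagMaps(
        lag=truth.true_delay.astype(float), maxcorr=np.full(shape, 0.99),
        amplitude=np.ones(shape), r2=np.full(shape, 0.98),
        sigmask=bold.mask.copy(), failed=np.zeros(shape, bool),
        mask=bold.mask.copy(), window=window, tr=bold.tr)


class TestRefineRegressor:
    def test_true_lags_reverse_the_construction(self, noiseless_radial,
                                                truth_probe):
        _, bold, truth = noiseless_radial
        maps = perfect_maps(bold, truth)
        refined = sm.refine_regressor(bold, maps, min_voxels=50)
        target = zscore(sm.bandpass_lfo(truth.driving_signal, bold.fs,
                                        sm.FilterBand()))
        # interior comparison: the filter's edge transients are not part
        # of the realignment being tested
        r = sm.refine.interior_corr(refined.samples, target, bold.fs)
        assert r >= 0.999
        assert refined.provenance == "refined:pass-1"

    def test_refined_beats_global_mean_at_snr1(self, snr1_radial):
        _, bold, truth = snr1_radial
        gm = sm.extract_global_mean(bold)
        maps = perfect_maps(bold, truth)
        refined = sm.refine_regressor(bold, maps, min_voxels=50)
        target = zscore(sm.bandpass_lfo(truth.driving_signal, bold.fs,
                                        sm.FilterBand()))
        r_gm = np.nanmax(lagged_pearson(target, gm.samples, -15, 15))
        r_ref = np.nanmax(lagged_pearson(target, refined.samples, -15, 15))
        assert r_ref > r_gm

    def test_zero_lags_give_filtered_weighted_mean(self, snr1_radial):
        _, bold, truth = snr1_radial
        maps = perfect_maps(bold, truth)
        maps.lag = np.zeros_like(maps.lag)
        refined = sm.refine_regressor(bold, maps, min_voxels=50)
        w = np.clip(maps.maxcorr[bold.mask], 0, None) ** 2
        Y = bold.voxel_matrix()
        Y = Y - Y.mean(axis=1, keepdims=True)
        avg = (w[:, None] * Y).sum(axis=0) / w.sum()
        expected = zscore(sm.bandpass_lfo(avg, bold.fs, sm.FilterBand()))
        assert np.allclose(refined.samples, expected, atol=1e-9)

    def test_scale_invariance(self, snr1_radial):
        _, bold, truth = snr1_radial
        maps = perfect_maps(bold, truth)
        r1 = sm.refine_regressor(bold, maps, min_voxels=50)
        r2 = sm.refine_regressor(bold.with_data(bold.data * 37.0), maps,
                                 min_voxels=50)
        assert np.allclose(r1.samples, r2.samples, atol=1e-9)

    def test_too_few_significant_voxels_raises(self, snr1_radial):
        _, bold, truth = snr1_radial
        maps = perfect_maps(bold, truth)
        maps.sigmask[:] = False
        maps.sigmask[0, 0, 0] = True
        with pytest.raises(EmptyMaskError, match="seed"):
            sm.refine_regressor(bold, maps)


class TestRunPasses:
    def test_convergence_improves_across_passes(self, snr1_radial):
        _, bold, _ = snr1_radial
        init = sm.extract_global_mean(bold)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            state, trace = sm.run_passes(bold, init, n_passes=3, n_null=500,
                                         min_sig_voxels=50, seed=1,
                                         conv_tol=0.9999)
        convs = [t["convergence_r"] for t in trace]
        assert np.all(np.diff(convs) >= -1e-6) or convs[-1] > 0.999

    def test_truth_init_converges_first_pass(self, noiseless_radial,
                                             truth_probe):
        _, bold, _ = noiseless_radial
        filt = zscore(sm.bandpass_lfo(truth_probe.samples, bold.fs,
                                      sm.FilterBand()))
        init = sm.ProbeRegressor(filt, fs=bold.fs, provenance="external")
        state, trace = sm.run_passes(bold, init, n_passes=3, n_null=500,
                                     min_sig_voxels=50, seed=2)
        assert len(trace) == 1
        assert state.convergence_r >= 0.999

    def test_bimodal_delay_phantom_warns_of_echo(self):
        field = np.zeros((8, 8, 4))
        field[4:] = 12.0
        spec = sm.PhantomSpec(grid_shape=(8, 8, 4), tr=1.0, n_timepoints=600,
                              delay_kind="custom", custom_delay_field=field,
                              delay_span=12.0, noise_sd=0.2, seed=33)
        bold, _ = sm.make_phantom(spec)
        init = sm.extract_global_mean(bold)
        lobes = sm.autocorr_sidelobes(init, sm.SearchWindow(-15, 15),
                                      warn=False)
        assert any(abs(p - 12.0) <= 1.5 for p, _ in lobes)
        with pytest.warns(SidelobeWarning):
            sm.run_passes(bold, init, n_passes=1, n_null=300,
                          min_sig_voxels=20, seed=3)


@pytest.fixture(scope="module")
def speckled():
    """Pseudoperiodic phantom with 5% of lags displaced by +10 s."""
    spec = sm.PhantomSpec(grid_shape=(10, 10, 6), tr=1.0,
                          n_timepoints=800, delay_span=3.0,
                          slfo_kind="pseudoperiodic", peak_freq=0.1,
                          peak_fraction=0.85, noise_sd=0.3, seed=44)
    bold, truth = sm.make_phantom(spec)
    probe = sm.ProbeRegressor(zscore(truth.driving_signal), fs=bold.fs)
    maps = sm.map_delays(bold, probe, sm.SearchWindow(-15, 15))
    maps.sigmask[:] = bold.mask
    rng = np.random.default_rng(7)
    n_mask = int(bold.mask.sum())
    bad_rows = rng.choice(n_mask, size=max(1, n_mask // 20), replace=False)
    bad3d = np.zeros_like(bold.mask)
    bad3d[tuple(np.argwhere(bold.mask)[bad_rows].T)] = True
    spk = maps.copy()
    spk.lag[bad3d] += 10.0
    lobes = sm.autocorr_sidelobes(probe, sm.SearchWindow(-15, 15), warn=False)
    return bold, truth, maps, spk, bad3d, lobes


class TestDespeckle:
    def test_sidelobe_identified(self, speckled):
        *_, lobes = speckled
        assert any(abs(p - 10.0) <= 1.0 for p, _ in lobes)

    def test_empty_sidelobe_list_is_identity(self, speckled):
        _, _, _, spk, _, _ = speckled
        out = sm.despeckle(spk, [])
        assert np.array_equal(out.lag, spk.lag, equal_nan=True)

    def test_restores_speckled_voxels_and_leaves_clean_alone(self, speckled):
        bold, truth, clean, spk, bad3d, lobes = speckled
        out = sm.despeckle(spk, lobes)
        tr = bold.tr
        fixed = np.abs(out.lag[bad3d] - truth.true_delay[bad3d]) <= tr
        assert fixed.mean() >= 0.90
        untouched = ~bad3d & bold.mask
        assert np.allclose(out.lag[untouched], spk.lag[untouched],
                           equal_nan=True)

    def test_idempotent(self, speckled):
        _, _, _, spk, _, lobes = speckled
        once = sm.despeckle(spk, lobes)
        twice = sm.despeckle(once, lobes)
        assert np.allclose(once.lag, twice.lag, equal_nan=True)

    def test_isolated_voxel_flagged_and_unchanged(self, speckled):
        bold, _, _, spk, _, lobes = speckled
        lonely = spk.copy()
        m = np.zeros_like(lonely.mask)
        m[0, 0, 0] = True
        m[5:9, 5:9, 2:5] = True
        lonely.mask = m
        lonely.lag[0, 0, 0] = 10.0  # looks speckled but has no neighbors
        out = sm.despeckle(lonely, lobes)
        assert out.lag[0, 0, 0] == lonely.lag[0, 0, 0]
        assert out.despeckle_isolated[0, 0, 0]
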
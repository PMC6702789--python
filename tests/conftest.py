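"""Shared fixtures: small seeded phantoms reused across the suite."""

import numpy as np
import pytest

import slfomap as sm


@pytest.fixture(scope="session")
def noiseless_radial():
    """Small noiseless radial phantom: exact ground truth, no confounds."""
    spec = sm.PhantomSpec(grid_shape=(8, 8, 6), tr=1.0, n_timepoints=600,
                          delay_span=5.0, noise_sd=0.0, seed=101)
    bold, truth = sm.make_phantom(spec)
    return spec, bold, truth


@pytest.fixture(scope="session")
def snr1_radial():
    """Small radial phantom at SNR 1 (amp 1, noise sd 1)."""
    spec = sm.PhantomSpec(grid_shape=(10, 10, 8), tr=1.0, n_timepoints=800,
                          delay_span=5.0, noise_sd=1.0, seed=202)
    bold, truth = sm.make_phantom(spec)
    return spec, bold, truth


@pytest.fixture(scope="session")
def truth_probe(noiseless_radial):
    """The true driving signal as a probe (delay-0 reference)."""
    _, bold, truth = noiseless_radial
    x = truth.driving_signal
    return sm.ProbeRegressor((x - x.mean()) / x.std(), fs=bold.fs,
                             band=sm.FilterBand(0.01, 0.15))


def naive_lagged_pearson(x, y, kmin, kmax):
    """Independent oracle: shift-and-Pearson loop over the overlap."""
    out = []
    n = len(x)
    for k in range(kmin, kmax + 1):
        if k >= 0:
            a, b = x[: n - k], y[k:]
        else:
            a, b = x[-k:], y[: n + k]
        out.append(np.corrcoef(a, b)[0, 1])
    return np.array(out)


@pytest.fixture
def naive_corr():
    return naive_lagged_pearson
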
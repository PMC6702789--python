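"""Low-level numerics shared by the lag-mapping modules.

Everything here operates on plain arrays: fractional (sub-sample) delays of
band-limited signals, and the batched lagged cross-correlation engine used
for voxelwise delay mapping and for the permutation nulls.

Conventions
-----------
* ``fracshift(x, s)`` returns ``x(t - s)`` — a *positive* shift delays the
  signal (moves features later in time).
* ``lagged_pearson(x, Y, kmin, kmax)[v, j]`` is the Pearson correlation of
  ``x[t]`` with ``Y[v, t + k_j]`` over the overlapping samples, so a signal
  that is a delayed copy of ``x`` peaks at a positive lag.
"""

from __future__ import annotations

import numpy as np
from scipy.fft import irfft, next_fast_len, rfft, rfftfreq

from .errors import WindowError

__all__ = ["fracshift", "fracshift_reflect", "lagged_pearson", "lagged_gcc",
           "zscore"]


def zscore(x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Remove the mean and scale to unit variance (population ddof=0)."""
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - mu) / sd


def fracshift(x: np.ndarray, shift_samples, axis: int = -1) -> np.ndarray:
    """Delay ``x`` by a (possibly fractional) number of samples.

    Implemented as a linear phase ramp in the frequency domain, which is
    exact for band-limited, circularly extended records.  ``shift_samples``
    may be a scalar, or an array broadcastable against ``x`` with the time
    axis removed (one shift per row), in which case a batch of shifted
    copies is produced.

    Returns ``y`` with ``y(t) = x(t - shift)`` under circular extension.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[axis]
    shift = np.asarray(shift_samples, dtype=float)
    if x.ndim == 1 and shift.ndim > 0:
        # broadcast one input signal against many shifts
        X = rfft(x)
        f = rfftfreq(n)
        phase = np.exp(-2j * np.pi * f[None, :] * shift.reshape(-1, 1))
        return irfft(X[None, :] * phase, n=n, axis=-1)
    X = rfft(x, axis=axis)
    f = rfftfreq(n)
    fshape = [1] * x.ndim
    fshape[axis] = f.size
    sshape = list(np.shape(shift)) or [1]
    if np.ndim(shift) == x.ndim - 1:
        sshape = list(np.shape(shift)) + [1]
        shift = shift.reshape(sshape)
    phase = np.exp(-2j * np.pi * f.reshape(fshape) * shift)
    return irfft(X * phase, n=n, axis=axis)


def fracshift_reflect(x: np.ndarray, shift_samples) -> np.ndarray:
    """Delay a *finite* record by a fractional number of samples.

    Like :func:`fracshift`, but the record is mirror-extended before the
    frequency-domain shift and trimmed afterwards.  The even extension
    removes the wrap-around discontinuity that makes the plain circular
    shift ring on non-periodic records; samples shifted in from beyond the
    record edge are filled with the reflected signal (the least-wrong
    guess — those samples are genuinely unobserved).

    ``x`` may be 1D with an array of shifts (batch of shifted copies) or
    2D with one shift per row.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if x.ndim == 1:
        xe = np.concatenate([x, x[::-1]])
    else:
        xe = np.concatenate([x, x[..., ::-1]], axis=-1)
    return fracshift(xe, shift_samples)[..., :n]


def _check_lag_range(n: int, kmin: int, kmax: int) -> None:
    if kmin > kmax:
        raise WindowError(f"empty lag range [{kmin}, {kmax}]")
    if max(abs(kmin), abs(kmax)) > n // 2:
        raise WindowError(
            f"search window of {max(abs(kmin), abs(kmax))} samples exceeds "
            f"half the record length ({n} samples)"
        )


def lagged_pearson(
    x: np.ndarray,
    Y: np.ndarray,
    kmin: int,
    kmax: int,
    min_overlap: float = 0.8,
) -> np.ndarray:
    """Pearson correlation of ``x`` against rows of ``Y`` at integer lags.

    At lag ``k`` the correlation is computed over the overlapping samples
    only (no zero padding, no circular wraparound): for ``k >= 0`` it is
    ``pearson(x[:n-k], Y[:, k:])``.  Lags whose overlap falls below
    ``min_overlap * n`` are returned as NaN.  Rows with zero variance in
    the overlap give NaN at that lag.

    Parameters
    ----------
    x : (n,) array — the probe.
    Y : (v, n) or (n,) array — voxel timecourses, one per row.
    kmin, kmax : inclusive integer lag range, in samples.

    Returns
    -------
    R : (v, kmax - kmin + 1) array of correlations (squeezed to 1D if ``Y``
        was 1D).
    """
    x = np.asarray(x, dtype=float)
    Y2 = np.atleast_2d(np.asarray(Y, dtype=float))
    n = x.size
    if Y2.shape[1] != n:
        raise ValueError("probe and voxel records differ in length")
    _check_lag_range(n, kmin, kmax)

    m = next_fast_len(2 * n)
    Fx = rfft(x, m)
    FY = rfft(Y2, m, axis=1)
    # C[:, k % m] = sum_t x[t] * Y[:, t + k]
    C = irfft(np.conj(Fx)[None, :] * FY, n=m, axis=1)

    cx = np.concatenate([[0.0], np.cumsum(x)])
    cx2 = np.concatenate([[0.0], np.cumsum(x * x)])
    cY = np.concatenate([np.zeros((Y2.shape[0], 1)), np.cumsum(Y2, axis=1)], axis=1)
    cY2 = np.concatenate(
        [np.zeros((Y2.shape[0], 1)), np.cumsum(Y2 * Y2, axis=1)], axis=1
    )

    ks = np.arange(kmin, kmax + 1)
    R = np.full((Y2.shape[0], ks.size), np.nan)
    for j, k in enumerate(ks):
        L = n - abs(k)
        if L < min_overlap * n or L < 3:
            continue
        if k >= 0:
            sx, sx2 = cx[n - k], cx2[n - k]
            sy = cY[:, n] - cY[:, k]
            sy2 = cY2[:, n] - cY2[:, k]
        else:
            sx = cx[n] - cx[-k]
            sx2 = cx2[n] - cx2[-k]
            sy = cY[:, n + k]
            sy2 = cY2[:, n + k]
        sxy = C[:, k % m]
        num = sxy - sx * sy / L
        vx = sx2 - sx * sx / L
        vy = sy2 - sy * sy / L
        denom = vx * vy
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, num / np.sqrt(np.maximum(denom, 0)), np.nan)
        R[:, j] = np.clip(r, -1.0, 1.0)
    return R if np.ndim(Y) > 1 else R[0]


def lagged_gcc(
    x: np.ndarray,
    Y: np.ndarray,
    kmin: int,
    kmax: int,
    eps: float = 1e-3,
) -> np.ndarray:
    """Generalized (prewhitened) cross-correlation at integer lags.

    The cross-spectrum is magnitude-flattened (PHAT-style) with the spectral
    magnitudes floored at ``eps`` times their maximum to avoid inflating
    bins that carry no signal.  The output is scaled so that a pure delay of
    a signal by itself gives a peak of 1, but the values are *not* Pearson
    correlations and do not represent variance explained.
    """
    x = np.asarray(x, dtype=float)
    Y2 = np.atleast_2d(np.asarray(Y, dtype=float))
    n = x.size
    _check_lag_range(n, kmin, kmax)
    m = next_fast_len(2 * n)
    Fx = rfft(x - x.mean(), m)
    FY = rfft(Y2 - Y2.mean(axis=1, keepdims=True), m, axis=1)
    G = np.conj(Fx)[None, :] * FY
    mag = np.abs(G)
    floor = eps * mag.max(axis=1, keepdims=True)
    Gw = G / np.maximum(mag, floor)
    # only bins that genuinely carry cross-power contribute to the peak
    weight = (mag > floor).astype(float)
    Gw = Gw * weight
    c = irfft(Gw, n=m, axis=1)
    # peak height for a pure delay: all retained bins phase-aligned
    nb = weight.shape[1]
    scale = (2.0 * weight[:, 1 : nb - 1].sum(axis=1) + weight[:, 0] + weight[:, -1]) / m
    scale = np.where(scale > 0, scale, 1.0)
    ks = np.arange(kmin, kmax + 1)
    R = c[:, ks % m] / scale[:, None]
    return R if np.ndim(Y) > 1 else R[0]
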
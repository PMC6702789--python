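"""Voxelwise lagged cross-correlation against the sLFO probe.

For every voxel the probe is compared with the voxel timecourse at a grid
of integer-sample lags inside a search window; the correlation peak gives
the blood-arrival delay (positive lag = signal arrives *later* than in the
probe) and the peak height the coupling strength.  The peak location is
refined below the sample interval by a 3-point parabolic fit.  For probes
with very non-uniform spectra a generalized (prewhitened) cross-correlation
mode is available; its peak magnitudes no longer represent variance
explained and are flagged accordingly.

Correlations use Pearson normalization over the *overlapping* samples at
each shift — no zero-padding and no circular wraparound, which would
fabricate correlation for travelling signals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from ._corr import fracshift_reflect, lagged_gcc, lagged_pearson
from .errors import SidelobeWarning
from .prep import BoldImage, ProbeRegressor, SearchWindow, bandpass_lfo
from .significance import NullDistribution, threshold

__all__ = [
    "SearchWindow",
    "CorrFunction",
    "LagMaps",
    "lagged_crosscorr",
    "find_peak",
    "map_delays",
    "recenter_zero_time",
    "autocorr_sidelobes",
]


@dataclass
class CorrFunction:
    """A sampled cross-correlation function r(lag)."""

    lags: np.ndarray  # seconds, uniform at the probe sampling interval
    r: np.ndarray
    normalization: str = "pearson-overlap"  # or "gcc"

    @property
    def dt(self) -> float:
        return float(self.lags[1] - self.lags[0])


@dataclass
class LagMaps:
    """Voxelwise lag-mapping results.

    ``lag`` (s), ``maxcorr`` (r), ``amplitude`` (signal units per unit
    probe), ``r2`` (fraction of voxel variance explained), ``sigmask``
    (passes the null threshold), and ``failed`` (no acceptable peak) are 3D
    fields; values are NaN (False for the boolean maps) outside the mask.

    The per-voxel correlation functions (``corr_values`` over ``corr_lags``,
    one row per in-mask voxel in C order of ``mask``) are retained so that
    despeckling can re-fit peaks under a constrained window without
    re-reading the data.  ``lag_offset`` records any zero-time recentering
    already applied to ``lag`` (the stored correlation lags stay in the
    original probe-relative convention).
    """

    lag: np.ndarray
    maxcorr: np.ndarray
    amplitude: np.ndarray
    r2: np.ndarray
    sigmask: np.ndarray
    failed: np.ndarray
    mask: np.ndarray
    window: SearchWindow
    mode: str = "direct"
    tr: float = 1.0
    threshold_r: Optional[float] = None
    corr_lags: Optional[np.ndarray] = None
    corr_values: Optional[np.ndarray] = None
    lag_offset: float = 0.0
    despeckle_isolated: Optional[np.ndarray] = None

    def copy(self) -> "LagMaps":
        return LagMaps(
            lag=self.lag.copy(), maxcorr=self.maxcorr.copy(),
            amplitude=self.amplitude.copy(), r2=self.r2.copy(),
            sigmask=self.sigmask.copy(), failed=self.failed.copy(),
            mask=self.mask.copy(), window=self.window, mode=self.mode,
            tr=self.tr, threshold_r=self.threshold_r,
            corr_lags=None if self.corr_lags is None else self.corr_lags.copy(),
            corr_values=None if self.corr_values is None else self.corr_values.copy(),
            lag_offset=self.lag_offset,
            despeckle_isolated=(None if self.despeckle_isolated is None
                                else self.despeckle_isolated.copy()),
        )


def lagged_crosscorr(
    probe: ProbeRegressor,
    voxel: np.ndarray,
    window: SearchWindow = SearchWindow(),
    mode: str = "direct",
) -> CorrFunction:
    """Cross-correlation of one voxel timecourse against the probe.

    Positive lags mean the voxel's signal occurs later than the probe's
    (blood arrives later).  Both inputs are assumed band-limited already.
    A zero-variance voxel yields all-NaN r rather than raising.
    """
    voxel = np.asarray(voxel, dtype=float).ravel()
    if voxel.size != probe.n:
        raise ValueError("probe and voxel records differ in length")
    dt = probe.dt
    kmin, kmax = window.sample_range(dt)
    if mode == "direct":
        r = lagged_pearson(probe.samples, voxel, kmin, kmax)
        norm = "pearson-overlap"
    elif mode == "gcc":
        r = lagged_gcc(probe.samples, voxel, kmin, kmax)
        norm = "gcc"
    else:
        raise ValueError(f"unknown mode {mode!r}")
    lags = np.arange(kmin, kmax + 1) * dt
    return CorrFunction(lags=lags, r=r, normalization=norm)


def find_peak(
    corr: CorrFunction,
    window: Optional[SearchWindow] = None,
    r_floor: Optional[float] = None,
) -> Tuple[float, float, bool]:
    """Locate the correlation maximum, refined by parabolic interpolation.

    Returns ``(lag, r, ok)``.  ``ok`` is False when the discrete argmax
    sits on the window boundary (the true peak may lie outside), when the
    peak value falls below ``r_floor``, or when the function is all-NaN
    (lag is then NaN).  Ties between equal maxima break toward the smallest
    absolute lag, for deterministic, physiologically central output.
    """
    lags, r = corr.lags, corr.r
    if window is not None:
        sel = (lags >= window.min_lag) & (lags <= window.max_lag)
        lags, r = lags[sel], r[sel]
    valid = np.isfinite(r)
    if not valid.any():
        return float("nan"), float("nan"), False
    rmax = np.nanmax(r)
    cand = np.flatnonzero(valid & (r >= rmax - 1e-12))
    i = cand[np.argmin(np.abs(lags[cand]))]
    lag, rpk = float(lags[i]), float(r[i])
    ok = True
    if i == 0 or i == r.size - 1:
        ok = False
    elif np.isfinite(r[i - 1]) and np.isfinite(r[i + 1]):
        denom = r[i - 1] - 2.0 * r[i] + r[i + 1]
        if denom < 0:
            delta = 0.5 * (r[i - 1] - r[i + 1]) / denom
            delta = float(np.clip(delta, -0.5, 0.5))
            lag = float(lags[i] + delta * corr.dt)
            rpk = float(min(1.0, r[i] - 0.25 * (r[i - 1] - r[i + 1]) * delta))
    if r_floor is not None and rpk < r_floor:
        ok = False
    return lag, rpk, ok


def _peaks_batch(R: np.ndarray, lags: np.ndarray, dt: float,
                 r_floor: Optional[float]) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized find_peak over rows of R (same rules as find_peak)."""
    v, L = R.shape
    lag_out = np.full(v, np.nan)
    r_out = np.full(v, np.nan)
    ok = np.zeros(v, dtype=bool)
    finite = np.isfinite(R)
    any_finite = finite.any(axis=1)
    Rm = np.where(finite, R, -np.inf)
    rmax = Rm.max(axis=1)
    # tie-break toward the smallest |lag|: scan columns in |lag| order
    order = np.argsort(np.abs(lags), kind="stable")
    idx = np.full(v, -1)
    for j in order:
        hit = (idx < 0) & any_finite & (Rm[:, j] >= rmax - 1e-12)
        idx[hit] = j
    rows = np.flatnonzero(idx >= 0)
    i = idx[rows]
    lag_out[rows] = lags[i]
    r_out[rows] = R[rows, i]
    interior = (i > 0) & (i < L - 1)
    ok[rows] = interior
    ri = rows[interior]
    ii = i[interior]
    rm1, r0, rp1 = R[ri, ii - 1], R[ri, ii], R[ri, ii + 1]
    good = np.isfinite(rm1) & np.isfinite(rp1)
    denom = rm1 - 2 * r0 + rp1
    refit = good & (denom < 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        delta = np.where(refit, 0.5 * (rm1 - rp1) / np.where(denom, denom, 1), 0.0)
    delta = np.clip(delta, -0.5, 0.5)
    lag_out[ri] = np.where(refit, lags[ii] + delta * dt, lag_out[ri])
    r_out[ri] = np.where(refit, np.minimum(1.0, r0 - 0.25 * (rm1 - rp1) * delta),
                         r_out[ri])
    if r_floor is not None:
        ok &= ~(r_out < r_floor)
    return lag_out, r_out, ok


def map_delays(
    bold: BoldImage,
    probe: ProbeRegressor,
    window: SearchWindow = SearchWindow(),
    null: Optional[NullDistribution] = None,
    mode: str = "direct",
    p: float = 0.05,
    prefilter: bool = True,
    r_floor: Optional[float] = None,
    filter_type: str = "butter",
) -> LagMaps:
    """Lag-map every in-mask voxel against the probe.

    Voxel timecourses are detrended and band-limited to the probe's band
    first (``prefilter=False`` if the data are already filtered).  The
    amplitude and r2 maps come from a least-squares fit of the lag-shifted
    probe (plus intercept) to each voxel's filtered timecourse.  Voxels with
    no acceptable peak (zero variance, boundary argmax, all-NaN) are marked
    in ``failed``; per-voxel trouble never aborts the volume.  The
    significance mask applies the empirical null threshold at level ``p``
    when a null distribution is supplied.
    """
    if abs(probe.fs - bold.fs) > 1e-9 * bold.fs:
        raise ValueError("probe is not sampled on the BOLD time grid")
    if probe.n != bold.n_timepoints:
        raise ValueError("probe length does not match the BOLD record")
    dt = bold.tr
    kmin, kmax = window.sample_range(dt)
    lags = np.arange(kmin, kmax + 1) * dt

    Y = bold.voxel_matrix()
    ref = probe.samples
    if prefilter:
        # filter voxels AND probe identically — the permutation null filters
        # both of its inputs, so the map statistic must too, or sigmask
        # calibration drifts
        Y = bandpass_lfo(Y, bold.fs, probe.band, filter_type=filter_type, axis=-1)
        ref = bandpass_lfo(ref, bold.fs, probe.band, filter_type=filter_type)
    if mode == "direct":
        R = lagged_pearson(ref, Y, kmin, kmax)
    elif mode == "gcc":
        R = lagged_gcc(ref, Y, kmin, kmax)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    lag_v, r_v, ok_v = _peaks_batch(R, lags, dt, r_floor)
    failed_v = ~ok_v

    # amplitude / variance explained from the lag-shifted probe fit
    amp_v = np.full(lag_v.shape, np.nan)
    r2_v = np.full(lag_v.shape, np.nan)
    fit_rows = np.flatnonzero(np.isfinite(lag_v))
    if fit_rows.size:
        shifts = lag_v[fit_rows] / dt
        reg = fracshift_reflect(probe.samples, shifts)  # probe delayed by lag
        reg -= reg.mean(axis=1, keepdims=True)
        Yf = Y[fit_rows] - Y[fit_rows].mean(axis=1, keepdims=True)
        rr = np.einsum("ij,ij->i", reg, reg)
        ry = np.einsum("ij,ij->i", reg, Yf)
        yy = np.einsum("ij,ij->i", Yf, Yf)
        with np.errstate(invalid="ignore", divide="ignore"):
            amp = np.where(rr > 0, ry / rr, np.nan)
            r2 = np.where((rr > 0) & (yy > 0), ry**2 / (rr * yy), np.nan)
        amp_v[fit_rows] = amp
        r2_v[fit_rows] = np.clip(r2, 0.0, 1.0)

    thr = None
    sig_v = np.zeros(lag_v.shape, dtype=bool)
    if null is not None:
        thr = float(threshold(null, p))
        sig_v = np.isfinite(r_v) & (r_v >= thr) & ~failed_v

    shape = bold.mask.shape

    def _field(values, fill=np.nan, dtype=float):
        out = np.full(shape, fill, dtype=dtype)
        out[bold.mask] = values
        return out

    return LagMaps(
        lag=_field(lag_v),
        maxcorr=_field(r_v),
        amplitude=_field(amp_v),
        r2=_field(r2_v),
        sigmask=_field(sig_v, fill=False, dtype=bool),
        failed=_field(failed_v, fill=False, dtype=bool),
        mask=bold.mask.copy(),
        window=window,
        mode=mode,
        tr=dt,
        threshold_r=thr,
        corr_lags=lags,
        corr_values=R,
    )


def recenter_zero_time(maps: LagMaps, binwidth: float = 0.25) -> LagMaps:
    """Shift the lag map so the mode of the delay histogram sits at zero.

    Delay is intrinsically relative; the convention is to call the most
    common arrival time "zero", after which non-constant maps necessarily
    contain both negative (early, arterial-side) and positive (late,
    venous-side) delays.  Bins are anchored at multiples of ``binwidth`` so
    the operation is exactly idempotent.
    """
    out = maps.copy()
    vals = out.lag[out.mask & ~out.failed]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return out
    bins = np.round(vals / binwidth).astype(int)
    uniq, counts = np.unique(bins, return_counts=True)
    # deterministic tie-break: the mode bin closest to zero
    top_bins = uniq[counts == counts.max()]
    mode_bin = top_bins[np.argmin(np.abs(top_bins))]
    shift = float(mode_bin) * binwidth
    out.lag = out.lag - shift
    out.lag_offset = maps.lag_offset + shift
    return out


def autocorr_sidelobes(
    probe: ProbeRegressor,
    window: SearchWindow = SearchWindow(),
    r_thresh: float = 0.3,
    warn: bool = True,
) -> List[Tuple[float, float]]:
    """Large autocorrelation sidelobes of the probe inside the search window.

    A pseudoperiodic sLFO (power concentrated in a narrow spectral peak)
    correlates strongly with copies of itself one period away, so the
    voxelwise cross-correlation develops multiple peaks and lags can be
    mis-assigned by a whole period.  This check finds local maxima of the
    probe autocorrelation at nonzero lag with \\|r\\| >= ``r_thresh``, sorted
    by magnitude, and emits a :class:`SidelobeWarning` when any are found.

    Returns a list of ``(period_seconds, magnitude)`` pairs (positive lags
    only; the autocorrelation is symmetric).
    """
    dt = probe.dt
    kmax = int(math.floor(max(abs(window.min_lag), abs(window.max_lag)) / dt))
    kmax = min(kmax, probe.n // 2)
    r = lagged_pearson(probe.samples, probe.samples, 0, kmax)
    lobes = []
    # positive local maxima only: these are the peaks that can capture the
    # voxelwise argmax one period away (negative lobes cannot)
    for i in range(1, r.size - 1):
        if not (np.isfinite(r[i - 1]) and np.isfinite(r[i]) and np.isfinite(r[i + 1])):
            continue
        if r[i] >= r_thresh and r[i] >= r[i - 1] and r[i] > r[i + 1]:
            lobes.append((i * dt, float(r[i])))
    lobes.sort(key=lambda pm: -abs(pm[1]))
    if lobes and warn:
        warnings.warn(
            f"probe autocorrelation has {len(lobes)} sidelobe(s) inside the "
            f"search window (largest |r|={abs(lobes[0][1]):.2f} at "
            f"{lobes[0][0]:.1f} s); lag maps may need despeckling",
            SidelobeWarning,
            stacklevel=2,
        )
    return lobes
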
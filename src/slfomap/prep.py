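"""Data containers, LFO-band filtering, and probe-regressor extraction.

The systemic low-frequency oscillation (sLFO) occupies roughly 0.01–0.15 Hz,
the same band as neuronally driven BOLD fluctuations, so it cannot be
removed by spectral filtering alone — but all of the lag-mapping machinery
operates on signals restricted to that band.  This module holds the two
central containers (:class:`BoldImage` for 4D data, :class:`ProbeRegressor`
for the 1D sLFO estimate) and the operations that produce starting probes:
the global mean of the data, or the mean over a venous/cerebellar seed ROI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
from scipy import signal as sps
from scipy.fft import irfft, rfft, rfftfreq

from ._corr import zscore
from .errors import (EmptyMaskError, InvalidBandError, RecordTooShortError,
                     WindowError)

__all__ = [
    "FilterBand",
    "SearchWindow",
    "BoldImage",
    "ProbeRegressor",
    "bandpass_lfo",
    "extract_global_mean",
    "extract_seed_regressor",
    "resample_to_grid",
    "default_mask",
]


@dataclass(frozen=True)
class FilterBand:
    """A passband in Hz.  Default is the LFO band, 0.01–0.15 Hz."""

    low: float = 0.01
    high: float = 0.15

    def __post_init__(self):
        if not (0 < self.low < self.high):
            raise InvalidBandError(f"need 0 < low < high, got ({self.low}, {self.high})")

    def validate_fs(self, fs: float) -> None:
        if self.high >= fs / 2:
            raise InvalidBandError(
                f"band high edge {self.high} Hz is at or above Nyquist ({fs / 2} Hz)"
            )


@dataclass(frozen=True)
class SearchWindow:
    """Lag search range in seconds.  Default +/-15 s covers the healthy
    in-vivo delay spread (~6.5 s) with margin."""

    min_lag: float = -15.0
    max_lag: float = 15.0

    def __post_init__(self):
        if not self.min_lag < self.max_lag:
            raise WindowError(f"need min_lag < max_lag, got {self}")

    def sample_range(self, dt: float) -> Tuple[int, int]:
        """Inclusive integer-sample lag range covered by the window."""
        return int(math.ceil(self.min_lag / dt)), int(math.floor(self.max_lag / dt))


@dataclass
class BoldImage:
    """A 4D BOLD record: voxel timecourses, repetition time, and a mask.

    ``data`` is (x, y, z, t) in arbitrary signal units; ``mask`` marks the
    voxels that participate in any statistic.  ``affine`` is carried
    opaquely for NIfTI round-trips.
    """

    data: np.ndarray
    tr: float
    mask: Optional[np.ndarray] = None
    affine: Optional[np.ndarray] = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D data, got shape {self.data.shape}")
        if self.data.shape[3] < 2:
            raise ValueError("need at least 2 timepoints")
        if not self.tr > 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if self.mask is None:
            self.mask = default_mask(self.data)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape does not match spatial shape")
        if self.affine is None:
            self.affine = np.eye(4)

    @property
    def shape(self) -> Tuple[int, int, int, int]:
        return self.data.shape

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[3]

    @property
    def fs(self) -> float:
        return 1.0 / self.tr

    def voxel_matrix(self) -> np.ndarray:
        """Masked voxel timecourses as an (n_voxels, t) matrix."""
        return self.data[self.mask]

    def with_data(self, data: np.ndarray) -> "BoldImage":
        return BoldImage(data=np.asarray(data, dtype=float), tr=self.tr,
                         mask=self.mask.copy(), affine=self.affine)


@dataclass
class ProbeRegressor:
    """A 1D estimate of the moving sLFO signal.

    After extraction the samples are band-limited, zero-mean and
    unit-variance.  ``provenance`` records how the probe was produced
    (``global-mean``, ``roi:<name>``, ``external``, ``refined:pass-k``,
    ``permuted``, ``phase-randomized``).
    """

    samples: np.ndarray
    fs: float
    band: FilterBand = field(default_factory=FilterBand)
    provenance: str = "external"

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        self.band.validate_fs(self.fs)

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def dt(self) -> float:
        return 1.0 / self.fs

    def normalized(self) -> "ProbeRegressor":
        return replace(self, samples=zscore(self.samples))


def resample_to_grid(probe: ProbeRegressor, fs: float,
                     n_timepoints: int) -> ProbeRegressor:
    """Resample an externally recorded probe onto the fMRI time grid.

    External recordings (e.g. peripheral optical timecourses) usually run
    at a much higher sampling rate than the scanner; they are brought onto
    the BOLD grid by band-limited (FFT) resampling before use.  The two
    records are assumed to start at the same instant and cover the same
    duration.
    """
    from scipy.signal import resample

    if abs(probe.fs - fs) < 1e-9 * fs and probe.n == n_timepoints:
        return probe
    if probe.n / probe.fs < (n_timepoints - 1) / fs:
        raise ValueError("external probe is shorter than the fMRI record")
    out = resample(probe.samples, int(round(probe.n * fs / probe.fs)))
    out = out[:n_timepoints]
    if out.size != n_timepoints:
        raise ValueError("resampled probe does not cover the fMRI record")
    return ProbeRegressor(zscore(out), fs=fs, band=probe.band,
                          provenance=probe.provenance)


def default_mask(data: np.ndarray) -> np.ndarray:
    """Voxels whose temporal mean exceeds 10% of the robust (98th pct) max."""
    mean = np.abs(np.asarray(data, dtype=float)).mean(axis=-1)
    robust_max = np.percentile(mean, 98)
    if robust_max <= 0:
        return np.ones(mean.shape, dtype=bool)
    return mean > 0.1 * robust_max


def bandpass_lfo(
    timecourse: np.ndarray,
    fs: float,
    band: FilterBand = FilterBand(),
    filter_type: str = "butter",
    detrend: bool = True,
    axis: int = -1,
) -> np.ndarray:
    """Band-limit a timecourse to the LFO band with zero phase distortion.

    The default filter is a 2nd-order Butterworth applied forward-backward
    (``sosfiltfilt``), which introduces no group delay; ``filter_type=
    "brickwall"`` zeroes FFT bins outside the band instead, which is exactly
    idempotent and gives perfect spectral containment.  A linear trend is
    removed first so that scanner drift does not leak through short records.
    The output is zero-mean along ``axis``.

    Raises
    ------
    InvalidBandError
        if the band reaches Nyquist.
    RecordTooShortError
        if the record is shorter than ~3 time constants of the high-pass
        edge (3 / (2*pi*low) seconds).
    """
    x = np.asarray(timecourse, dtype=float)
    band.validate_fs(fs)
    n = x.shape[axis]
    duration = n / fs
    min_duration = 3.0 / (2.0 * np.pi * band.low)
    if duration < min_duration:
        raise RecordTooShortError(
            f"record of {duration:.1f} s is shorter than {min_duration:.1f} s "
            f"(3 time constants at {band.low} Hz)"
        )
    if detrend:
        x = sps.detrend(x, axis=axis, type="linear")
    if filter_type == "butter":
        sos = sps.butter(2, [band.low, band.high], btype="bandpass", fs=fs, output="sos")
        y = sps.sosfiltfilt(sos, x, axis=axis)
    elif filter_type == "brickwall":
        X = rfft(x, axis=axis)
        f = rfftfreq(n, d=1.0 / fs)
        keep = (f >= band.low) & (f <= band.high)
        shape = [1] * x.ndim
        shape[axis] = f.size
        y = irfft(X * keep.reshape(shape), n=n, axis=axis)
    else:
        raise ValueError(f"unknown filter_type {filter_type!r}")
    return y - y.mean(axis=axis, keepdims=True)


def extract_global_mean(
    bold: BoldImage,
    band: FilterBand = FilterBand(),
    filter_type: str = "butter",
) -> ProbeRegressor:
    """Starting probe from the global mean over the mask.

    The global mean is a temporally blurred version of the true driving
    signal (it sums delayed copies over the whole brain), which is exactly
    what the refinement loop sharpens.
    """
    if not bold.mask.any():
        raise EmptyMaskError("mask selects no voxels")
    gm = bold.voxel_matrix().mean(axis=0)
    filt = bandpass_lfo(gm, bold.fs, band, filter_type=filter_type)
    return ProbeRegressor(zscore(filt), fs=bold.fs, band=band, provenance="global-mean")


def extract_seed_regressor(
    bold: BoldImage,
    roi: np.ndarray,
    band: FilterBand = FilterBand(),
    name: str = "seed",
    filter_type: str = "butter",
) -> ProbeRegressor:
    """Starting probe from the mean over a seed ROI (e.g. superior sagittal
    sinus or cerebellum — regions of homogeneous blood-arrival delay).

    The ROI must lie inside the brain mask and be nonempty.  An ROI that
    spans regions of very different delay produces a probe with "echoes"
    (delayed copies of itself), visible as autocorrelation sidelobes.
    """
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != bold.mask.shape:
        raise ValueError("ROI shape does not match spatial shape")
    if not roi.any():
        raise EmptyMaskError("ROI selects no voxels")
    if np.any(roi & ~bold.mask):
        raise ValueError("ROI extends outside the brain mask")
    tc = bold.data[roi].mean(axis=0)
    filt = bandpass_lfo(tc, bold.fs, band, filter_type=filter_type)
    return ProbeRegressor(zscore(filt), fs=bold.fs, band=band, provenance=f"roi:{name}")
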
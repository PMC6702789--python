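"""Traveling-wave phantoms with known ground truth.

A phantom is a 4D record in which a single band-limited "driving" signal
propagates through the voxel grid with a spatially smooth delay field —
the idealized form of the systemic LFO travelling with the blood — plus
optional stationary "network" signals, white (or AR(1)) noise, and a
constant offset:

    voxel(v, t) = offset + amp(v) * driving(t - delay(v))
                + sum_k net_amp_k(v) * network_k(t) + noise(v, t)

Every downstream stage (probe extraction, lag mapping, significance,
refinement, denoising) is validated against the :class:`PhantomTruth`
returned alongside the image.

Fractional-sample delays are realized exactly: the driving signal is
generated on an extended, circularly periodic record, delayed with a
frequency-domain phase ramp, and trimmed, so the shifted copies are true
band-limited interpolants of one another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.fft import irfft, rfftfreq

from ._corr import fracshift, zscore
from .errors import InvalidSpecError
from .prep import BoldImage, FilterBand

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "NetworkROI",
    "make_driving_signal",
    "make_delay_field",
    "make_phantom",
    "two_block_preset",
]


@dataclass(frozen=True)
class NetworkROI:
    """A stationary network: a voxel set sharing one timecourse."""

    voxels: np.ndarray  # 3D boolean
    amplitude: float = 1.0


@dataclass
class PhantomSpec:
    """Parameters of a traveling-sLFO phantom.

    Defaults describe the standard healthy-circulation test case: a 20^3
    grid, HCP-like sampling (TR 0.72 s, 1200 timepoints), a radial delay
    field spanning 6.5 s (the in-vivo range of blood-arrival delays), a
    band-limited 0.01–0.15 Hz driving signal of unit amplitude, and white
    noise of matching standard deviation (SNR 1).
    """

    grid_shape: Tuple[int, int, int] = (20, 20, 20)
    tr: float = 0.72
    n_timepoints: int = 1200
    delay_kind: str = "radial"  # {"radial", "linear-gradient", "custom"}
    delay_span: float = 6.5
    delay_axis: int = 0  # for linear-gradient
    custom_delay_field: Optional[np.ndarray] = None
    slfo_kind: str = "bandlimited-noise"  # {"bandlimited-noise", "sum-of-sinusoids", "pseudoperiodic"}
    slfo_band: Tuple[float, float] = (0.01, 0.15)
    sinusoid_freqs: Tuple[float, ...] = (0.02, 0.05, 0.08)
    peak_freq: float = 0.1
    peak_fraction: float = 0.8
    slfo_amplitude: float = 1.0
    slfo_amplitude_field: Optional[np.ndarray] = None
    network_rois: Sequence[NetworkROI] = field(default_factory=tuple)
    noise_sd: float = 1.0
    ar1_coef: float = 0.0
    offset: float = 100.0
    seed: int = 0
    mask: Optional[np.ndarray] = None

    def __post_init__(self):
        if len(self.grid_shape) != 3 or any(s < 1 for s in self.grid_shape):
            raise InvalidSpecError(f"bad grid_shape {self.grid_shape}")
        if not self.tr > 0:
            raise InvalidSpecError("tr must be positive")
        if self.n_timepoints < 2:
            raise InvalidSpecError("need at least 2 timepoints")
        low, high = self.slfo_band
        if not (0 < low < high):
            raise InvalidSpecError(f"bad slfo_band {self.slfo_band}")
        if high >= 0.5 / self.tr:
            raise InvalidSpecError(
                f"slfo_band high edge {high} Hz is at or above Nyquist "
                f"({0.5 / self.tr:.4g} Hz)"
            )
        if self.delay_span < 0:
            raise InvalidSpecError("delay_span must be nonnegative")
        if self.delay_span >= self.n_timepoints * self.tr:
            raise InvalidSpecError("delay_span exceeds the record duration")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be nonnegative")
        if self.slfo_amplitude < 0:
            raise InvalidSpecError("slfo_amplitude must be nonnegative")
        if self.slfo_amplitude_field is not None:
            f = np.asarray(self.slfo_amplitude_field, dtype=float)
            if f.shape != tuple(self.grid_shape):
                raise InvalidSpecError("slfo_amplitude_field shape mismatch")
            if (f < 0).any():
                raise InvalidSpecError("amplitudes must be nonnegative")
        if self.delay_kind == "custom" and self.custom_delay_field is None:
            raise InvalidSpecError("custom delay kind needs custom_delay_field")
        if self.slfo_kind == "pseudoperiodic":
            if not (0 <= self.peak_fraction <= 1):
                raise InvalidSpecError("peak_fraction must be in [0, 1]")
            if not (low <= self.peak_freq <= high):
                raise InvalidSpecError("peak_freq must lie inside slfo_band")

    @property
    def band(self) -> FilterBand:
        return FilterBand(*self.slfo_band)

    def child_rngs(self):
        """All randomness flows from the single seed via spawned children."""
        kids = np.random.SeedSequence(self.seed).spawn(3)
        return {name: np.random.default_rng(ss)
                for name, ss in zip(("driving", "network", "noise"), kids)}


@dataclass
class PhantomTruth:
    """Ground truth implied by a :class:`PhantomSpec`."""

    true_delay: np.ndarray  # 3D, seconds
    true_slfo_amplitude: np.ndarray  # 3D
    driving_signal: np.ndarray  # 1D, length n_timepoints, zero-delay reference
    network_memberships: np.ndarray  # 3D int label field (0 = none)
    network_timecourses: Tuple[np.ndarray, ...] = ()


def _bandlimited_noise(rng, n: int, dt: float, low: float, high: float) -> np.ndarray:
    """Gaussian noise restricted to [low, high] Hz by zero-phase FFT masking."""
    f = rfftfreq(n, d=dt)
    keep = (f >= low) & (f <= high)
    if not keep.any():
        raise InvalidSpecError("band contains no resolvable frequency bins")
    coef = rng.standard_normal(f.size) + 1j * rng.standard_normal(f.size)
    coef[0] = 0.0
    if n % 2 == 0:
        coef[-1] = coef[-1].real
    return irfft(coef * keep, n=n)


def _driving_raw(spec: PhantomSpec, n: int, rng) -> np.ndarray:
    dt = spec.tr
    low, high = spec.slfo_band
    if spec.slfo_kind == "bandlimited-noise":
        return _bandlimited_noise(rng, n, dt, low, high)
    if spec.slfo_kind == "sum-of-sinusoids":
        t = np.arange(n) * dt
        phases = rng.uniform(0, 2 * np.pi, size=len(spec.sinusoid_freqs))
        return sum(np.sin(2 * np.pi * f0 * t + p)
                   for f0, p in zip(spec.sinusoid_freqs, phases))
    if spec.slfo_kind == "pseudoperiodic":
        f = rfftfreq(n, d=dt)
        in_band = (f >= low) & (f <= high)
        near_peak = in_band & (np.abs(f - spec.peak_freq) <= 0.005)
        if not near_peak.any():
            near_peak = in_band & (np.abs(f - spec.peak_freq) <= np.diff(f[:2])[0])
        broad = in_band & ~near_peak
        coef = rng.standard_normal(f.size) + 1j * rng.standard_normal(f.size)
        coef[0] = 0.0
        if n % 2 == 0:
            coef[-1] = coef[-1].real
        out = np.zeros(f.size, dtype=complex)

        def _power(mask):
            return float(np.sum(np.abs(coef[mask]) ** 2))

        if broad.any() and _power(broad) > 0 and spec.peak_fraction < 1:
            out[broad] = coef[broad] * math.sqrt(
                (1 - spec.peak_fraction) / _power(broad))
        if near_peak.any() and _power(near_peak) > 0 and spec.peak_fraction > 0:
            out[near_peak] = coef[near_peak] * math.sqrt(
                spec.peak_fraction / _power(near_peak))
        return irfft(out, n=n)
    raise InvalidSpecError(f"unknown slfo_kind {spec.slfo_kind!r}")


def make_driving_signal(spec: PhantomSpec, n: Optional[int] = None,
                        rng=None) -> np.ndarray:
    """The phantom's driving sLFO timecourse, zero-mean and unit-variance.

    For the band-limited kinds at least 95% of the spectral power lies
    inside ``slfo_band`` (the construction is exact, so effectively 100%);
    for the pseudoperiodic kind at least ``peak_fraction`` of the band
    power is concentrated within +/-0.005 Hz of ``peak_freq``.
    """
    if n is None:
        n = spec.n_timepoints
    if rng is None:
        rng = spec.child_rngs()["driving"]
    return zscore(_driving_raw(spec, n, rng))


def make_delay_field(spec: PhantomSpec) -> np.ndarray:
    """The 3D blood-arrival delay field, in seconds.

    The field spans exactly ``delay_span`` (max - min), mirroring the
    in-vivo pattern in which the signal appears first centrally and
    propagates outward over ~6.5 s.  ``radial`` is monotone in distance
    from the grid center; ``linear-gradient`` ramps along ``delay_axis``;
    ``custom`` rescales a user field affinely onto [0, delay_span].
    """
    shape = tuple(spec.grid_shape)
    if spec.delay_kind == "custom":
        raw = np.asarray(spec.custom_delay_field, dtype=float)
        if raw.shape != shape:
            raise InvalidSpecError("custom delay field shape mismatch")
    elif spec.delay_kind == "radial":
        center = (np.asarray(shape, dtype=float) - 1) / 2.0
        grid = np.indices(shape, dtype=float)
        raw = np.sqrt(sum((grid[i] - center[i]) ** 2 for i in range(3)))
    elif spec.delay_kind == "linear-gradient":
        ax = spec.delay_axis
        n_ax = shape[ax]
        ramp = np.arange(n_ax, dtype=float)
        raw = np.moveaxis(
            np.broadcast_to(ramp, shape[:ax] + shape[ax + 1:] + (n_ax,)).copy(),
            -1, ax)
    else:
        raise InvalidSpecError(f"unknown delay_kind {spec.delay_kind!r}")
    lo, hi = raw.min(), raw.max()
    if hi == lo:
        return np.zeros(shape)
    return spec.delay_span * (raw - lo) / (hi - lo)


def make_phantom(spec: PhantomSpec) -> Tuple[BoldImage, PhantomTruth]:
    """Render the phantom and its ground truth.

    Identical specs (including the seed) produce bit-identical output.
    """
    rngs = spec.child_rngs()
    shape = tuple(spec.grid_shape)
    n = spec.n_timepoints
    delay = make_delay_field(spec)

    pad = int(math.ceil(delay.max() / spec.tr)) + 8
    n_ext = n + pad
    d_ext = zscore(_driving_raw(spec, n_ext, rngs["driving"]))

    if spec.slfo_amplitude_field is not None:
        amp = np.asarray(spec.slfo_amplitude_field, dtype=float)
    else:
        amp = np.full(shape, float(spec.slfo_amplitude))

    n_vox = int(np.prod(shape))
    delays_flat = delay.reshape(-1) / spec.tr  # in samples
    data = np.empty((n_vox, n))
    # delay in the frequency domain, in batches to bound memory
    batch = max(1, int(2e7 // n_ext))
    for start in range(0, n_vox, batch):
        sl = slice(start, min(start + batch, n_vox))
        shifted = fracshift(d_ext, delays_flat[sl])
        data[sl] = shifted[:, pad:pad + n]
    data *= amp.reshape(-1, 1)

    labels = np.zeros(shape, dtype=int)
    net_tcs = []
    low, high = spec.slfo_band
    for k, roi in enumerate(spec.network_rois, start=1):
        vox = np.asarray(roi.voxels, dtype=bool)
        if vox.shape != shape:
            raise InvalidSpecError("network ROI shape mismatch")
        tc = zscore(_bandlimited_noise(rngs["network"], n, spec.tr, low, high))
        net_tcs.append(tc)
        data[vox.reshape(-1)] += roi.amplitude * tc
        labels[vox] = k

    if spec.noise_sd > 0:
        noise = rngs["noise"].standard_normal((n_vox, n))
        if spec.ar1_coef:
            a = spec.ar1_coef
            for t in range(1, n):
                noise[:, t] = a * noise[:, t - 1] + math.sqrt(1 - a * a) * noise[:, t]
        data += spec.noise_sd * noise

    data += spec.offset
    mask = (np.ones(shape, dtype=bool) if spec.mask is None
            else np.asarray(spec.mask, dtype=bool))
    bold = BoldImage(data=data.reshape(shape + (n,)), tr=spec.tr, mask=mask)
    truth = PhantomTruth(
        true_delay=delay,
        true_slfo_amplitude=amp,
        driving_signal=d_ext[pad:pad + n].copy(),
        network_memberships=labels,
        network_timecourses=tuple(net_tcs),
    )
    return bold, truth


#: Explicit geometry of the two-block preset (chosen, not printed anywhere):
#: two 8x8x4 blocks in a 32x16x4 grid, delay ramping 0 -> 6 s along axis 0
#: within each block, identical between blocks.
TWO_BLOCK_PRESET = {
    "grid_shape": (32, 16, 4),
    "block_shape": (8, 8, 4),
    "block_origins": ((4, 4, 0), (20, 4, 0)),
    "delay_span": 6.0,
    "delay_axis": 0,
}


def two_block_preset(noise_sd: float = 0.5, offset: float = 100.0,
                seed: int = 0) -> PhantomSpec:
    """Two identical blocks carrying a progressively delayed sum of
    sinusoids, with additive noise and a constant offset.

    The signal in each block ramps from 0 to 6 s of delay along the first
    axis; corresponding voxels in the two blocks carry identical delays (and,
    at ``noise_sd=0``, identical timecourses).  Outside the blocks there is
    only offset + noise; the mask covers the blocks.
    """
    g = TWO_BLOCK_PRESET
    shape = g["grid_shape"]
    bx, by, bz = g["block_shape"]
    delay = np.zeros(shape)
    amp = np.zeros(shape)
    mask = np.zeros(shape, dtype=bool)
    ramp = np.linspace(0.0, g["delay_span"], bx)
    for ox, oy, oz in g["block_origins"]:
        delay[ox:ox + bx, oy:oy + by, oz:oz + bz] = ramp[:, None, None]
        amp[ox:ox + bx, oy:oy + by, oz:oz + bz] = 1.0
        mask[ox:ox + bx, oy:oy + by, oz:oz + bz] = True
    return PhantomSpec(
        grid_shape=shape,
        tr=0.72,
        n_timepoints=1200,
        delay_kind="custom",
        custom_delay_field=delay,
        delay_span=g["delay_span"],
        slfo_kind="sum-of-sinusoids",
        slfo_amplitude_field=amp,
        noise_sd=noise_sd,
        offset=offset,
        seed=seed,
        mask=mask,
    )
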
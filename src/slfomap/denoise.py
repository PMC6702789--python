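"""Removal of the moving sLFO signal: dynamic vs. static GSR.

Static global signal regression (sGSR) removes one unshifted global-mean
regressor from every voxel.  Because the global mean is a sum of delayed
copies of the travelling sLFO, it is misaligned with most voxels; removing
a misaligned copy necessarily *adds* an inverted, attenuated copy of the
signal at the correct delay, which manifests as spurious anticorrelations
between regions of different blood-arrival time.

Dynamic GSR (dGSR) instead removes the sLFO probe at each voxel's own
fitted lag, taking out the moving signal without the inversion artifact
while leaving stationary (neuronal) network signals intact.

``seed_connectivity`` provides the standard zero-lag seed correlation map
used to evaluate those side effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ._corr import fracshift_reflect
from .errors import EmptyMaskError
from .lagcorr import LagMaps
from .prep import BoldImage, ProbeRegressor

__all__ = ["DenoiseResult", "dgsr", "sgsr", "seed_connectivity"]


@dataclass
class DenoiseResult:
    """Residual data after sLFO removal.

    ``r2_map`` is the fraction of each voxel's (detrended) variance removed
    by the regressor.  ``flagged`` marks voxels passed through unchanged
    (failed lag fits, lags at the window edge).  The residual is exactly
    orthogonal to the regressor actually removed at each voxel.
    """

    residual: BoldImage
    r2_map: np.ndarray
    method: str  # {"dGSR", "sGSR"}
    regressor_provenance: str = ""
    flagged: Optional[np.ndarray] = None


def _regress_out(Y: np.ndarray, regs: np.ndarray) -> tuple:
    """Remove intercept + linear trend + one regressor (row-wise) from Y.

    ``regs`` is (v, n) — one regressor per voxel (rows may be identical).
    Returns (residual, r2) where r2 is the regressor-attributable variance
    fraction of the detrended signal.  The residual is orthogonal to the
    constant, the trend, and the regressor.
    """
    v, n = Y.shape
    t = np.arange(n) - (n - 1) / 2.0
    t = t / np.sqrt((t**2).sum())
    # project out intercept and trend from both sides
    Yd = Y - Y.mean(axis=1, keepdims=True)
    Yd = Yd - (Yd @ t)[:, None] * t[None, :]
    Rd = regs - regs.mean(axis=1, keepdims=True)
    Rd = Rd - np.einsum("ij,j->i", Rd, t)[:, None] * t[None, :]
    rr = np.einsum("ij,ij->i", Rd, Rd)
    ry = np.einsum("ij,ij->i", Rd, Yd)
    yy = np.einsum("ij,ij->i", Yd, Yd)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(rr > 0, ry / rr, 0.0)
        r2 = np.where((rr > 0) & (yy > 0), ry**2 / (rr * yy), 0.0)
    resid = Yd - beta[:, None] * Rd
    return resid, np.clip(r2, 0.0, 1.0)


def dgsr(
    bold: BoldImage,
    probe: ProbeRegressor,
    maps: LagMaps,
    restrict_to_sigmask: bool = False,
    edge_margin: float = 0.0,
) -> DenoiseResult:
    """Dynamic GSR: remove the probe from each voxel at that voxel's lag.

    Per voxel the probe is delayed by the fitted lag (band-limited
    interpolation), then intercept + linear trend + shifted probe are fit
    by least squares and subtracted.  Voxels whose lag fit failed or sits
    at the window edge are passed through unchanged (detrended only is NOT
    applied to them) and flagged.  By default voxels failing the
    significance threshold are still denoised — their fitted coefficient is
    simply small; ``restrict_to_sigmask=True`` limits removal to
    significant voxels.
    """
    if abs(probe.fs - bold.fs) > 1e-9 * bold.fs or probe.n != bold.n_timepoints:
        raise ValueError("probe is not on the BOLD time grid")
    shape = bold.mask.shape
    lag_rel = maps.lag + maps.lag_offset
    at_edge = (
        (lag_rel <= maps.window.min_lag + edge_margin)
        | (lag_rel >= maps.window.max_lag - edge_margin)
    )
    denoisable = bold.mask & ~maps.failed & np.isfinite(lag_rel) & ~at_edge
    if restrict_to_sigmask:
        denoisable &= maps.sigmask
    flagged = bold.mask & ~denoisable

    out = bold.data.copy()
    r2_map = np.full(shape, np.nan)
    rows3d = np.nonzero(denoisable)
    if rows3d[0].size:
        Y = bold.data[denoisable]
        shifts = lag_rel[denoisable] / maps.tr
        regs = np.empty_like(Y)
        batch = max(1, int(2e7 // probe.n))
        for s in range(0, Y.shape[0], batch):
            sl = slice(s, min(s + batch, Y.shape[0]))
            regs[sl] = fracshift_reflect(probe.samples, shifts[sl])
        resid, r2 = _regress_out(Y, regs)
        out[denoisable] = resid
        r2_map[denoisable] = r2
    residual = BoldImage(out, tr=bold.tr, mask=bold.mask.copy(),
                         affine=bold.affine)
    return DenoiseResult(residual=residual, r2_map=r2_map, method="dGSR",
                         regressor_provenance=probe.provenance, flagged=flagged)


def sgsr(bold: BoldImage, regressor: Optional[np.ndarray] = None) -> DenoiseResult:
    """Static GSR: remove one unshifted regressor from every voxel.

    The regressor defaults to the mean timecourse over the mask (classic
    global signal regression); intercept and linear trend are included in
    the fit as in :func:`dgsr`.
    """
    if not bold.mask.any():
        raise EmptyMaskError("mask selects no voxels")
    if regressor is None:
        regressor = bold.voxel_matrix().mean(axis=0)
        provenance = "global-mean"
    else:
        provenance = "external"
    regressor = np.asarray(regressor, dtype=float).ravel()
    if regressor.size != bold.n_timepoints:
        raise ValueError("regressor length does not match the record")
    Y = bold.voxel_matrix()
    regs = np.broadcast_to(regressor, Y.shape)
    resid, r2 = _regress_out(Y, regs)
    out = bold.data.copy()
    out[bold.mask] = resid
    r2_map = np.full(bold.mask.shape, np.nan)
    r2_map[bold.mask] = r2
    residual = BoldImage(out, tr=bold.tr, mask=bold.mask.copy(),
                         affine=bold.affine)
    return DenoiseResult(residual=residual, r2_map=r2_map, method="sGSR",
                         regressor_provenance=provenance,
                         flagged=np.zeros(bold.mask.shape, dtype=bool))


def seed_connectivity(bold: BoldImage, seed_roi: np.ndarray) -> np.ndarray:
    """Zero-lag Pearson correlation of every voxel with the seed mean.

    The standard evaluation map for denoising side effects: on a
    travelling-sLFO phantom the pre-denoise map shows widespread positive
    correlation tapering with delay difference; after sGSR far-delay
    regions turn spuriously negative; after dGSR they drop below the
    spurious-correlation threshold.  Returns NaN outside the mask.
    """
    seed_roi = np.asarray(seed_roi, dtype=bool)
    if seed_roi.shape != bold.mask.shape:
        raise ValueError("seed shape does not match spatial shape")
    if not seed_roi.any():
        raise EmptyMaskError("seed ROI selects no voxels")
    if np.any(seed_roi & ~bold.mask):
        raise ValueError("seed ROI extends outside the mask")
    seed_tc = bold.data[seed_roi].mean(axis=0)
    seed_tc = seed_tc - seed_tc.mean()
    ss = np.sqrt((seed_tc**2).sum())
    Y = bold.voxel_matrix()
    Yd = Y - Y.mean(axis=1, keepdims=True)
    denom = ss * np.sqrt(np.einsum("ij,ij->i", Yd, Yd))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, Yd @ seed_tc / denom, np.nan)
    out = np.full(bold.mask.shape, np.nan)
    out[bold.mask] = np.clip(r, -1.0, 1.0)
    return out
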
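"""Scikit-learn-style estimators wrapping the lag-mapping pipeline.

:class:`LagMapper` is the fit side — it learns the refined sLFO probe, the
voxelwise lag/strength maps and the significance threshold from a
:class:`~slfomap.prep.BoldImage`.  :class:`DynamicGSR` and
:class:`StaticGSR` are transformers producing denoised data.  All three
follow the usual conventions (``get_params``/``set_params``, ``fit``
returning ``self``, fitted attributes with a trailing underscore), so they
compose with :func:`sklearn.base.clone` and sklearn pipelines.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .denoise import dgsr, sgsr
from .errors import EmptyMaskError
from .lagcorr import recenter_zero_time
from .prep import (BoldImage, FilterBand, SearchWindow, extract_global_mean,
                   extract_seed_regressor)
from .refine import run_passes

__all__ = ["LagMapper", "DynamicGSR", "StaticGSR"]


def _as_bold(X, tr: Optional[float]) -> BoldImage:
    if isinstance(X, BoldImage):
        return X
    X = np.asarray(X, dtype=float)
    if X.ndim != 4:
        raise ValueError("X must be a BoldImage or a 4D (x, y, z, t) array")
    if tr is None:
        raise ValueError("pass tr= when X is a bare array")
    return BoldImage(X, tr=tr)


class LagMapper(BaseEstimator):
    """Map voxelwise blood-arrival lag and sLFO coupling strength.

    Starting from the global mean (or a seed ROI) the probe regressor is
    iteratively refined; each pass recomputes the permutation null, maps
    lags by peak-picked cross-correlation, despeckles pseudoperiodic
    sidelobe errors, and re-aggregates significant voxels into a sharper
    probe.  Lags are finally recentered so the histogram mode is zero.

    Parameters
    ----------
    band : (low, high) Hz — LFO passband (default 0.01–0.15).
    window : (min, max) s — lag search range (default +/-15).
    n_passes, n_null, p : refinement passes, null iterations, significance.
    mode : "direct" (overlap Pearson) or "gcc" (prewhitened).
    probe_source : "global-mean" or "roi" (requires ``seed_roi``).
    random_state : seed for the permutation nulls.

    Attributes (after fit)
    ----------------------
    probe_ : the refined sLFO regressor.
    maps_ : :class:`~slfomap.lagcorr.LagMaps` from the final probe.
    null_, threshold_ : final null distribution and p-threshold.
    trace_ : per-pass audit trail.
    """

    def __init__(self, band: Tuple[float, float] = (0.01, 0.15),
                 window: Tuple[float, float] = (-15.0, 15.0),
                 n_passes: int = 3, n_null: int = 10000, p: float = 0.05,
                 mode: str = "direct", despeckle: bool = True,
                 probe_source: str = "global-mean", seed_roi=None,
                 recenter: bool = True, min_sig_voxels: int = 100,
                 tr: Optional[float] = None, filter_type: str = "butter",
                 random_state: int = 0):
        self.band = band
        self.window = window
        self.n_passes = n_passes
        self.n_null = n_null
        self.p = p
        self.mode = mode
        self.despeckle = despeckle
        self.probe_source = probe_source
        self.seed_roi = seed_roi
        self.recenter = recenter
        self.min_sig_voxels = min_sig_voxels
        self.tr = tr
        self.filter_type = filter_type
        self.random_state = random_state

    def fit(self, X, y=None):
        bold = _as_bold(X, self.tr)
        band = FilterBand(*self.band)
        window = SearchWindow(*self.window)
        if not bold.mask.any():
            raise EmptyMaskError("mask selects no voxels")
        if self.probe_source == "global-mean":
            init = extract_global_mean(bold, band, filter_type=self.filter_type)
        elif self.probe_source == "roi":
            if self.seed_roi is None:
                raise ValueError("probe_source='roi' requires seed_roi")
            init = extract_seed_regressor(bold, self.seed_roi, band,
                                          filter_type=self.filter_type)
        else:
            raise ValueError(f"unknown probe_source {self.probe_source!r}")
        state, trace = run_passes(
            bold, init, window=window, band=band, n_passes=self.n_passes,
            n_null=self.n_null, p=self.p, do_despeckle=self.despeckle,
            mode=self.mode, seed=self.random_state,
            min_sig_voxels=self.min_sig_voxels, filter_type=self.filter_type)
        maps = state.maps
        if self.recenter:
            maps = recenter_zero_time(maps)
        self.init_probe_ = init
        self.probe_ = state.probe
        self.maps_ = maps
        self.null_ = state.null
        self.threshold_ = maps.threshold_r
        self.convergence_r_ = state.convergence_r
        self.trace_ = trace
        return self

    @property
    def lag_map_(self):
        return self.maps_.lag

    @property
    def maxcorr_map_(self):
        return self.maps_.maxcorr


class DynamicGSR(LagMapper, TransformerMixin):
    """Dynamic global signal regression as a transformer.

    ``fit`` runs the full :class:`LagMapper` pipeline; ``transform``
    removes the refined probe from each voxel at that voxel's own lag and
    returns the residual :class:`~slfomap.prep.BoldImage`.
    """

    def __init__(self, band=(0.01, 0.15), window=(-15.0, 15.0), n_passes=3,
                 n_null=10000, p=0.05, mode="direct", despeckle=True,
                 probe_source="global-mean", seed_roi=None, recenter=True,
                 min_sig_voxels=100, tr=None, filter_type="butter",
                 random_state=0, restrict_to_sigmask: bool = False):
        super().__init__(band=band, window=window, n_passes=n_passes,
                         n_null=n_null, p=p, mode=mode, despeckle=despeckle,
                         probe_source=probe_source, seed_roi=seed_roi,
                         recenter=recenter, min_sig_voxels=min_sig_voxels,
                         tr=tr, filter_type=filter_type,
                         random_state=random_state)
        self.restrict_to_sigmask = restrict_to_sigmask

    def transform(self, X) -> BoldImage:
        bold = _as_bold(X, self.tr)
        result = dgsr(bold, self.probe_, self.maps_,
                      restrict_to_sigmask=self.restrict_to_sigmask)
        self.denoise_result_ = result
        return result.residual


class StaticGSR(BaseEstimator, TransformerMixin):
    """Classic (static) global signal regression, for comparison.

    Stateless apart from parameter echo: the global-mean regressor is
    recomputed from the data passed to ``transform``.
    """

    def __init__(self, tr: Optional[float] = None):
        self.tr = tr

    def fit(self, X, y=None):
        self.n_features_in_ = 1  # nominal; operates on whole images
        return self

    def transform(self, X) -> BoldImage:
        bold = _as_bold(X, self.tr)
        result = sgsr(bold)
        self.denoise_result_ = result
        return result.residual
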
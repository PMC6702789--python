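"""Run configuration and end-to-end pipeline orchestration.

``run_pipeline`` binds the stages together — load, probe extraction,
refinement passes, zero-time recentering, optional dynamic GSR — and
writes every artifact (maps, probes, null, trace, residual) plus a
checksummed manifest, so that identical config + inputs give identical
outputs.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple



from . import io as sio

from .lagcorr import recenter_zero_time
from .phantom import PhantomSpec, two_block_preset, make_phantom
from .prep import (BoldImage, FilterBand, SearchWindow, extract_global_mean,
                   extract_seed_regressor)
from .denoise import dgsr, sgsr
from .refine import run_passes

__all__ = ["RunConfig", "run_pipeline", "make_phantom_files"]

log = logging.getLogger("slfomap")


@dataclass
class RunConfig:
    """Everything needed to reproduce a run; JSON-round-trippable.

    Every stochastic operation derives its seed from the single ``seed``.
    """

    input_path: str = ""
    mask_path: Optional[str] = None
    seed_roi_path: Optional[str] = None
    output_dir: str = "."
    tr: Optional[float] = None
    band: Tuple[float, float] = (0.01, 0.15)
    window: Tuple[float, float] = (-15.0, 15.0)
    n_passes: int = 3
    n_null: int = 10000
    p_threshold: float = 0.05
    mode: str = "direct"
    despeckle: bool = True
    denoise: Optional[str] = None  # None, "dGSR", "sGSR"
    seed: int = 0
    extra: Dict = field(default_factory=dict)

    def to_json(self, path) -> Path:
        return sio.write_json(asdict(self), path)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = json.load(fh)
        d["band"] = tuple(d.get("band", (0.01, 0.15)))
        d["window"] = tuple(d.get("window", (-15.0, 15.0)))
        return cls(**d)


def run_pipeline(config: RunConfig,
                 bold: Optional[BoldImage] = None) -> Dict[str, str]:
    """Execute the full pipeline and write the artifact set.

    ``bold`` may be supplied directly (phantoms, tests); otherwise it is
    loaded from ``config.input_path``.  Returns the manifest name->path
    dict.  Sidelobe and convergence warnings are captured into the run log
    and manifest.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if bold is None:
        bold = sio.load_bold(config.input_path, tr=config.tr,
                             mask_path=config.mask_path)
    band = FilterBand(*config.band)
    window = SearchWindow(*config.window)

    if config.seed_roi_path:
        roi = sio.load_mask(config.seed_roi_path)
        init = extract_seed_regressor(bold, roi, band)
    else:
        init = extract_global_mean(bold, band)

    captured = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        state, trace = run_passes(
            bold, init, window=window, band=band, n_passes=config.n_passes,
            n_null=config.n_null, p=config.p_threshold,
            do_despeckle=config.despeckle, mode=config.mode,
            seed=config.seed)
        captured = [f"{w.category.__name__}: {w.message}" for w in wlist]
    for msg in captured:
        log.warning(msg)
    maps = recenter_zero_time(state.maps)

    written: Dict[str, str] = {}
    written.update(sio.save_lagmaps(
        maps, outdir, affine=bold.affine, prefix="run",
        sidecar_extra={"p_threshold": config.p_threshold,
                       "band": list(config.band),
                       "n_null": config.n_null,
                       "software": "slfomap"}))
    written["probe"] = str(sio.write_timecourse(
        state.probe.samples, state.probe.fs, outdir / "run_probe.tsv"))
    written["init_probe"] = str(sio.write_timecourse(
        init.samples, init.fs, outdir / "run_desc-initial_probe.tsv"))
    written["null"] = str(sio.write_timecourse(
        state.null.values, 0.0, outdir / "run_null.tsv"))
    written["trace"] = str(sio.write_json(
        {"passes": trace, "convergence_r": state.convergence_r,
         "warnings": captured}, outdir / "run_trace.json"))
    written["config"] = str(config.to_json(outdir / "run_config.json"))

    if config.denoise:
        if config.denoise.lower() == "dgsr":
            res = dgsr(bold, state.probe, maps)
        elif config.denoise.lower() == "sgsr":
            res = sgsr(bold)
        else:
            raise ValueError(f"unknown denoise method {config.denoise!r}")
        written["residual"] = str(sio.save_bold(
            res.residual, outdir / "run_desc-denoised_bold.nii.gz"))
        written["denoise_r2"] = str(sio.save_map3d(
            res.r2_map, bold.affine, outdir / "run_desc-removedr2_map.nii.gz"))
        written["denoise_sidecar"] = str(sio.write_json(
            {"method": res.method, "regressor": res.regressor_provenance},
            outdir / "run_denoise.json"))

    sio.write_manifest(written, outdir / "run_manifest.json")
    written["manifest"] = str(outdir / "run_manifest.json")
    return written


def make_phantom_files(outdir, preset: str = "radial", seed: int = 0,
                       noise_sd: float = 1.0, **spec_kwargs) -> Dict[str, str]:
    """Generate a phantom and write it (thin wrapper over the generator
    with the same determinism contract)."""
    if preset == "two-block":
        spec = two_block_preset(seed=seed, noise_sd=noise_sd)
    elif preset == "radial":
        spec = PhantomSpec(seed=seed, noise_sd=noise_sd, **spec_kwargs)
    else:
        raise ValueError(f"unknown preset {preset!r}")
    bold, truth = make_phantom(spec)
    written = sio.save_phantom(spec, bold, truth, outdir)
    sio.write_manifest(written, Path(outdir) / "phantom_manifest.json")
    return written
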
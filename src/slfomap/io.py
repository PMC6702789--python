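"""File I/O: NIfTI-1 images, TSV timecourses, JSON sidecars, manifests.

Naming of map outputs follows BIDS-derivatives-flavored suffixes
(``desc-maxtime``, ``desc-maxcorr`` ...) for interoperability with other
lag-mapping tools.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Optional, Tuple

import nibabel as nib
import numpy as np

from .lagcorr import LagMaps
from .phantom import PhantomSpec, PhantomTruth
from .prep import BoldImage

__all__ = [
    "load_bold",
    "save_bold",
    "save_map3d",
    "load_mask",
    "save_lagmaps",
    "write_timecourse",
    "read_timecourse",
    "save_phantom",
    "write_json",
    "sha256_of",
    "write_manifest",
]

MAP_SUFFIXES = {
    "lag": "desc-maxtime",
    "maxcorr": "desc-maxcorr",
    "amplitude": "desc-fitamp",
    "r2": "desc-r2",
    "sigmask": "desc-sigmask",
    "failed": "desc-failed",
}


def load_bold(path, tr: Optional[float] = None, mask_path=None) -> BoldImage:
    """Read a 4D NIfTI-1 image.  TR is taken from the header (pixdim[4])
    unless overridden; an explicit ``tr`` takes precedence."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4D image, got shape {data.shape}")
    header_tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
    use_tr = tr if tr is not None else header_tr
    if not use_tr or use_tr <= 0:
        raise ValueError(f"{path}: no usable TR in header; pass tr explicitly")
    mask = load_mask(mask_path) if mask_path is not None else None
    return BoldImage(data=data, tr=use_tr, mask=mask, affine=img.affine)


def load_mask(path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.dataobj) > 0


def save_bold(bold: BoldImage, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(bold.data.astype(np.float32), bold.affine)
    img.header.set_zooms(img.header.get_zooms()[:3] + (bold.tr,))
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    return path


def save_map3d(field: np.ndarray, affine, path) -> Path:
    path = Path(path)
    nib.save(nib.Nifti1Image(np.asarray(field, dtype=np.float32), affine), str(path))
    return path


def save_lagmaps(maps: LagMaps, outdir, affine=None, prefix: str = "sub",
                 sidecar_extra: Optional[Dict] = None) -> Dict[str, str]:
    """Write the six map volumes plus a JSON sidecar; returns name->path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4) if affine is None else affine
    written = {}
    for name, suffix in MAP_SUFFIXES.items():
        field = getattr(maps, name)
        path = outdir / f"{prefix}_{suffix}_map.nii.gz"
        save_map3d(np.asarray(field, dtype=float), affine, path)
        written[name] = str(path)
    sidecar = {
        "window": [maps.window.min_lag, maps.window.max_lag],
        "mode": maps.mode,
        "tr": maps.tr,
        "threshold_r": maps.threshold_r,
        "lag_offset": maps.lag_offset,
    }
    if sidecar_extra:
        sidecar.update(sidecar_extra)
    sc = outdir / f"{prefix}_lagmaps.json"
    write_json(sidecar, sc)
    written["sidecar"] = str(sc)
    return written


def write_timecourse(samples: np.ndarray, fs: float, path) -> Path:
    """Single-column TSV with a ``# samplerate=<Hz>`` header line."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# samplerate={fs:.10g}\n")
        for v in np.asarray(samples, dtype=float).ravel():
            fh.write(f"{v:.10g}\n")
    return path


def read_timecourse(path) -> Tuple[np.ndarray, Optional[float]]:
    """Read a one-sample-per-line timecourse; returns (samples, fs or None)."""
    fs = None
    vals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "samplerate=" in line:
                    fs = float(line.split("samplerate=")[1])
                continue
            vals.append(float(line.split()[0]))
    return np.asarray(vals), fs


def save_phantom(spec: PhantomSpec, bold: BoldImage, truth: PhantomTruth,
                 outdir, prefix: str = "phantom") -> Dict[str, str]:
    """Write the phantom 4D image, truth volumes, driving signal and a
    JSON echo of the generating parameters."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {
        "bold": str(save_bold(bold, outdir / f"{prefix}_bold.nii.gz")),
        "true_delay": str(save_map3d(truth.true_delay, bold.affine,
                                     outdir / f"{prefix}_desc-truedelay_map.nii.gz")),
        "true_amplitude": str(save_map3d(truth.true_slfo_amplitude, bold.affine,
                                         outdir / f"{prefix}_desc-trueamp_map.nii.gz")),
        "networks": str(save_map3d(truth.network_memberships, bold.affine,
                                   outdir / f"{prefix}_desc-network_map.nii.gz")),
        "mask": str(save_map3d(bold.mask.astype(np.float32), bold.affine,
                               outdir / f"{prefix}_mask.nii.gz")),
        "driving": str(write_timecourse(truth.driving_signal, bold.fs,
                                        outdir / f"{prefix}_driving.tsv")),
    }
    echo = {
        k: v for k, v in vars(spec).items()
        if isinstance(v, (int, float, str, tuple, list, type(None)))
    }
    sc = outdir / f"{prefix}_spec.json"
    write_json(echo, sc)
    written["spec"] = str(sc)
    return written


def write_json(obj: Dict, path) -> Path:
    path = Path(path)

    def _default(o):
        if isinstance(o, np.generic):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
    return path


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(paths: Dict[str, str], outpath) -> Path:
    """Machine-readable manifest of written artifacts with checksums."""
    manifest = {
        name: {"path": str(p), "sha256": sha256_of(p)}
        for name, p in sorted(paths.items())
    }
    return write_json(manifest, outpath)
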
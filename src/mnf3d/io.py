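"""Reading and writing volumes, parametric maps, features and metrics.

Volumes travel as NIfTI (spacing in the header zooms) or as raw float32
with a JSON sidecar describing shape, spacing, dtype and byte order.
Feature tables are CSV; metric reports are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .types import EnvelopeVolume

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_raw",
    "load_raw",
    "load_volume",
    "save_parametric_volume",
    "write_features_csv",
    "read_features_csv",
    "write_metrics_json",
    "export_slice_pngs",
]


def save_nifti(volume, path, spacing=None):
    """Write a volume (EnvelopeVolume or ndarray) as NIfTI with spacing in the header."""
    if isinstance(volume, EnvelopeVolume):
        data, spacing = volume.data, volume.spacing
    else:
        data = np.asarray(volume)
        spacing = spacing or (1.0, 1.0, 1.0)
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(data), affine)
    img.header.set_zooms(spacing)
    nib.save(img, str(path))


def load_nifti(path) -> EnvelopeVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return EnvelopeVolume(data, spacing=spacing)


def save_raw(array, path_prefix, spacing=(1.0, 1.0, 1.0)):
    """Write raw little-endian float32 voxels plus a JSON sidecar."""
    array = np.asarray(array, dtype="<f4")
    prefix = Path(path_prefix)
    array.tofile(prefix.with_suffix(".raw"))
    sidecar = {
        "shape": list(array.shape),
        "spacing_mm": list(spacing),
        "dtype": "float32",
        "byte_order": "little",
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_raw(path_prefix) -> EnvelopeVolume:
    prefix = Path(path_prefix)
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    dtype = "<f4" if sidecar.get("byte_order", "little") == "little" else ">f4"
    data = np.fromfile(prefix.with_suffix(".raw"), dtype=dtype).reshape(sidecar["shape"])
    return EnvelopeVolume(data.astype(np.float64), spacing=tuple(sidecar["spacing_mm"]))


def load_volume(path) -> EnvelopeVolume:
    """Load a volume by extension: .nii/.nii.gz as NIfTI, otherwise raw+sidecar."""
    p = str(path)
    if p.endswith(".nii") or p.endswith(".nii.gz"):
        return load_nifti(p)
    return load_raw(Path(p).with_suffix(""))


def save_parametric_volume(pv, path_prefix, spacing=(1.0, 1.0, 1.0)):
    """Write mu/omega maps as two NIfTI files plus JSON metadata."""
    prefix = Path(path_prefix)
    save_nifti(np.nan_to_num(pv.mu_map), f"{prefix}_mu.nii.gz", spacing)
    save_nifti(np.nan_to_num(pv.omega_map), f"{prefix}_omega.nii.gz", spacing)
    meta = {
        "lattice_size": pv.lattice_config.lattice_size,
        "mode": pv.lattice_config.mode,
        "min_samples": pv.lattice_config.min_samples,
        "n_valid": int(pv.valid_mask.sum()),
        "n_invalid": int((~pv.valid_mask).sum()),
    }
    Path(f"{prefix}_meta.json").write_text(json.dumps(meta, indent=2))


def write_features_csv(table, path):
    table.to_frame().to_csv(path, index=False)


def read_features_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_metrics_json(report, path):
    Path(path).write_text(json.dumps(report.to_dict(), indent=2))


def export_slice_pngs(fmap, out_dir, axis: int = 2, cmap: str = "jet"):
    """Export per-slice colormap renders of a fractal map as PNG files."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    data = fmap.fd_map if hasattr(fmap, "fd_map") else np.asarray(fmap)
    if data.ndim != 3:
        raise ParameterError("expected a 3D map")
    for k in range(data.shape[axis]):
        sl = np.take(data, k, axis=axis)
        fig, ax = plt.subplots(figsize=(4, 4))
        im = ax.imshow(sl.T, origin="lower", cmap=cmap, vmin=2.0, vmax=3.0)
        fig.colorbar(im, ax=ax, shrink=0.8)
        ax.set_axis_off()
        fig.savefig(out / f"slice_{k:03d}.png", dpi=100, bbox_inches="tight")
        plt.close(fig)
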
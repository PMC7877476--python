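"""NIfTI and tabular I/O for beta series, masks and accuracy maps."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import BetaSeries, VolumeGeometry
from .decoding import AccuracyMap

__all__ = [
    "save_mask", "load_mask",
    "save_beta_series", "load_beta_series",
    "save_accuracy_map", "load_accuracy_map",
]


def _affine(voxel_size_mm=(2.0, 2.0, 2.0)) -> np.ndarray:
    aff = np.eye(4)
    aff[[0, 1, 2], [0, 1, 2]] = voxel_size_mm
    return aff


def save_mask(mask: np.ndarray, path, voxel_size_mm=(2.0, 2.0, 2.0)) -> None:
    img = nib.Nifti1Image(mask.astype(np.uint8), _affine(voxel_size_mm))
    nib.save(img, str(path))


def load_mask(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj) > 0


def save_beta_series(betas: BetaSeries, nifti_path, sidecar_path) -> None:
    """4-D NIfTI (x, y, z, trial) plus a labels TSV sidecar."""
    vox = (betas.geometry.voxel_size_mm if betas.geometry
           else (2.0, 2.0, 2.0))
    vols = np.moveaxis(betas.data, 0, -1).astype(np.float32)
    nib.save(nib.Nifti1Image(vols, _affine(vox)), str(nifti_path))
    pd.DataFrame({
        "trial": np.arange(1, betas.n_trials + 1),
        "run": betas.run_labels,
        "category": betas.categories,
        "subcategory": betas.subcategories,
    }).to_csv(sidecar_path, sep="\t", index=False)


def load_beta_series(nifti_path, sidecar_path, mask_path=None) -> BetaSeries:
    img = nib.load(str(nifti_path))
    data = np.moveaxis(np.asarray(img.dataobj, dtype=np.float64), -1, 0)
    labels = pd.read_csv(sidecar_path, sep="\t")
    if mask_path is not None:
        mask = load_mask(mask_path)
    else:
        mask = np.any(data != 0, axis=0)
    vox = tuple(float(z) for z in img.header.get_zooms()[:3])
    geometry = VolumeGeometry(shape=data.shape[1:], voxel_size_mm=vox,
                              mask=mask)
    return BetaSeries(data=data, mask=mask,
                      run_labels=labels["run"].to_numpy(),
                      categories=labels["category"].to_numpy(),
                      subcategories=labels["subcategory"].to_numpy(),
                      geometry=geometry)


def save_accuracy_map(amap: AccuracyMap, nifti_path, sidecar_path=None,
                      voxel_size_mm=(2.0, 2.0, 2.0)) -> None:
    """3-D float NIfTI, NaN outside mask, with a JSON sidecar."""
    nib.save(nib.Nifti1Image(amap.data.astype(np.float32),
                             _affine(voxel_size_mm)), str(nifti_path))
    if sidecar_path is not None:
        Path(sidecar_path).write_text(json.dumps({
            "chance": amap.chance, "level": amap.level,
            "subject_id": amap.subject_id,
        }, indent=1))


def load_accuracy_map(nifti_path, sidecar_path) -> AccuracyMap:
    data = np.asarray(nib.load(str(nifti_path)).dataobj, dtype=np.float64)
    meta = json.loads(Path(sidecar_path).read_text())
    return AccuracyMap(data=data, mask=np.isfinite(data),
                       chance=meta["chance"], level=meta["level"],
                       subject_id=meta.get("subject_id", ""))
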
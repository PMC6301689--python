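"""Volumetric file I/O and report writing.

Supported volume formats: NIfTI (``.nii``/``.nii.gz``) via nibabel and
MetaImage (``.mha``/``.mhd``) via SimpleITK. Volumes are stored and returned
with axis order (x, y, z), z being the slice direction; spacing is taken from
the file header and any NIfTI rescale slope/intercept is applied on read.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import SimpleITK as sitk

from . import __version__
from .phantom_sim import GroundTruth
from .pvc_scoring import ScanResult
from .volume import CTVolume

__all__ = [
    "VolumeIOError",
    "read_volume",
    "write_volume",
    "write_lesion_report",
    "write_ground_truth",
    "write_provenance",
]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_META_SUFFIXES = (".mha", ".mhd")


class VolumeIOError(Exception):
    """A volume file could not be read or written."""


def _format_of(path: Path) -> str:
    name = path.name.lower()
    if any(name.endswith(s) for s in _NIFTI_SUFFIXES):
        return "nifti"
    if any(name.endswith(s) for s in _META_SUFFIXES):
        return "meta"
    raise VolumeIOError(
        f"unrecognized volume format for {path.name!r}; "
        f"supported: {_NIFTI_SUFFIXES + _META_SUFFIXES}"
    )


def read_volume(path) -> CTVolume:
    """Read a NIfTI or MetaImage volume as a :class:`CTVolume` in HU."""
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such file: {path}")
    fmt = _format_of(path)
    try:
        if fmt == "nifti":
            img = nib.load(str(path))
            data = np.asarray(img.get_fdata())  # applies scl_slope/scl_inter
            zooms = img.header.get_zooms()[:3]
            origin = tuple(float(v) for v in img.affine[:3, 3])
        else:
            img = sitk.ReadImage(str(path))
            data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)  # (z,y,x) -> (x,y,z)
            zooms = img.GetSpacing()
            origin = tuple(float(v) for v in img.GetOrigin())
    except VolumeIOError:
        raise
    except Exception as exc:  # corrupt/truncated file: fail cleanly
        raise VolumeIOError(f"could not read {path}: {exc}") from exc
    if len(zooms) != 3 or any(not np.isfinite(z) or z <= 0 for z in zooms):
        raise VolumeIOError(f"missing or invalid voxel spacing in {path}: {zooms}")
    return CTVolume(data, tuple(float(z) for z in zooms), origin)


def write_volume(volume: CTVolume, path) -> None:
    """Write a :class:`CTVolume` to NIfTI or MetaImage (spacing in the header)."""
    path = Path(path)
    fmt = _format_of(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.asarray(volume.intensities, dtype=np.float32)
    if fmt == "nifti":
        affine = np.diag([*volume.spacing_mm, 1.0])
        affine[:3, 3] = volume.origin_mm
        nib.save(nib.Nifti1Image(data, affine), str(path))
    else:
        img = sitk.GetImageFromArray(data.transpose(2, 1, 0))
        img.SetSpacing(tuple(float(s) for s in volume.spacing_mm))
        img.SetOrigin(tuple(float(o) for o in volume.origin_mm))
        sitk.WriteImage(img, str(path))


def lesion_report_frame(result: ScanResult) -> pd.DataFrame:
    """Per-lesion results table (one row per lesion)."""
    rows = []
    for seg, score in zip(result.segmentations, result.scores):
        mix = score.mixture
        rows.append(
            {
                "lesion_id": score.label_id,
                "n_voxels": score.n_voxels,
                "d1_mm": seg.d1_mm,
                "d2_mm": seg.d2_mm,
                "mu_b_hu": mix.mu_B if mix else float("nan"),
                "sigma_b_hu": mix.sigma_B if mix else float("nan"),
                "threshold_hu": score.threshold_hu,
                "x_min_hu": score.x_min_hu,
                "x_max_hu": score.x_max_hu,
                "ccs_volume_mm3": score.ccs_volume_mm3,
                "pvc_volume_mm3": score.pvc_volume_mm3,
                "status": score.status,
            }
        )
    return pd.DataFrame(rows)


def write_lesion_report(result: ScanResult, path) -> pd.DataFrame:
    """Write the per-lesion CSV report; returns the frame written."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = lesion_report_frame(result)
    df.to_csv(path, index=False, float_format="%.6g")
    return df


def write_ground_truth(gt: GroundTruth, path) -> pd.DataFrame:
    """Write true insert volumes as CSV (insert_id, shape, density, volume)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "insert_id": [ins.insert_id for ins in gt.inserts],
            "shape": [ins.shape for ins in gt.inserts],
            "density_mg_cm3": [ins.ha_density_mg_cm3 for ins in gt.inserts],
            "true_volume_mm3": gt.true_volumes_mm3,
        }
    )
    df.to_csv(path, index=False, float_format="%.6g")
    return df


def write_provenance(path, config: dict, seed: int, **extra) -> None:
    """Record how outputs were produced (config, seed, package version)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    record = {"package": "pvccs", "version": __version__, "seed": seed, "config": config}
    record.update(extra)
    path.write_text(json.dumps(record, indent=2, sort_keys=True, default=str) + "\n")
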
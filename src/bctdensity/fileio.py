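"""NIfTI, CSV and JSON input/output.

Volumes are stored as NIfTI with the isotropic voxel size in the header
zooms; arrays are written in the package's native index order (slice, row,
column) without reorientation, so a read-after-write round trip is
bit-identical. Label maps use the integer codes of :class:`~.volume.Tissue`
(0=air, 1=adipose, 2=gland, 3=skin, 4=pectoralis, 5=rib, 6=skinfold).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .volume import CTVolume, LabelMap


class FileFormatError(ValueError):
    """Malformed or inconsistent input file."""


def _affine(voxel_size: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size
    return aff


def _read_zooms(img, path) -> float:
    zooms = img.header.get_zooms()[:3]
    if max(zooms) - min(zooms) > 1e-3 * max(zooms):
        raise FileFormatError(
            f"{path}: anisotropic voxels {zooms} unsupported (field: pixdim)"
        )
    if zooms[0] <= 0:
        raise FileFormatError(f"{path}: non-positive voxel size (field: pixdim)")
    return float(zooms[0])


def read_volume(path, laterality: str = "right") -> CTVolume:
    """Read an HU volume from NIfTI, honouring the header voxel size."""
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(np.float32)
    except Exception as exc:  # nibabel raises several unrelated types
        raise FileFormatError(f"{path}: not a readable NIfTI volume ({exc})") from exc
    vs = _read_zooms(img, path)
    if data.ndim != 3:
        raise FileFormatError(f"{path}: expected a 3D volume, got {data.ndim}D (field: dim)")
    if not np.all(np.isfinite(data)):
        raise FileFormatError(f"{path}: non-finite HU values (field: data)")
    return CTVolume(hu=data, voxel_size=vs, laterality=laterality)


def write_volume(volume: CTVolume, path) -> None:
    img = nib.Nifti1Image(volume.hu.astype(np.float32), _affine(volume.voxel_size))
    img.header.set_zooms((volume.voxel_size,) * 3)
    nib.save(img, str(path))


def read_labels(path, laterality: str = "right") -> LabelMap:
    try:
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(np.uint8)
    except Exception as exc:
        raise FileFormatError(f"{path}: not a readable NIfTI label map ({exc})") from exc
    return LabelMap(labels=data, voxel_size=_read_zooms(img, path), laterality=laterality)


def write_labels(labels: LabelMap, path) -> None:
    img = nib.Nifti1Image(labels.labels.astype(np.uint8), _affine(labels.voxel_size))
    img.header.set_zooms((labels.voxel_size,) * 3)
    nib.save(img, str(path))


def check_spacing_match(volume: CTVolume, labels: LabelMap, tol: float = 1e-6) -> None:
    """Raise when a volume and label map disagree in spacing or shape."""
    if volume.shape != labels.shape:
        raise FileFormatError(
            f"shape mismatch: volume {volume.shape} vs labels {labels.shape} (field: dim)"
        )
    if abs(volume.voxel_size - labels.voxel_size) > tol:
        raise FileFormatError(
            f"spacing mismatch: volume {volume.voxel_size} mm vs labels "
            f"{labels.voxel_size} mm (field: pixdim)"
        )


def write_features_csv(frame: pd.DataFrame, path) -> None:
    """Fixed-column-order CSV writer for composition feature tables."""
    frame.to_csv(path, index=False, float_format="%.10g")


def read_features_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
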
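"""Readers/writers for volumes, masks, training tables and manifests.

Volumes use NIfTI-1.  On disk the array axes follow the package convention
``[lr, ap, si]`` stored with an RAS-like diagonal affine carrying the voxel
spacing; arbitrary NIfTI orientations are mapped to that convention through
the file's affine on read.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .features import FEATURE_NAMES
from .knn import KnnModel
from .volume import DiskVolume, VoxelVolume


def write_volume(volume: VoxelVolume, path) -> None:
    affine = np.diag([*volume.spacing_mm, 1.0])
    img = nib.Nifti1Image(np.asarray(volume.data), affine)
    img.header.set_zooms(volume.spacing_mm)
    nib.save(img, str(path))


def write_mask(mask: np.ndarray, spacing_mm: Sequence[float], path) -> None:
    affine = np.diag([*spacing_mm, 1.0])
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), affine)
    img.header.set_zooms(tuple(spacing_mm))
    nib.save(img, str(path))


def read_volume(path) -> VoxelVolume:
    """Read a NIfTI volume into the [lr, ap, si] axis convention.

    The file's affine provides the orientation; volumes written by
    :func:`write_volume` round-trip voxel- and spacing-identically.  A file
    without usable orientation metadata (singular affine) is rejected.
    """
    img = nib.load(str(path))
    affine = img.affine
    if affine is None or abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError(
            f"{path}: no usable orientation metadata; re-export the volume with "
            "a valid affine or supply explicit axis mapping"
        )
    canonical = nib.as_closest_canonical(img)  # RAS+ == (lr, ap, si)
    data = np.asarray(canonical.dataobj)
    spacing = tuple(float(z) for z in canonical.header.get_zooms()[:3])
    return VoxelVolume(data, spacing)


def read_mask(path) -> VoxelVolume:
    v = read_volume(path)
    return VoxelVolume(v.data.astype(bool), v.spacing_mm)


def regions_to_csv(regions, path) -> None:
    """One row per region: the 8 features plus the label."""
    rows = []
    for r in regions:
        if r.features is None:
            raise ValueError("region has no computed features")
        row = dict(zip(FEATURE_NAMES, r.features.as_array()))
        row["label"] = r.label
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_training_csv(path) -> tuple[np.ndarray, List[str]]:
    df = pd.read_csv(path)
    missing = [c for c in (*FEATURE_NAMES, "label") if c not in df.columns]
    if missing:
        raise ValueError(f"training CSV missing columns: {missing}")
    return df[list(FEATURE_NAMES)].to_numpy(dtype=float), df["label"].tolist()


def save_model(model: KnnModel, path) -> None:
    Path(path).write_text(model.to_json())


def load_model(path) -> KnnModel:
    return KnnModel.from_json(Path(path).read_text())


def write_disk_manifest(disks: Sequence[DiskVolume], paths: Sequence[str], out_path) -> None:
    """JSON manifest describing per-disk mask files and their provenance."""
    entries = []
    for d, p in zip(disks, paths):
        entries.append(
            {
                "disk_id": d.disk_id,
                "file": str(p),
                "source": d.source,
                "n_voxels": d.n_voxels,
                "centroid_mm": list(d.centroid_mm),
                "assigned_coronal": list(d.assigned_coronal),
            }
        )
    Path(out_path).write_text(json.dumps({"disks": entries}, indent=2))
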
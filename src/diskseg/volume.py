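"""Core spatial containers shared across the segmentation pipeline.

Axis convention for 3D grids: ``[lr, ap, si]`` where

* ``lr`` — left→right (the sagittal stacking axis),
* ``ap`` — anterior→posterior (the coronal stacking axis),
* ``si`` — inferior→superior (along the spine).

A sagittal slice is a fixed-``lr`` plane (2D axes ``(ap, si)``); a coronal
slice is a fixed-``ap`` plane (2D axes ``(lr, si)``).  All spacings are in
millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
from skimage.measure import find_contours

AXES = ("lr", "ap", "si")

SAGITTAL = "sagittal"
CORONAL = "coronal"


@dataclass
class VoxelVolume:
    """A 3D scalar intensity grid with per-axis spacing in mm."""

    data: np.ndarray
    spacing_mm: Tuple[float, float, float]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("VoxelVolume data must be 3-dimensional")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be three positive values")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return tuple(self.data.shape)

    def extent_mm(self) -> Tuple[float, float, float]:
        """Physical extent along each axis (distance between outermost voxel centres)."""
        return tuple((n - 1) * s for n, s in zip(self.data.shape, self.spacing_mm))

    def sagittal_slice(self, index: int) -> "SliceImage":
        return SliceImage(
            pixels=self.data[index, :, :],
            spacing_mm=(self.spacing_mm[1], self.spacing_mm[2]),
            plane=SAGITTAL,
            index=int(index),
        )

    def coronal_slice(self, index: int) -> "SliceImage":
        return SliceImage(
            pixels=self.data[:, index, :],
            spacing_mm=(self.spacing_mm[0], self.spacing_mm[2]),
            plane=CORONAL,
            index=int(index),
        )


@dataclass
class SliceImage:
    """A single 2D slice extracted from a :class:`VoxelVolume`.

    ``pixels`` is indexed ``(row, col)``; for a sagittal slice rows run along
    ``ap`` and columns along ``si``, for a coronal slice rows run along ``lr``.
    """

    pixels: np.ndarray
    spacing_mm: Tuple[float, float]
    plane: str = SAGITTAL
    index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("SliceImage pixels must be 2-dimensional")
        if min(self.pixels.shape) < 16:
            raise ValueError("SliceImage must be at least 16x16 pixels")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("slice spacing must be positive")
        if self.plane not in (SAGITTAL, CORONAL):
            raise ValueError(f"unknown plane {self.plane!r}")

    @property
    def dynamic_range(self) -> Tuple[float, float]:
        return float(self.pixels.min()), float(self.pixels.max())

    @property
    def pixel_area_mm2(self) -> float:
        return self.spacing_mm[0] * self.spacing_mm[1]


def trace_contour(mask: np.ndarray) -> np.ndarray:
    """Closed sub-pixel boundary polygon of a binary 2D mask.

    Returns an ``(M, 2)`` float array of ``(row, col)`` vertices with the first
    vertex repeated at the end (closed contour).  The longest contour is
    returned when the mask has holes.
    """
    mask = np.asarray(mask, dtype=bool)
    padded = np.pad(mask, 1).astype(float)
    contours = find_contours(padded, 0.5)
    if not contours:
        return np.empty((0, 2), dtype=float)
    longest = max(contours, key=len)
    return longest - 1.0  # undo padding offset


@dataclass
class Region2D:
    """A connected pixel set produced by per-slice segmentation.

    Carries the member pixel coordinates and intensities, the identity of the
    owning slice, a closed boundary contour, and (once computed) the texture
    feature vector and classifier label.
    """

    pixels: np.ndarray  # (N, 2) int (row, col)
    intensities: np.ndarray  # (N,) float
    plane: str
    slice_index: int
    slice_dynamic_range: Tuple[float, float]
    contour: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    features: Optional[object] = None  # FeatureVector, set by features module
    label: str = "unlabeled"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.intp).reshape(-1, 2)
        self.intensities = np.asarray(self.intensities, dtype=float).reshape(-1)
        if len(self.pixels) == 0:
            raise ValueError("Region2D must contain at least one pixel")
        if len(self.pixels) != len(self.intensities):
            raise ValueError("pixels and intensities must have matching length")

    @property
    def area_px(self) -> int:
        return int(len(self.pixels))

    @property
    def mean_intensity(self) -> float:
        return float(self.intensities.mean())

    def bounding_box(self) -> Tuple[int, int, int, int]:
        """(row_min, col_min, row_max, col_max), inclusive."""
        rmin, cmin = self.pixels.min(axis=0)
        rmax, cmax = self.pixels.max(axis=0)
        return int(rmin), int(cmin), int(rmax), int(cmax)

    def mask(self, shape: Tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        m[self.pixels[:, 0], self.pixels[:, 1]] = True
        return m


@dataclass
class DiskVolume:
    """A 3D voxel set for one intervertebral disk with provenance.

    ``source`` records where the voxels came from: ``sagittal_reference`` for
    the classified sagittal stack (Dref), ``coronal`` for components built
    from the reconstructed coronal segmentation (Dcor), and ``fused`` for the
    union of the two.
    """

    mask: np.ndarray  # 3D bool on the stated grid
    spacing_mm: Tuple[float, float, float]
    source: str = "sagittal_reference"
    disk_id: Optional[int] = None
    assigned_coronal: Tuple[int, ...] = ()

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("DiskVolume mask must be 3-dimensional")
        if not self.mask.any():
            raise ValueError("DiskVolume must be nonempty")
        if self.source not in ("sagittal_reference", "coronal", "fused"):
            raise ValueError(f"unknown source {self.source!r}")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def centroid_mm(self) -> Tuple[float, float, float]:
        idx = np.argwhere(self.mask)
        c = idx.mean(axis=0) * np.asarray(self.spacing_mm)
        return tuple(float(v) for v in c)

    def volume_mm3(self) -> float:
        return self.n_voxels * float(np.prod(self.spacing_mm))
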
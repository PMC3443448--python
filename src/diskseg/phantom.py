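"""Synthetic scoliotic-spine MR phantom with ground-truth disk masks.

The phantom emulates the statistical structure that the segmentation pipeline
assumes in short-TE spine MR images: bright roughly-ellipsoidal intervertebral
disks stacked between larger, darker vertebral bodies along a laterally curved
spine, over a dark background, degraded by a Gaussian point-spread blur and
additive Gaussian noise.

Contrast presets emulate the three acquisition families qualitatively:

* ``medic``      — 1 mm isotropic voxels, crisp boundaries;
* ``spin_echo``  — 2 mm sagittal slices with a 0.4 mm gap (2.4 mm slice
  pitch along ``lr``) and finer in-plane sampling; an optional
  ``bright_nucleus`` artifact renders the nucleus brighter than the annulus;
* ``fisp``       — 1 mm isotropic voxels with additionally blurred disk
  boundaries.

The lateral curvature of the spine centreline is a single circular arc in the
coronal (lr–si) plane whose end-tangent angle difference equals
``cobb_like_angle_deg`` — the clinical Cobb-angle notion without vertebral
rotation.  Disks are ellipsoids oriented perpendicular to the local centreline
tangent.  Ground-truth masks are the noise-free voxelized ellipsoids before
any blurring.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage as ndi

from .volume import Region2D, VoxelVolume

# Tissue intensities on an arbitrary [0, 1] scale; what matters downstream is
# the ordering disk > vertebra > background and the disk/background contrast
# that noise_sigma is expressed against.
BACKGROUND_INTENSITY = 0.15
VERTEBRA_INTENSITY = 0.45
DISK_INTENSITY = 0.85
NUCLEUS_INTENSITY = 0.98
ANNULUS_INTENSITY = 0.68  # used only in bright_nucleus mode

#: preset -> (spacing_mm (lr, ap, si), extra disk-edge blur sigma in mm)
CONTRAST_PRESETS = {
    "medic": ((1.0, 1.0, 1.0), 0.0),
    "spin_echo": ((2.4, 0.7, 0.7), 0.0),
    "fisp": ((1.0, 1.0, 1.0), 1.5),
}

_DEFAULT_FOV_MM = (56.0, 44.0, 144.0)


@dataclass
class PhantomSpec:
    """Parameters of the synthetic spine volume.

    ``disk_semi_axes_mm`` is ordered ``(ap, lr, si)``.  ``noise_sigma`` is the
    additive-noise standard deviation relative to the disk/background
    intensity contrast.  ``grid_shape``/``spacing_mm`` may be left ``None`` to
    derive them from a standard 56x44x144 mm field of view and the preset's
    native spacing.
    """

    grid_shape: Optional[Tuple[int, int, int]] = None
    spacing_mm: Optional[Tuple[float, float, float]] = None
    n_disks: int = 5
    cobb_like_angle_deg: float = 30.0
    disk_semi_axes_mm: Tuple[float, float, float] = (12.0, 14.0, 4.0)
    contrast_preset: str = "medic"
    blur_sigma_mm: float = 0.8
    noise_sigma: float = 0.05
    bright_nucleus: bool = False
    seed: int = 42

    def __post_init__(self) -> None:
        if self.contrast_preset not in CONTRAST_PRESETS:
            raise ValueError(
                f"unknown contrast_preset {self.contrast_preset!r}; "
                f"expected one of {sorted(CONTRAST_PRESETS)}"
            )
        if self.n_disks < 1:
            raise ValueError("n_disks must be >= 1")
        if self.blur_sigma_mm < 0:
            raise ValueError("blur_sigma_mm must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not (0.0 <= self.cobb_like_angle_deg < 90.0):
            raise ValueError("cobb_like_angle_deg must be in [0, 90)")
        if any(a <= 0 for a in self.disk_semi_axes_mm):
            raise ValueError("disk semi-axes must be positive")
        if self.spacing_mm is not None and any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm entries must be positive")

    def resolved_spacing(self) -> Tuple[float, float, float]:
        if self.spacing_mm is not None:
            return tuple(float(s) for s in self.spacing_mm)
        return CONTRAST_PRESETS[self.contrast_preset][0]

    def resolved_shape(self) -> Tuple[int, int, int]:
        if self.grid_shape is not None:
            return tuple(int(n) for n in self.grid_shape)
        sp = self.resolved_spacing()
        return tuple(int(round(f / s)) + 1 for f, s in zip(_DEFAULT_FOV_MM, sp))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.resolved_shape())
        d["spacing_mm"] = list(self.resolved_spacing())
        return d


@dataclass
class PhantomVolume:
    """A rendered phantom: intensity volume plus per-disk ground truth."""

    volume: VoxelVolume
    truth_masks: List[np.ndarray]
    disk_ids: List[int]
    spec: PhantomSpec
    disk_centroids_mm: List[Tuple[float, float, float]] = field(default_factory=list)

    @property
    def n_disks(self) -> int:
        return len(self.truth_masks)

    def sidecar(self) -> dict:
        """JSON-serializable record of the generating parameters and geometry."""
        return {
            "spec": self.spec.to_dict(),
            "disk_ids": list(self.disk_ids),
            "disk_centroids_mm": [list(c) for c in self.disk_centroids_mm],
        }


def _vertebra_semi_axes(disk_semi: Sequence[float]) -> Tuple[float, float, float]:
    ap, lr, si = disk_semi
    return (ap, 0.9 * lr, 2.0 * si)


def _ellipsoid_mask(
    shape: Tuple[int, int, int],
    spacing: Tuple[float, float, float],
    center_mm: Tuple[float, float, float],
    semi_mm: Tuple[float, float, float],  # (lr, ap, si) local axes
    tilt_rad: float,
) -> np.ndarray:
    """Voxelize an ellipsoid rotated by ``tilt_rad`` about the ap axis.

    Evaluates the quadratic form only inside the bounding sub-box for speed.
    A voxel belongs to the mask when its centre lies inside the ellipsoid.
    """
    a_lr, b_ap, c_si = semi_mm
    cx, cy, cz = center_mm
    half = (
        max(a_lr, c_si) + 2 * spacing[0],
        b_ap + 2 * spacing[1],
        max(a_lr, c_si) + 2 * spacing[2],
    )
    lo = [max(0, int(math.floor((c - h) / s))) for c, h, s in zip(center_mm, half, spacing)]
    hi = [
        min(n, int(math.ceil((c + h) / s)) + 1)
        for n, c, h, s in zip(shape, center_mm, half, spacing)
    ]
    mask = np.zeros(shape, dtype=bool)
    if any(l >= h for l, h in zip(lo, hi)):
        return mask
    x = np.arange(lo[0], hi[0]) * spacing[0] - cx
    y = np.arange(lo[1], hi[1]) * spacing[1] - cy
    z = np.arange(lo[2], hi[2]) * spacing[2] - cz
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    ct, st = math.cos(tilt_rad), math.sin(tilt_rad)
    U = X * ct + Z * st  # local lr
    W = -X * st + Z * ct  # local si
    inside = (U / a_lr) ** 2 + (Y / b_ap) ** 2 + (W / c_si) ** 2 <= 1.0
    mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] = inside
    return mask


def _centerline(
    z_disks: np.ndarray, cobb_deg: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Lateral offset and tangent tilt of the spine arc at each disk centre.

    The arc is a circle segment in the lr–si plane whose chord joins the first
    and last disk centres; the tangent-angle difference between the chord ends
    equals ``cobb_deg``.  Returns ``(offset_mm, tilt_rad)`` per disk.
    """
    n = len(z_disks)
    if cobb_deg == 0.0 or n == 1:
        return np.zeros(n), np.zeros(n)
    theta = math.radians(cobb_deg)
    chord = float(z_disks[-1] - z_disks[0])
    radius = chord / (2.0 * math.sin(theta / 2.0))
    zm = 0.5 * (z_disks[0] + z_disks[-1])
    dz = np.clip(z_disks - zm, -radius, radius)
    offset = np.sqrt(radius**2 - dz**2) - radius * math.cos(theta / 2.0)
    tilt = np.arctan2(-dz, np.sqrt(radius**2 - dz**2))
    return offset, tilt


def make_spine_phantom(spec: PhantomSpec) -> PhantomVolume:
    """Render a synthetic scoliotic spine volume with ground-truth disk masks.

    Deterministic for a fixed ``spec.seed``.  Raises ``ValueError`` when the
    superior–inferior grid extent cannot contain ``n_disks`` disks plus the
    flanking vertebral bodies, naming the minimal required extent.
    """
    shape = spec.resolved_shape()
    spacing = spec.resolved_spacing()
    disk_ap, disk_lr, disk_si = spec.disk_semi_axes_mm
    vert_ap, vert_lr, vert_si = _vertebra_semi_axes(spec.disk_semi_axes_mm)

    pitch = 2.0 * (disk_si + vert_si)  # disk-centre spacing along si
    si_extent = (shape[2] - 1) * spacing[2]
    margin = disk_si + 2.0 * vert_si
    required = (spec.n_disks - 1) * pitch + 2.0 * margin
    if si_extent < required:
        raise ValueError(
            f"grid too small for {spec.n_disks} disks: superior-inferior extent "
            f"is {si_extent:.1f} mm but at least {required:.1f} mm is needed"
        )

    xc = (shape[0] - 1) / 2.0 * spacing[0]
    yc = (shape[1] - 1) / 2.0 * spacing[1]
    z0 = (si_extent - (spec.n_disks - 1) * pitch) / 2.0
    z_disks = z0 + pitch * np.arange(spec.n_disks)
    offsets, tilts = _centerline(z_disks, spec.cobb_like_angle_deg)

    vol = np.full(shape, BACKGROUND_INTENSITY, dtype=float)

    # Vertebral bodies sit between and beyond the disks; their centreline
    # offsets/tilts are interpolated on the same arc.
    z_verts = np.concatenate([[z_disks[0] - pitch / 2.0], z_disks + pitch / 2.0])
    v_off, v_tilt = _centerline_at(z_disks, offsets, tilts, z_verts, spec)
    for zv, ov, tv in zip(z_verts, v_off, v_tilt):
        m = _ellipsoid_mask(shape, spacing, (xc + ov, yc, zv), (vert_lr, vert_ap, vert_si), tv)
        vol[m] = VERTEBRA_INTENSITY

    _, edge_sigma = CONTRAST_PRESETS[spec.contrast_preset]
    truth_masks: List[np.ndarray] = []
    centroids: List[Tuple[float, float, float]] = []
    for zd, od, td in zip(z_disks, offsets, tilts):
        center = (xc + od, yc, zd)
        m = _ellipsoid_mask(shape, spacing, center, (disk_lr, disk_ap, disk_si), td)
        truth_masks.append(m)
        idx = np.argwhere(m)
        centroids.append(tuple((idx.mean(axis=0) * np.asarray(spacing)).tolist()))
        disk_val = ANNULUS_INTENSITY if spec.bright_nucleus else DISK_INTENSITY
        if edge_sigma > 0:
            soft = ndi.gaussian_filter(
                m.astype(float), sigma=[edge_sigma / s for s in spacing]
            )
            soft = np.clip(soft, 0.0, 1.0)
            vol = vol * (1.0 - soft) + disk_val * soft
        else:
            vol[m] = disk_val
        if spec.bright_nucleus:
            nucleus = _ellipsoid_mask(
                shape,
                spacing,
                center,
                (0.55 * disk_lr, 0.55 * disk_ap, 0.55 * disk_si),
                td,
            )
            vol[nucleus] = NUCLEUS_INTENSITY

    if spec.blur_sigma_mm > 0:
        vol = ndi.gaussian_filter(vol, sigma=[spec.blur_sigma_mm / s for s in spacing])
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        contrast = DISK_INTENSITY - BACKGROUND_INTENSITY
        vol = vol + rng.normal(0.0, spec.noise_sigma * contrast, size=shape)

    return PhantomVolume(
        volume=VoxelVolume(vol.astype(np.float32), spacing),
        truth_masks=truth_masks,
        disk_ids=list(range(spec.n_disks)),
        spec=spec,
        disk_centroids_mm=centroids,
    )


def _centerline_at(z_disks, offsets, tilts, z_query, spec):
    """Evaluate the arc at arbitrary si positions (vertebra centres)."""
    if spec.cobb_like_angle_deg == 0.0 or len(z_disks) == 1:
        return np.zeros(len(z_query)), np.zeros(len(z_query))
    theta = math.radians(spec.cobb_like_angle_deg)
    chord = float(z_disks[-1] - z_disks[0])
    radius = chord / (2.0 * math.sin(theta / 2.0))
    zm = 0.5 * (z_disks[0] + z_disks[-1])
    dz = np.clip(np.asarray(z_query) - zm, -radius + 1e-9, radius - 1e-9)
    off = np.sqrt(radius**2 - dz**2) - radius * math.cos(theta / 2.0)
    tilt = np.arctan2(-dz, np.sqrt(radius**2 - dz**2))
    return off, tilt


def make_training_regions(
    spec: PhantomSpec, n_per_class: int, seed: int
) -> List[Region2D]:
    """Synthesize labeled training regions for the disk/background classifier.

    Emulates how such training data is produced from clinical images: rendered
    sagittal slices are watershed-segmented and the resulting candidate
    regions are labeled against the ground truth — candidates covering a disk
    cross-section (2D Dice ≥ 0.5) become ``disk`` samples (bright, elliptical,
    smooth texture), candidates with no disk overlap become ``background``
    samples (vertebral bodies and other tissue, different intensity
    statistics).  This keeps the training distribution aligned with the
    regions the classifier will actually see.  ``n_per_class`` samples per
    label are drawn with the given ``seed``; deterministic.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    from .watershed import SegmentationParams, segment_slice  # local: avoid cycle

    phantom = make_spine_phantom(spec)
    vol = phantom.volume
    rng = np.random.default_rng(seed)
    params = SegmentationParams()

    disk_pool: List[Region2D] = []
    background_pool: List[Region2D] = []
    order = rng.permutation(vol.shape[0])
    for i in order:
        sl = vol.sagittal_slice(int(i))
        shape = sl.pixels.shape
        truth_2d = [m[int(i)] for m in phantom.truth_masks if m[int(i)].any()]
        for region in segment_slice(sl, params):
            mask = region.mask(shape)
            best_dice = 0.0
            any_overlap = False
            for t in truth_2d:
                ov = int((mask & t).sum())
                if ov:
                    any_overlap = True
                    best_dice = max(best_dice, 2.0 * ov / (mask.sum() + t.sum()))
            if best_dice >= 0.5:
                region.label = "disk"
                disk_pool.append(region)
            elif not any_overlap:
                region.label = "background"
                background_pool.append(region)
        if len(disk_pool) >= 3 * n_per_class and len(background_pool) >= 3 * n_per_class:
            break
    if not disk_pool or not background_pool:
        raise ValueError("phantom slices yielded no usable training regions")

    def _sample(pool: List[Region2D]) -> List[Region2D]:
        idx = rng.choice(len(pool), size=n_per_class, replace=len(pool) < n_per_class)
        return [pool[int(j)] for j in np.atleast_1d(idx)]

    return _sample(disk_pool) + _sample(background_pool)


def write_sidecar(phantom: PhantomVolume, path) -> None:
    with open(path, "w") as fh:
        json.dump(phantom.sidecar(), fh, indent=2)
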
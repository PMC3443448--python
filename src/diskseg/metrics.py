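"""Quantitative evaluation of segmentations.

Implements the validation suite used to judge the reconstruction: the Dice
similarity coefficient DSC(X, Y) = 2|X∩Y| / (|X| + |Y|) in 3D and per slice,
the mid-sagittal/lateral slice partition, signed volume discrepancy
(over-/under-estimation), a boundary-distance measure localized to the
spinal-canal side of the disk, and pairwise variability tables comparing
several raters/methods.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DSCResult:
    """Spatial overlap between two voxel sets, with the raw counts."""

    value: float
    n_x: int
    n_y: int
    n_intersection: int


def dsc(x: np.ndarray, y: np.ndarray) -> DSCResult:
    """Dice similarity coefficient of two binary masks on the same grid.

    1 means perfect overlap, 0 means no overlap; symmetric in its arguments.
    Raises on grid mismatch and on two empty sets (0/0 undefined).
    """
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    if x.shape != y.shape:
        raise ValueError(f"grid mismatch: {x.shape} vs {y.shape}")
    n_x = int(x.sum())
    n_y = int(y.sum())
    if n_x + n_y == 0:
        raise ValueError("DSC undefined for two empty sets")
    n_i = int((x & y).sum())
    return DSCResult(value=2.0 * n_i / (n_x + n_y), n_x=n_x, n_y=n_y, n_intersection=n_i)


def dsc_per_slice(
    x: np.ndarray, y: np.ndarray, axis: int = 0
) -> List[Tuple[int, DSCResult]]:
    """2D DSC for every slice along ``axis`` where x∪y is nonempty.

    Slices where both masks are empty are skipped; a slice where exactly one
    is empty scores 0.
    """
    x = np.asarray(x, dtype=bool)
    y = np.asarray(y, dtype=bool)
    if x.shape != y.shape:
        raise ValueError(f"grid mismatch: {x.shape} vs {y.shape}")
    out: List[Tuple[int, DSCResult]] = []
    for i in range(x.shape[axis]):
        xs = np.take(x, i, axis=axis)
        ys = np.take(y, i, axis=axis)
        if not xs.any() and not ys.any():
            continue
        out.append((i, dsc(xs, ys)))
    return out


@dataclass(frozen=True)
class SlicePartition:
    """Mid vs lateral split of the slice indices spanning one disk."""

    mid_indices: Tuple[int, ...]
    lateral_indices: Tuple[int, ...]


def partition_mid_lateral(spanning_indices: Sequence[int]) -> SlicePartition:
    """Split a disk's spanning slices into ~80% mid and ~10% per lateral side.

    The per-side lateral count is ceil(0.10 * n_total); the remainder is mid.
    The split is symmetric (equal count trimmed at each end).  Requires at
    least 3 spanning slices.
    """
    idx = list(spanning_indices)
    n = len(idx)
    if n < 3:
        raise ValueError("need at least 3 spanning slices to partition")
    per_side = math.ceil(0.10 * n)
    lateral = tuple(idx[:per_side] + idx[n - per_side :])
    mid = tuple(idx[per_side : n - per_side])
    return SlicePartition(mid_indices=mid, lateral_indices=lateral)


@dataclass(frozen=True)
class VolumeDiscrepancy:
    """Signed relative volume difference; negative = under-estimation."""

    relative: float
    n_auto: int
    n_manual: int
    volume_auto_mm3: float
    volume_manual_mm3: float


def volume_discrepancy(
    auto: np.ndarray, manual: np.ndarray, spacing: Sequence[float]
) -> VolumeDiscrepancy:
    auto = np.asarray(auto, dtype=bool)
    manual = np.asarray(manual, dtype=bool)
    if auto.shape != manual.shape:
        raise ValueError("grid mismatch")
    n_a, n_m = int(auto.sum()), int(manual.sum())
    if n_m == 0:
        raise ValueError("manual set is empty")
    vx = float(np.prod(spacing))
    return VolumeDiscrepancy(
        relative=(n_a - n_m) / n_m,
        n_auto=n_a,
        n_manual=n_m,
        volume_auto_mm3=n_a * vx,
        volume_manual_mm3=n_m * vx,
    )


def _boundary(mask: np.ndarray) -> np.ndarray:
    # 4-connected inner boundary; array-edge pixels of the mask count too.
    er = ndi.binary_erosion(mask, structure=ndi.generate_binary_structure(2, 1))
    return mask & ~er


def canal_boundary_distance(
    auto: np.ndarray,
    manual: np.ndarray,
    canal_slices: Sequence[int],
    spacing: Sequence[float],
    posterior_band_fraction: float = 0.25,
) -> Tuple[float, float, int]:
    """Mean boundary distance (mm) near the spinal canal, pooled over slices.

    On each listed sagittal slice (``lr`` index), every *manual*
    posterior-facing boundary pixel lying in the posterior band — the
    posterior ``posterior_band_fraction`` of the manual disk's
    anterior–posterior extent, with posterior = increasing ``ap`` index — is
    matched to the nearest *automatic* boundary pixel (Euclidean, in mm).
    Posterior-facing means the next pixel in the ``ap`` direction is outside
    the mask, so the measure tracks the boundary that faces the spinal
    canal rather than the disk's lateral rim.  Returns
    ``(mean, std, n_points)`` with a population std.  Slices with an empty
    automatic mask are skipped and logged.
    """
    auto = np.asarray(auto, dtype=bool)
    manual = np.asarray(manual, dtype=bool)
    if auto.shape != manual.shape:
        raise ValueError("grid mismatch")
    if len(canal_slices) == 0:
        raise ValueError("canal_slices must be nonempty")
    sp = np.asarray(spacing[1:], dtype=float)  # in-plane (ap, si) spacing
    dists: List[float] = []
    for s in canal_slices:
        man, aut = manual[s], auto[s]
        if not man.any():
            raise ValueError(f"manual mask empty on listed slice {s}")
        if not aut.any():
            logger.warning("canal distance: automatic mask empty on slice %d; skipped", s)
            continue
        posterior_facing = man.copy()
        posterior_facing[:-1] &= ~man[1:]  # next-ap neighbour outside mask
        posterior_facing[-1] &= man[-1]
        bm = np.argwhere(_boundary(man) & posterior_facing)
        ba = np.argwhere(_boundary(aut))
        rows = np.argwhere(man)[:, 0]
        ap_min, ap_max = rows.min(), rows.max()
        extent = ap_max - ap_min
        cutoff = ap_min + (1.0 - posterior_band_fraction) * extent
        band = bm[bm[:, 0] >= cutoff]
        if len(band) == 0:
            band = bm[bm[:, 0] == bm[:, 0].max()]
        tree = cKDTree(ba * sp)
        d, _ = tree.query(band * sp)
        dists.extend(np.atleast_1d(d).tolist())
    if not dists:
        raise ValueError("no usable slices for canal boundary distance")
    arr = np.asarray(dists)
    return float(arr.mean()), float(arr.std()), len(arr)


def variability_table(
    segmentations: Mapping[str, Mapping[object, np.ndarray]],
) -> pd.DataFrame:
    """Pairwise mean 3D DSC (with spread) across disks for named raters.

    ``segmentations`` maps a name (e.g. ``user1``, ``user2``, ``auto``) to a
    mapping of disk id → binary mask.  For every unordered pair of names the
    per-disk DSC is averaged over the disks both names segmented (missing
    disks are excluded for that pair and logged).  Both the population and
    the sample (n−1) standard deviation are reported.
    """
    names = list(segmentations)
    if len(names) < 2:
        raise ValueError("need at least 2 named segmentations")
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            values = []
            for disk in segmentations[a]:
                if disk not in segmentations[b]:
                    logger.warning("disk %r missing for %r; excluded from (%s,%s)", disk, b, a, b)
                    continue
                values.append(dsc(segmentations[a][disk], segmentations[b][disk]).value)
            for disk in segmentations[b]:
                if disk not in segmentations[a]:
                    logger.warning("disk %r missing for %r; excluded from (%s,%s)", disk, a, a, b)
            if not values:
                continue
            v = np.asarray(values)
            rows.append(
                {
                    "pair": f"{a} vs {b}",
                    "mean_dsc": float(v.mean()),
                    "std_pop": float(v.std()),
                    "std_sample": float(v.std(ddof=1)) if len(v) > 1 else float("nan"),
                    "n_disks": len(v),
                }
            )
    return pd.DataFrame(rows)
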
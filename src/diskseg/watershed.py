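"""Marker-controlled watershed segmentation of a single slice.

The per-slice stage of the pipeline: a morphological gradient highlights
boundaries, internal markers seed one catchment basin per locally-bright
homogeneous structure, external markers (the deepest valley lines between
internal markers) seed the separating background, the combined markers are
imposed as the only regional minima of the gradient, and marker-seeded
flooding grows the basins.  Basins grown from internal markers become
candidate regions; background basins and basins touching the image border are
discarded.  Over-segmentation is expected and tolerated — the classifier
removes false candidates afterwards.

Flooding uses 4-connectivity with a fully deterministic priority: pixels are
assigned in increasing order of (gray value, row, col), i.e. gray-level ties
are broken in raster-scan order, so results are reproducible bit-for-bit
across runs and platforms.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import disk as disk_se
from skimage.morphology import h_maxima, reconstruction

from .volume import Region2D, SliceImage, trace_contour

WSHED = -1  # label of watershed-line pixels in flooding output

_N4 = ((-1, 0), (1, 0), (0, -1), (0, 1))
_S8 = np.ones((3, 3), dtype=int)  # 8-connectivity for marker components


class EmptyMarkerError(ValueError):
    """Raised when minima imposition / flooding would be unseeded."""


@dataclass
class SegmentationParams:
    """Tunable constants of the per-slice segmentation.

    ``se_radius_px``    radius of the disk structuring element of the
                        morphological gradient (px).
    ``smooth_radius_px`` radius used for the opening/closing-by-reconstruction
                        smoothing before marker extraction (px).
    ``h_fraction``      h-maxima contrast threshold as a fraction of the slice
                        dynamic range.
    ``min_area_mm2``    minimum internal-marker component area; converted to
                        pixels with the slice's pixel area.
    """

    se_radius_px: int = 1
    smooth_radius_px: int = 2
    h_fraction: float = 0.10
    min_area_mm2: float = 30.0


@dataclass
class MarkerSet:
    """Internal / external / combined binary markers for one slice."""

    internal: np.ndarray
    external: np.ndarray

    def __post_init__(self) -> None:
        self.internal = np.asarray(self.internal, dtype=bool)
        self.external = np.asarray(self.external, dtype=bool)
        if self.internal.shape != self.external.shape:
            raise ValueError("internal/external marker shapes differ")
        if (self.internal & self.external).any():
            raise ValueError("internal and external markers must be disjoint")

    @property
    def combined(self) -> np.ndarray:
        return self.internal | self.external


def morphological_gradient(slice_img: SliceImage, se_radius_px: int = 1) -> np.ndarray:
    """Dilation minus erosion with a disk structuring element.

    Nonnegative everywhere; zero on constant images; invariant to adding a
    constant to the input.
    """
    if se_radius_px < 1:
        raise ValueError("se_radius_px must be >= 1")
    se = disk_se(se_radius_px)
    img = np.asarray(slice_img.pixels, dtype=float)
    dil = ndi.grey_dilation(img, footprint=se)
    ero = ndi.grey_erosion(img, footprint=se)
    return dil - ero


def _smooth_by_reconstruction(img: np.ndarray, radius: int) -> np.ndarray:
    """Opening-by-reconstruction then closing-by-reconstruction.

    Flattens texture inside bright/dark structures while preserving their
    boundaries, so that h-maxima mark whole structures rather than noise peaks.
    """
    if radius < 1:
        return img
    se = disk_se(radius)
    eroded = ndi.grey_erosion(img, footprint=se)
    opened = reconstruction(eroded, img, method="dilation")
    dilated = ndi.grey_dilation(opened, footprint=se)
    closed = reconstruction(dilated, opened, method="erosion")
    return closed


def extract_internal_markers(
    slice_img: SliceImage, params: SegmentationParams
) -> np.ndarray:
    """Connected marker components inside locally bright, homogeneous areas.

    Smooths the slice by opening/closing by reconstruction, takes the h-maxima
    of the smoothed image (h = ``h_fraction`` of the slice dynamic range), and
    removes components smaller than the area threshold.  May return an empty
    mask (e.g. on constant slices) — a valid outcome.
    """
    img = np.asarray(slice_img.pixels, dtype=float)
    lo, hi = float(img.min()), float(img.max())
    if hi <= lo:
        return np.zeros(img.shape, dtype=bool)
    smoothed = _smooth_by_reconstruction(img, params.smooth_radius_px)
    h = params.h_fraction * (hi - lo)
    markers = h_maxima(smoothed, h, footprint=_S8).astype(bool)
    min_area_px = max(1, int(round(params.min_area_mm2 / slice_img.pixel_area_mm2)))
    lbl, n = ndi.label(markers, structure=_S8)
    if n:
        counts = np.bincount(lbl.ravel())
        small = np.flatnonzero(counts < min_area_px)
        markers[np.isin(lbl, small[small > 0])] = False
    return markers


def extract_external_markers(
    internal: np.ndarray, shape: Optional[Tuple[int, int]] = None
) -> np.ndarray:
    """Deepest valley lines surrounding every internal marker.

    Ridge lines of the watershed of the distance-from-internal-markers map
    (equivalently, of the inverted nearest-marker relief): every pair of
    internal components is separated by an external line.  With fewer than two
    internal components the image border frame is returned instead, which
    pins the background basin.  Always disjoint from ``internal``.
    """
    internal = np.asarray(internal, dtype=bool)
    if shape is None:
        shape = internal.shape
    lbl, n = ndi.label(internal, structure=_S8)
    external = np.zeros(shape, dtype=bool)
    if n < 2:
        external[0, :] = external[-1, :] = True
        external[:, 0] = external[:, -1] = True
        external &= ~internal
        return external
    edt = ndi.distance_transform_edt(~internal)
    flooded = flood_watershed(edt, lbl)
    external = (flooded == WSHED) & ~internal
    return external


def impose_minima(gradient: np.ndarray, markers: np.ndarray) -> np.ndarray:
    """Force the regional minima of ``gradient`` to coincide with ``markers``.

    Standard reconstruction-by-erosion minima imposition: after it, the
    regional minima of the output are exactly the marker components and
    nowhere else.  Idempotent.  Raises :class:`EmptyMarkerError` on an empty
    marker mask (the subsequent watershed would be unseeded).
    """
    gradient = np.asarray(gradient, dtype=float)
    markers = np.asarray(markers, dtype=bool)
    if gradient.shape != markers.shape:
        raise ValueError("gradient and marker shapes differ")
    if not markers.any():
        raise EmptyMarkerError("cannot impose minima from an empty marker mask")
    if markers.all():
        return np.full(gradient.shape, float(gradient.min()))
    lo, hi = float(gradient.min()), float(gradient.max())
    rng = hi - lo if hi > lo else 1.0
    low_val = lo - rng - 1.0
    big = hi + 1.0
    seed = np.where(markers, low_val, big)
    mask_img = np.minimum(gradient, seed)
    out = reconstruction(seed, mask_img, method="erosion")
    # canonical marker depth: one unit below the off-marker relief, which
    # makes the operation exactly idempotent
    out[markers] = out[~markers].min() - 1.0
    return out


def flood_watershed(image: np.ndarray, markers: np.ndarray) -> np.ndarray:
    """Marker-seeded watershed flooding with deterministic tie-breaking.

    ``markers`` is an integer label image (0 = unlabeled, >0 = seeds).  Pixels
    are assigned in increasing (gray value, row, col) order; a pixel whose
    already-assigned 4-neighbours carry a single basin label joins that basin,
    otherwise it becomes a watershed-line pixel (label ``WSHED`` = -1).  The
    result is a partition: every reachable pixel is exactly one of seed,
    basin member, or watershed line.
    """
    img = np.asarray(image, dtype=float)
    out = np.asarray(markers).astype(np.int64).copy()
    if img.shape != out.shape:
        raise ValueError("image and marker shapes differ")
    h, w = img.shape
    pushed = out > 0
    heap: list = []
    for r, c in np.argwhere(out > 0):
        for dr, dc in _N4:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and not pushed[rr, cc]:
                pushed[rr, cc] = True
                heapq.heappush(heap, (img[rr, cc], rr, cc))
    while heap:
        _, r, c = heapq.heappop(heap)
        labels = set()
        for dr, dc in _N4:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w:
                l = out[rr, cc]
                if l > 0:
                    labels.add(l)
        out[r, c] = labels.pop() if len(labels) == 1 else WSHED
        for dr, dc in _N4:
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and not pushed[rr, cc]:
                pushed[rr, cc] = True
                heapq.heappush(heap, (float(img[rr, cc]), int(rr), int(cc)))
    return out


def _region_from_mask(mask: np.ndarray, slice_img: SliceImage) -> Region2D:
    pix = np.argwhere(mask)
    return Region2D(
        pixels=pix,
        intensities=np.asarray(slice_img.pixels, dtype=float)[pix[:, 0], pix[:, 1]],
        plane=slice_img.plane,
        slice_index=slice_img.index,
        slice_dynamic_range=slice_img.dynamic_range,
        contour=trace_contour(mask),
    )


def watershed_segment(
    modified_gradient: np.ndarray, markers: MarkerSet, slice_img: SliceImage
) -> List[Region2D]:
    """Grow basins on the marker-modified gradient and keep candidates.

    Basins grown from internal marker components become candidate regions
    (label ``unlabeled``); basins grown from external markers and basins that
    touch the image border are dropped as background.  Returned regions are
    pairwise disjoint.
    """
    if not markers.combined.any():
        raise EmptyMarkerError("watershed requires a nonempty combined marker set")
    lbl_int, n_int = ndi.label(markers.internal, structure=_S8)
    seeds = lbl_int.astype(np.int64)
    ext_label = n_int + 1
    seeds[markers.external & (seeds == 0)] = ext_label
    flooded = flood_watershed(modified_gradient, seeds)
    regions: List[Region2D] = []
    for l in range(1, n_int + 1):
        mask = flooded == l
        if not mask.any():
            continue
        if mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any():
            continue  # border-touching basins are background
        regions.append(_region_from_mask(mask, slice_img))
    return regions


def segment_slice(
    slice_img: SliceImage, params: Optional[SegmentationParams] = None
) -> List[Region2D]:
    """Full per-slice chain: gradient → markers → imposition → flooding.

    Returns an empty list when no internal markers are found (typical for
    far-lateral slices where structures are too small) — not an error.
    Deterministic.
    """
    if params is None:
        params = SegmentationParams()
    internal = extract_internal_markers(slice_img, params)
    if not internal.any():
        return []
    external = extract_external_markers(internal)
    markers = MarkerSet(internal=internal, external=external)
    gradient = morphological_gradient(slice_img, params.se_radius_px)
    imposed = impose_minima(gradient, markers.combined)
    return watershed_segment(imposed, markers, slice_img)
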
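"""Texture features of candidate regions.

Eight descriptors per region: four histogram-statistical features of the
member-pixel intensities (mean, standard deviation, skewness, Shannon
entropy) and four spectral features of the polar-aggregated 2D Fourier
energy spectrum of the region patch (the angle at which the angular spectrum
S(θ) is maximal, its value, the variance of S(θ), and S(θ)max − S(θ)mean).

The spectral features describe the orientation and frequency content of the
intensity variation *inside* the region: the patch is cropped to the region
bounding box (making the features translation-invariant within the slice),
pixels outside the region are filled with the region mean so the silhouette
does not dominate the spectrum, the patch mean is subtracted, and the patch
is zero-padded to a square before the FFT.  The DC component (radius 0) is
excluded; angle bins cover [0°, 180°) — conjugate-symmetric frequency pairs
fall in the same bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Tuple

import numpy as np

from .volume import Region2D

FEATURE_NAMES = (
    "hist_mean",
    "hist_std",
    "hist_skewness",
    "hist_entropy",
    "theta_max_deg",
    "s_max",
    "s_var",
    "s_max_minus_mean",
)


@dataclass(frozen=True)
class FeatureVector:
    hist_mean: float
    hist_std: float
    hist_skewness: float
    hist_entropy: float
    theta_max_deg: float
    s_max: float
    s_var: float
    s_max_minus_mean: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)


@dataclass
class SpectralConfig:
    """Resolution of the spectral features (all config keys).

    ``energy=True`` uses |F|^2 (energy spectrum); ``False`` uses |F|.
    """

    pad_to: int = 64
    angle_bin_deg: float = 5.0
    energy: bool = True
    min_bbox: int = 8


def statistical_features(
    region: Region2D, hist_bins: int = 32
) -> Tuple[float, float, float, float]:
    """Population moments and histogram entropy of region intensities.

    Skewness is the third standardized moment, defined as 0 for constant
    regions.  Entropy is the base-2 Shannon entropy of the intensity
    histogram with ``hist_bins`` equal-width bins spanning the owning slice's
    dynamic range.
    """
    x = region.intensities
    mean = float(x.mean())
    std = float(x.std())  # population
    if std > 0:
        skew = float(np.mean(((x - mean) / std) ** 3))
    else:
        skew = 0.0
    lo, hi = region.slice_dynamic_range
    if hi <= lo:
        entropy = 0.0
    else:
        counts, _ = np.histogram(x, bins=hist_bins, range=(lo, hi))
        p = counts[counts > 0] / counts.sum()
        entropy = float(-(p * np.log2(p)).sum())
    return mean, std, skew, entropy


def _region_patch(region: Region2D) -> np.ndarray:
    rmin, cmin, rmax, cmax = region.bounding_box()
    h, w = rmax - rmin + 1, cmax - cmin + 1
    mean = region.mean_intensity
    patch = np.full((h, w), mean, dtype=float)
    patch[region.pixels[:, 0] - rmin, region.pixels[:, 1] - cmin] = region.intensities
    return patch - mean


def angular_spectrum(patch: np.ndarray, config: SpectralConfig) -> np.ndarray:
    """S(θ): the Fourier spectrum summed over radius per angle bin.

    ``patch`` must already be mean-subtracted.  Returns one value per
    ``angle_bin_deg``-wide bin covering [0°, 180°).
    """
    size = max(config.pad_to, *patch.shape)
    spec = np.fft.fftshift(np.fft.fft2(patch, s=(size, size)))
    mag = np.abs(spec)
    s = mag**2 if config.energy else mag
    center = size // 2
    iy, ix = np.indices((size, size))
    fy = iy - center  # frequency along patch rows
    fx = ix - center  # frequency along patch columns
    r = np.hypot(fy, fx)
    theta = np.degrees(np.arctan2(fy, fx)) % 180.0
    n_bins = int(round(180.0 / config.angle_bin_deg))
    bins = np.minimum((theta / config.angle_bin_deg).astype(int), n_bins - 1)
    keep = r >= 1.0  # exclude DC
    return np.bincount(bins[keep], weights=s[keep], minlength=n_bins)


def spectral_features(
    region: Region2D, config: SpectralConfig | None = None
) -> Tuple[float, float, float, float]:
    """(θmax, S(θ)max, var S(θ), S(θ)max − S(θ)mean) of the region patch.

    Regions whose bounding box is smaller than ``min_bbox`` in either
    dimension, and regions with an all-zero spectrum (constant intensity),
    get (0, 0, 0, 0).  Ties in the arg-max angle resolve to the smallest
    angle.  θmax reports the centre of the winning bin.
    """
    if config is None:
        config = SpectralConfig()
    rmin, cmin, rmax, cmax = region.bounding_box()
    if (rmax - rmin + 1) < config.min_bbox or (cmax - cmin + 1) < config.min_bbox:
        return 0.0, 0.0, 0.0, 0.0
    patch = _region_patch(region)
    s_theta = angular_spectrum(patch, config)
    if not np.any(s_theta > 0):
        return 0.0, 0.0, 0.0, 0.0
    imax = int(np.argmax(s_theta))  # first (smallest-angle) maximum on ties
    theta_max = (imax + 0.5) * config.angle_bin_deg
    s_max = float(s_theta[imax])
    return theta_max, s_max, float(s_theta.var()), float(s_max - s_theta.mean())


def compute_features(
    region: Region2D,
    hist_bins: int = 32,
    spectral_config: SpectralConfig | None = None,
) -> FeatureVector:
    """Compute all eight features and attach them to the region."""
    mean, std, skew, entropy = statistical_features(region, hist_bins)
    tmax, smax, svar, smm = spectral_features(region, spectral_config)
    fv = FeatureVector(mean, std, skew, entropy, tmax, smax, svar, smm)
    region.features = fv
    return fv


def feature_matrix(regions: Iterable[Region2D]) -> np.ndarray:
    rows: List[np.ndarray] = []
    for r in regions:
        if r.features is None:
            raise ValueError("region has no computed features")
        rows.append(r.features.as_array())
    return np.vstack(rows) if rows else np.empty((0, len(FEATURE_NAMES)))
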
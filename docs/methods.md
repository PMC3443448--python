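# Methods

This note records the models, parameter choices and numerical conventions
behind `diskseg`, and what the synthetic-phantom experiments do and do not
demonstrate.

## Segmentation model

The pipeline assumes short-TE spine MR contrast: intervertebral disks
brighter than vertebral bodies, both brighter than background, with no
annulus/nucleus distinction required.  Segmentation is strictly per slice
(2D watershed); three-dimensionality enters only when per-slice masks are
stacked and fused.

**Morphological gradient.** Grey dilation minus erosion with a disk
structuring element (`se_radius_px`, default 1 px).  Nonnegative, and
invariant to additive intensity shifts, so absolute scanner scaling is
irrelevant.

**Internal markers.** The slice is smoothed by opening-by-reconstruction
followed by closing-by-reconstruction (disk SE, `smooth_radius_px`, default
2 px), which levels texture inside structures while preserving their
boundaries.  The h-maxima of the smoothed slice are taken with
h = `h_fraction` × slice dynamic range (default 0.10), and components
smaller than `min_area_mm2` (default 30 mm², converted by pixel area) are
removed.  An empty marker set is a valid outcome (constant or structure-free
slices) and the slice simply yields no candidates.

**External markers.** Watershed ridge lines of the distance-from-markers
relief: every pair of internal components is separated; with fewer than two
internal components the image border frame is used.  This pins the
background basin cheaply and guarantees candidates cannot leak to the
border.

**Minima imposition and flooding.** The combined markers are imposed as the
only regional minima of the gradient by reconstruction-by-erosion; the
marker depth is canonicalized one unit below the off-marker relief, making
the operation exactly idempotent.  Flooding uses 4-connectivity for basins
(8-connectivity for marker components) and a fully ordered priority
(gray value, row, col): gray-level ties resolve in raster-scan order, so
results are bit-for-bit reproducible and an independent frontier-scan
implementation must — and in the tests does — produce identical basins.
Border-touching basins are always discarded as background.  Over-segmentation
is expected; the classifier removes it.

## Classification model

Eight features per region.  Histogram statistics (population mean, std,
third standardized moment — defined 0 for constant regions — and base-2
Shannon entropy over 32 equal-width bins spanning the slice dynamic range;
`hist_bins` is a config key).  Spectral features come from the 2D Fourier
energy spectrum |F|² (config flag for |F|) of the mean-subtracted region
patch: the patch is cropped to the bounding box (translation invariance),
pixels outside the region are filled with the region mean so the silhouette
does not dominate, and the patch is zero-padded to at least 64×64.  S(θ)
aggregates the spectrum over radius ≥ 1 (DC excluded) in 5° bins over
[0°, 180°); the features are the arg-max bin centre θ_max (smallest angle on
ties), S(θ)_max, var S(θ), and S(θ)_max − S(θ)_mean.  Regions with a
bounding box under 8×8 px get an all-zero spectral vector.

The k-NN classifier (default k = 5, odd so votes cannot tie; Euclidean
distance in z-standardized feature space; distance ties broken by
training-row order) labels **sagittal** regions only — coronal regions are
matched later by anatomy, which is far cheaper than classifying them.

Training data are produced the way such data would be made in practice:
rendered slices are watershed-segmented and candidates are labeled against
the ground truth (2D Dice ≥ 0.5 → disk; zero overlap → background).  This
keeps the training distribution aligned with the candidate regions the
classifier actually sees; training on idealized truth cross-sections instead
produces a domain shift (candidates are basin-shaped, slightly eroded, with
narrower histograms) and sporadic misclassifications.  The default model
pools 150 regions per class from three phantom renderings with distinct
noise seeds.

## Fusion model

All fusion happens on a common isotropic lattice (`iso_mm`, default 1 mm);
the intensity volume is resampled by trilinear interpolation (slice pitch
along `lr` is honoured for gapped spin-echo-style acquisitions), binary
masks by nearest neighbour.

The classified sagittal masks are stacked, single-slice dropouts are bridged
(a voxel missing on one slice but present on both neighbours is filled —
two-slice gaps are genuine holes and stay open), and 26-connected components
≥ `min_voxels` (default 30) become reference disk volumes D_ref.

Coronal candidate volumes are built by *region continuity*: regions on
adjacent coronal slices are joined when their overlap covers ≥ 50% of the
larger region.  Plain 26-connected stacking is kept for the sagittal path
(and exposed as `build_disk_volumes`), but is too permissive for the
unclassified coronal plane: a vertebral fragment or a taper-end ghost
touching a disk band through a blurred interface would chain onto it and
drag the fused Dice below the sagittal-only value.  Genuine cross-sections
change size gradually between neighbouring slices, so true chains link
comfortably at the 50% threshold (config key).

Each coronal volume joins the reference volume with the nearest centroid if
the distance is ≤ `max_dist_mm` (default 10 mm — about half a vertebral-body
height, so vertebral components, whose centroids sit a half-pitch away,
cannot attach); otherwise it is background.  Equidistant candidates join the
lower disk index.  The fused volume is the plain voxel union
D = D_ref ∪ (assigned D_cor), so |D| ≥ |D_ref| always.

## Evaluation conventions

* DSC is undefined (error) for two empty sets; per-slice DSC skips slices
  empty in both masks and scores 0 where exactly one is empty.  The
  voxel-weighted mean of per-slice DSC equals the 3D DSC (checked in tests).
* Mid/lateral partition: ⌈0.10·n⌉ slices per side are lateral, the rest
  mid-sagittal.  This rule reproduces all 27 published (mid, lateral) count
  pairs the package's tests freeze.
* Volume discrepancy is (|auto| − |manual|)/|manual|; negative means
  under-estimation, which surgeons read as a safety margin.
* Canal boundary distance: on each listed sagittal slice, manual
  posterior-facing boundary pixels within the posterior 25% of the disk's
  ap extent (`posterior_band_fraction`) are matched to the nearest automatic
  boundary pixel in mm.  Direction is manual→automatic (not symmetric or
  Hausdorff) because the quantity of interest is how far the automatic
  boundary retreats from the canal.  Pooled std is population; across-disk
  variability tables report both population and sample std.

## Robustness design

`generate_design(M=3, k=4, p=2, blocks=3)` builds the 3^(4−2) fraction from
a full 3² base factorial with GF(3) generator columns (f₃ = a+b,
f₄ = a+2b mod 3), replicates it across blocks and randomizes run order
within blocks by seed.  With this aliasing, all eight orthogonal-polynomial
main-effect contrasts (linear x and quadratic 3x²−2 per factor, the `*`
naming convention marking quadratics) plus the block dummies are estimable;
every two-factor interaction contrast is aliased with main effects, and the
fit reports them as such instead of silently including them.  Effects are
estimated by OLS; the standardized effect (t value) drives the Pareto
ranking.  The exact published 27-run layout came from a proprietary design
package and is not derivable from stated rules, so the module guarantees
the defining properties (run count, balance, blocking, estimability) and
additionally accepts an externally supplied design CSV for direct analysis.

## The phantom: what it emulates, and what it does not

The phantom renders ellipsoidal disks (default semi-axes 12×14×4 mm in
ap×lr×si) perpendicular to a spine centreline that bends as a single
circular arc in the coronal plane; the end-tangent angle difference equals
`cobb_like_angle_deg`, matching the clinical Cobb notion without vertebral
rotation.  Vertebral bodies are larger, darker ellipsoids between the disks.
Intensities (background 0.15, vertebra 0.45, disk 0.85 on an arbitrary
scale) are blurred by an isotropic Gaussian PSF (`blur_sigma_mm`, default
0.8 mm) and degraded by additive Gaussian noise whose σ is
`noise_sigma` × the disk/background contrast.  Presets: `medic` 1 mm
isotropic; `spin_echo` 2 mm slices with 0.4 mm gap along `lr` (2.4 mm
pitch) and 0.7 mm in plane, with an optional bright-nucleus artifact
(nucleus rendered above the annulus, the failure mode that misleads
boundary detection); `fisp` 1 mm isotropic with additionally blurred disk
boundaries.  Ground-truth masks are the noise-free voxelized ellipsoids
before blur.  Default problem size: a 56×44×144 mm field of view, five
disks, 30° curve, noise 0.05 — small enough that the full pipeline runs in
seconds on one CPU while leaving every stage nontrivial.

Not emulated: MR physics (TR/TE, k-space, Rician noise — additive Gaussian
is used since the pipeline only consumes magnitude-like contrast), vertebral
rotation and wedging, double curves, annulus/nucleus substructure (except
the bright-nucleus artifact), and real tissue texture.  Passing the phantom
tests therefore shows the pipeline's mechanics are correct under the
contrast structure it assumes — it does not certify clinical accuracy,
which requires validation against expert manual segmentations.

## Known limitations

* The internal/external marker recipe reconstructs a published intent whose
  operator-level details live in prior work; all its constants are config
  keys rather than fitted values.
* Whether the angular spectrum should use |F| or |F|² is genuinely open;
  energy (|F|²) is the default, a config flag switches to amplitude.
* The pure-Python flooding favours determinism and oracle-checkability over
  speed; ~10⁶-pixel volumes segment in seconds, but very large volumes
  would benefit from a compiled queue.
* Coronal candidates are filtered only by area/border/continuity rules;
  a pathological volume whose background mimics disk bands within 10 mm of
  a disk centroid could still fuse incorrectly.
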
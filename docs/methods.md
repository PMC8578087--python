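# Methods

## The problem

Cross-modality imaging of tumor vasculature acquires the same specimen with
modalities that trade penetration against resolution: whole-animal microMRI
resolves vessels down to roughly 100 μm diameter, contrast-perfused ex vivo
microCT reaches ~20 μm at a 10 μm grid, photoacoustic tomography resolves
capillaries but only within ~3 mm of the surface, and HREM delivers ~3 μm
sections at the cost of destructive resin embedding that deforms the tissue.
Comparing or fusing these datasets requires vessel segmentation, a common
reference space, and structural statistics that are meaningful across
resolutions. vasculink implements that pipeline and validates it on
synthetic vasculature with exact ground truth.

## Coordinate and format conventions

All volumes are axis-aligned grids with identity orientation; voxel
coordinates refer to voxel *centers*, the physical position of index
(i, j, k) being `origin + (i·sx, j·sy, k·sz)` mm. The interchange format is
uncompressed MetaImage (`.mhd` + `.raw`, x fastest on disk); binary masks
are serialized 8-bit with foreground 255. TIFF carries no spacing, so
spacing must always be supplied — the readers refuse to guess physical
units. Scalar data handed between stages is quantized to 8-bit with a
linear [lo, hi] → [0, 255] map, rounding half-away-from-zero. Whether
legacy exports treated the Offset as a voxel center or corner is not
standardized across tools; vasculink uses centers throughout, which users
comparing against external exports should keep in mind. Affine transforms
ride along in `.mhd` headers as `TransformMatrix` (9 values, row-major) and
`Offset` (3 values); when a transform is attached to a volume it occupies
those geometry fields, matching how interactive registration tools persist
alignments.

## Phantom model

The generator grows a recursive bifurcation tree: from a root of radius
`root_radius_mm` entering the domain face, each segment walks ~0.1 mm steps
with Gaussian angular jitter (`tortuosity_deg`, default 6°), reflecting off
the domain walls, then splits into `branching_factor` children tilted by
`branch_angle_deg` (default 35°) at evenly spread azimuths. Child radii obey
Murray's law `r_parent^m = Σ r_child^m` with exponent `m = radius_rule`
(default 3), the classic minimum-work result for vascular branching; equal
children therefore shrink by `b^(-1/m)` per generation. An optional
`prune_tip_fraction` removes random terminal segments to emulate blindly
ending vessels seen in real tumor vasculature. The model is deliberately
the simplest one that exposes the behaviors the downstream pipeline must
handle — multiscale radii, branch points, tortuosity, blind ends — and makes
no hemodynamic or biological claims.

Rasterization marks voxel centers inside flat-ended tapered tubes around
each polyline edge (flat ends keep the voxel count consistent with the
frustum-sum analytic volume; consecutive edges cover each other's joints),
with an optional fractional mode that supersamples each voxel to capture
partial-volume occupancy of sub-voxel vessels.

## Modality emulation

`simulate_modality` is phenomenological, not physical: (1) optional smooth
nonlinear deformation, (2) Gaussian blur at the profile's PSF FWHM,
(3) linear resampling to the modality grid, (4) additive Gaussian noise as
a fraction of the vessel/background contrast, (5) exponential depth
attenuation beyond `max_depth_mm` (e-folding 0.5 mm, floor 10⁻³). Vessel
visibility limits are *emergent*: a vessel much thinner than the PSF and
voxel dilutes below the noise floor, so the MRI-like profile
(FWHM 0.12 mm, noise 0.05) censors sub-100-μm-diameter vessels without any
explicit cut; each profile's `min_detectable_radius_mm` documents the
expected limit and is verified by tests rather than enforced on the data.
The deformation field is Gaussian-smoothed white noise rescaled so its
*maximum* displacement equals the stated amplitude, guaranteeing the bound
used by the deformation property test. Image warping uses the pull-back
approximation `out(x) = in(x − u(x))`, consistent with the push of
centerline points `x → x + u(x)` to first order in the field's gradient —
adequate for the smooth, large-scale distortions emulated here. Speckle
and Rician noise are left as profile extensions; MR k-space and CT
projection physics are out of scope.

Default HREM deformation amplitude is 1 mm, reflecting the millimeter-scale
distortions reported for resin-sectioned samples; the bundled
co-registration study scales it to 0.5 mm on its ~4.4 mm phantom domain so
the deformation stays well inside the volume.

## Segmentation

Per-modality masks come from intensity thresholding — Otsu on the full
256-bin volume histogram, or a fixed value — with foreground strictly above
the threshold, followed by binary closing (ball structuring element) and
removal of 26-connected components below a size floor. 26-connectivity is
used throughout as the permissive choice that preserves thin diagonal
vessels. Interactive manual correction is replaced by an
accept-external-mask pathway: any mask file can be substituted at any
stage. Default thresholds are configuration entries, not constants, since
usable values are modality- and acquisition-specific.

OCTA angiograms are the pixel-wise mean absolute difference over
consecutive B-scan pairs (signed and squared variants available),
Gaussian-smoothed, with values at or below the threshold zeroed. The
statistic is zero exactly when the series is temporally constant.

## Skeletonization and morphometry

Masks are thinned to one-voxel centerlines (Lee et al. 1994 topological
thinning via scikit-image). Skeleton voxels with ≠ 2 neighbors under
26-connectivity become graph nodes; adjacent node voxels merge into one
node at their centroid; degree-2 chains become polyline segments in mm. A
*segment* is a maximal branch between branch points and/or endpoints — note
that segment counts are inherently software-dependent (automated
segmentation fragments vessels differently than manual tracing), so
cross-modality comparisons should lean on the ratio and average parameters.

Thinning of thick digital tubes produces two artifact classes that the
graph-simplification pass removes before statistics: (1) *fishtails* — a
tube end thinned into two near-parallel arms; detected as two terminal
spurs at one junction whose mean separation is below 1.25× the local vessel
radius (from the mask's Euclidean distance transform), keeping the longer
arm; (2) *spurs* — short terminal twigs; pruned when shorter than 2 voxels
or 2× the local radius, shortest first, never reducing a junction below
degree 2, with pass-through chains re-merged afterwards. Both factors are
exposed as parameters of `skeletonize`. The thresholds are geometric (in
units of local radius), so behavior is resolution-independent; on noiseless
phantom trees the recovered segment count is exact.

Reported parameters: vessel volume = foreground count × voxel volume;
perfusion volume = 100 · vessel/tumor volume (tumor from a co-registered
mask or a declared VOI volume in mm³); lengths are polyline arc lengths.
Reports round to 2 decimals for display; raw values are retained.

## Registration

Affine transforms map reference-space physical points to moving-space
points (pull convention), which is what resampling consumes directly: the
output voxel at reference point x samples the input at T(x). The fit
minimizes Σ‖A·p_fixed + t − p_moving‖² by least squares on the (N×4)
design matrix; fewer than 4 pairs, or a condition number above 10⁸
(coplanar or coincident fixed points), raises a descriptive error instead
of returning a garbage fit. "Affine" is taken literally (shear included);
landmark files are plain CSV `label,fx,fy,fz,mx,my,mz` in mm, and a
phantom helper pairs ground-truth branch nodes by id, with optional
Gaussian jitter emulating manual placement. Mask resampling is
nearest-neighbor only (binarity preserved by construction); the reference
grid defaults to the coarsest common CT-like grid, the usual trade-off
between data size and detail.

Quality is quantified as landmark RMS and centerline deviation: each
densified point of one centerline graph is matched to its nearest point on
the other (k-d tree), summarized as mean/median/max. Under smooth nonlinear
distortion an affine can match well locally while failing globally;
`local_window_deviation` reports the best mean over 1 mm³ windows
(≥ 10 samples) to quantify that contrast. Non-rigid registration is out of
scope.

## Rendering

Grouped MIP reduces the volume to maxima over consecutive `group_size`
slices (default 5; a trailing partial group is kept). Each channel's slices
are scaled by a linear ramp `w_k = start + (end − start)·k/(n−1)` — red
0.75→1.0, green 0→0.75 by default; a single slice takes the end value —
and a final per-channel MIP yields the RGB image, normalized by its global
maximum before 8-bit export. The projection axis defaults to z and is
configurable. Mask fusion assigns each co-registered mask a channel at
full intensity; overlap is additive per channel (red+green renders
yellow).

## Pipeline and reproducibility

A run is fully specified by (config, seed). The global seed fans out per
stage as `crc32("{seed}:{stage}") mod 2³¹`, so stages are independently
reproducible. Each non-reference modality receives a small random rigid
pose (≤ 8°, ≤ 0.4 mm) to make registration non-trivial; the moving-frame
truth is the phantom resampled through that pose, landmarks are the true
branch points (optionally jittered), and alignment quality is measured
between the reference truth centerline and the moving truth centerline
mapped back through the *fitted* transform — isolating registration error
from segmentation discrepancy. The per-modality tumor reference is an
ellipsoid inscribed in the domain, rasterized on each modality's grid.
Masks, reports, transforms and rendered images are byte-identical across
reruns; only the manifest's timestamps vary.

## Problem sizes used in validation

The bundled studies run on deliberately modest grids: the co-registration
study uses a 4.4 mm domain at the 34.4 μm CT reference (~128³) with the
truth rasterized at 20 μm; segmentation accuracy uses 3 mm domains (~87³ at
CT resolution); the cylinder-volume oracle uses 10 μm and 5 μm grids. These
sizes keep the full validation suite in the minutes range while exercising
every code path at realistic voxel-to-vessel ratios.

## Known limitations

- The phantom is geometric, not hemodynamic; intensity statistics of real
  acquisitions (speckle, Rician noise, contrast-agent heterogeneity,
  motion) are not reproduced, so passing tests demonstrate algorithmic
  correctness on idealized inputs, not segmentation performance on real
  tumors.
- The deformation model is a single smooth random field; real HREM
  distortion accumulates per section and can be discontinuous at tears.
- Segment counts depend on the skeletonization and its artifact thresholds;
  only ratio/average parameters should be compared across tools.
- Registration is affine-only by design; residual nonlinear deformation is
  reported, not corrected.
- DICOM and vendor-native formats are not read; data must be exported to
  MetaImage/NIfTI/TIFF first.
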
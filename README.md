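# vasculink

A toolkit for cross-modality imaging (CMI) of tumor vasculature: the same
specimen is imaged sequentially with complementary modalities — in vivo
microMRI and photoacoustics, ex vivo contrast-perfused microCT, and
high-resolution episcopic microscopy (HREM) — and the resulting vessel
networks are segmented, co-registered into one reference space, quantified,
and rendered together. vasculink implements that computational pipeline as a
reusable Python library with a thin command-line layer, and pairs it with a
ground-truthed synthetic vascular phantom generator so every stage can be
validated without animal data.

It is aimed at preclinical imaging scientists and image-analysis developers
who need a reproducible, open-format (MetaImage/NIfTI/TIFF/CSV/PNG) pipeline
for multiscale vascular data — and a test bed that knows the right answer.

## What it computes

- **Phantoms** (`vasculink.phantom`): recursive bifurcating vascular trees.
  Child radii follow Murray's law, `r_parent^m = Σ r_child^m` (default
  m = 3, so two equal children give `r_child/r_parent = 2^(-1/3) ≈ 0.794`).
  Trees are rasterized to binary or partial-volume masks and degraded into
  modality-specific acquisitions (PSF blur, grid resampling, noise, depth
  attenuation, smooth nonlinear deformation), with presets for MRI-like
  (60×60×200 μm, ~100 μm detectability), CT-like (34.4 μm), HREM-like
  (~3 μm + sectioning distortion), PAT-like (~3 mm penetration) profiles.
- **Segmentation** (`vasculink.segmentation`): per-modality intensity
  thresholding (Otsu or fixed) plus binary morphological cleanup, and OCT
  angiography as the mean absolute difference of consecutive B-scans
  (static tissue cancels, moving blood survives).
- **Morphometry** (`vasculink.morphometry`): skeleton-based structural
  parameters per (modality, tumor) pair — tumor volume, vessel volume,
  perfusion volume (100 · V_vessel / V_tumor, in %), total vessel length,
  segment count, longest and mean segment length.
- **Registration** (`vasculink.registration`): pairwise affine
  landmark-based co-registration into the CT-resolution reference space
  (least squares over corresponding vessel branch points), resampling,
  transform persistence in `.mhd` headers, and quality metrics (landmark
  RMS, centerline deviation, local-vs-global deviation under nonlinear
  distortion).
- **Rendering** (`vasculink.rendering`): depth-cued maximum intensity
  projections (grouped 5-slice MIPs, red channel ramped 75%→100% and green
  0%→75% with depth, so hue encodes vessel depth) and RGB fusion of
  co-registered masks.
- **Pipeline** (`vasculink.pipeline`): one seeded, configured run of
  phantom → acquire → segment → register → quantify → render, fully
  reproducible byte-for-byte.

## Worked example

```bash
python examples/04_landmark_registration.py
```

```
landmarks used:        16
landmark RMS residual: 0.0241 mm
centerline deviation:  mean 0.0116 mm, max 0.0239 mm
-> deviations well below the 0.0344 mm reference voxel mean the affine
   registration is sub-voxel accurate despite landmark jitter.
```

A phantom tree was moved by a known rigid pose; its branch points (with
17 μm of simulated manual-clicking jitter) were used as landmarks. The
fitted affine brings the moving centerline back onto the reference with a
mean error of 12 μm — a third of a CT-resolution voxel — which is the
pipeline's core guarantee: what the landmarks can see, the affine recovers.

The other examples each demonstrate one capability and print what the
numbers mean: phantom morphometry (`01`), modality censoring (`02`), OCTA
contrast (`03`), depth-cued rendering (`05`), and the full pipeline with its
parameters-by-modality table (`06`). The same operations are available from
the shell:

```bash
vasculink phantom --seed 3 --generations 2 --spacing 0.04 phantom.mhd
vasculink segment --method otsu --min-size 10 --closing 1 in.mhd mask.mhd
vasculink register --fixed ct.mhd --moving mri.mhd --landmarks lm.csv -o aligned.mhd
vasculink render mip --group 5 --red 0.75:1.0 --green 0.0:0.75 ct.mhd mip.png
vasculink run --config run.yaml
```

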
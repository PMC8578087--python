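"""Simulate MRI-like and CT-like acquisitions of one phantom and segment both.

Finer modalities recover more of the vascular tree: the MRI-like profile
(60x60x200 um voxels, ~100 um detectability limit) censors thin branches
that the CT-like profile (34.4 um isotropic) still resolves.
"""

import numpy as np

from vasculink import (
    ImageVolume,
    PhantomSpec,
    compute_report,
    ct_like,
    generate_vessel_tree,
    morphological_cleanup,
    mri_like,
    rasterize_tree,
    simulate_modality,
    threshold_segment,
)

spec = PhantomSpec(domain_size_mm=(3.0, 3.0, 3.0), root_radius_mm=0.2,
                   generations=3, segment_length_range_mm=(0.5, 0.8), seed=4)
tree = generate_vessel_tree(spec)
fine = ImageVolume(np.zeros((150, 150, 150), np.uint8), (0.02,) * 3)
truth = rasterize_tree(tree, fine, fractional=True, supersample=2)

for profile in (ct_like(), mri_like()):
    image = simulate_modality(truth, profile, seed=1)
    mask = morphological_cleanup(threshold_segment(image, "otsu"),
                                 min_component_voxels=10, closing_radius_voxels=1)
    rep = compute_report(mask, tumor=27.0)
    print(f"{profile.name:>9}: {rep.n_segments:3d} segments, "
          f"total length {rep.total_vessel_length_mm:6.2f} mm, "
          f"vessel volume {rep.vessel_volume_mm3:.3f} mm^3")
print(f"ground truth: {tree.n_segments:3d} segments, "
      f"total length {tree.total_length_mm():6.2f} mm")
print("-> the CT-like column sees more segments and length than the MRI-like")
print("   one: resolution censoring, not biology, drives such differences.")
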
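"""Run the whole pipeline: phantom -> acquire -> segment -> register -> report.

One seeded run produces per-modality masks, transforms, aligned masks in the
CT-resolution reference space, a parameters-by-modality CSV, registration
quality metrics, and rendered QC images.  Re-running with the same seed
reproduces every mask and report byte for byte.
"""

import json

import pandas as pd

from vasculink import PhantomSpec, ct_like, mri_like
from vasculink.pipeline import ModalityConfig, PipelineConfig, run_pipeline

config = PipelineConfig(
    phantom=PhantomSpec(
        domain_size_mm=(2.5, 2.5, 2.5),
        root_radius_mm=0.18,
        generations=2,
        segment_length_range_mm=(0.5, 0.8),
    ),
    modalities=[
        ModalityConfig("ct_like", ct_like()),
        ModalityConfig("mri_like", mri_like()),
    ],
    reference="ct_like",
    truth_spacing_mm=0.02,
    landmark_jitter_mm=0.017,  # emulate half-voxel manual landmark error
    output_dir="pipeline_run",
    seed=7,
)
manifest = run_pipeline(config)

print("outputs:")
for key, path in sorted(manifest.outputs.items()):
    print(f"  {key:24s} {path}")

table = pd.read_csv(manifest.outputs["report"], index_col=0)
print("\nstructural parameters by modality:")
print(table)

quality = json.load(open(manifest.outputs["quality"]))
print("\nregistration quality (mm):")
for name, q in quality.items():
    print(f"  {name:9s} landmark RMS {q['landmark_rms_mm']:.4f}, "
          f"mean centerline deviation {q['mean_deviation_mm']:.4f}")
print("-> the MRI-like modality was deliberately misaligned; a sub-voxel mean")
print("   deviation (< 0.0344 mm) shows the landmark registration recovered it.")
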
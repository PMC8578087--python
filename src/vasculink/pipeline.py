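"""End-to-end phantom → segment → co-register → quantify → render runs.

One configured, seeded run generates a ground-truthed vascular phantom,
renders it through each configured modality profile (each non-reference
modality in its own, deliberately misaligned coordinate frame), segments
vessel masks, fits pairwise affine transforms from corresponding branch-point
landmarks back into the reference (CT-resolution) space, resamples all masks
there, computes the per-modality structural parameter table, measures
registration quality, and writes depth-cued MIP and RGB fusion renderings.
Every intermediate artifact lands in open formats (MetaImage, CSV, JSON,
PNG) and the whole run is reproducible from (config, seed).
"""

from __future__ import annotations

import hashlib
import json
import os
import zlib
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io_formats import (
    BinaryMask,
    ImageVolume,
    quantize_to_8bit,
    write_metaimage,
)
from .morphometry import compute_report
from .phantom import (
    DisplacementField,
    ModalityProfile,
    PhantomSpec,
    ct_like,
    generate_vessel_tree,
    hrem_like,
    mri_like,
    pat_like,
    rasterize_tree,
    us_like,
)
from .registration import (
    AffineTransform3D,
    centerline_deviation,
    fit_affine_landmarks,
    invert,
    landmark_rms,
    landmarks_from_node_pairs,
    local_window_deviation,
    resample_to_reference,
    save_transform,
)
from .rendering import depth_cued_projection, fuse_masks, save_png
from .segmentation import morphological_cleanup, threshold_segment

__all__ = [
    "SegmentationParams",
    "ModalityConfig",
    "PipelineConfig",
    "RunManifest",
    "run_pipeline",
    "stage_seed",
    "ellipsoid_mask",
]

_PROFILE_FACTORIES = {
    "mri_like": mri_like,
    "ct_like": ct_like,
    "hrem_like": hrem_like,
    "pat_like": pat_like,
    "us_like": us_like,
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: CRC32 of ``"{seed}:{stage}"`` mod 2^31."""
    return zlib.crc32(f"{global_seed}:{stage}".encode()) % (2**31)


@dataclass
class SegmentationParams:
    method: str = "otsu"
    threshold: float | None = None
    min_component_voxels: int = 10
    closing_radius_voxels: int = 1


@dataclass
class ModalityConfig:
    name: str
    profile: ModalityProfile
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    misalign: bool = True      # give the modality its own pose (ignored for reference)


@dataclass
class PipelineConfig:
    """Configuration of one reproducible pipeline run."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    modalities: list[ModalityConfig] = field(default_factory=list)
    reference: str = "ct_like"
    truth_spacing_mm: float = 0.02
    landmark_jitter_mm: float = 0.0
    landmark_source: str = "phantom-auto"   # or path to a landmark CSV
    output_dir: str = "vasculink_run"
    seed: int = 0
    mip_group_size: int = 5

    def __post_init__(self) -> None:
        if not self.modalities:
            self.modalities = [
                ModalityConfig("ct_like", ct_like()),
                ModalityConfig("mri_like", mri_like()),
            ]
        names = [m.name for m in self.modalities]
        if self.reference not in names:
            raise ValueError(
                f"reference modality {self.reference!r} not in modality list {names}"
            )
        if len(set(names)) != len(names):
            raise ValueError("modality names must be unique")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(os.fspath(path)) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        phantom = PhantomSpec(**raw.get("phantom", {}))
        modalities = []
        for m in raw.get("modalities", []):
            prof_cfg = dict(m.get("profile", {}))
            base = prof_cfg.pop("preset", m.get("name"))
            if base in _PROFILE_FACTORIES:
                if "spacing_mm" in prof_cfg:
                    prof_cfg["spacing_mm"] = tuple(prof_cfg["spacing_mm"])
                profile = _PROFILE_FACTORIES[base](**prof_cfg)
            else:
                prof_cfg.setdefault("name", m["name"])
                prof_cfg["spacing_mm"] = tuple(prof_cfg["spacing_mm"])
                profile = ModalityProfile(**prof_cfg)
            seg = SegmentationParams(**m.get("segmentation", {}))
            modalities.append(
                ModalityConfig(m["name"], profile, seg, m.get("misalign", True))
            )
        kwargs = {
            k: raw[k]
            for k in (
                "reference",
                "truth_spacing_mm",
                "landmark_jitter_mm",
                "landmark_source",
                "output_dir",
                "seed",
                "mip_group_size",
            )
            if k in raw
        }
        return cls(phantom=phantom, modalities=modalities, **kwargs)


@dataclass
class RunManifest:
    """Record of one pipeline run: outputs, parameters, warnings."""

    config_hash: str
    seed: int
    version: str
    started_utc: str
    finished_utc: str = ""
    outputs: dict[str, str] = field(default_factory=dict)
    stage_seeds: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def save(self, path: str | os.PathLike) -> None:
        with open(os.fspath(path), "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def ellipsoid_mask(geometry: ImageVolume, center_mm=None, semiaxes_mm=None) -> BinaryMask:
    """Ellipsoidal tumor mask on a grid (defaults: inscribed in the domain)."""
    shape = np.asarray(geometry.shape)
    spacing = np.asarray(geometry.spacing)
    extent = shape * spacing
    center = np.asarray(center_mm if center_mm is not None else geometry.origin + extent / 2.0)
    semi = np.asarray(semiaxes_mm if semiaxes_mm is not None else extent / 2.0)
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    inside = np.zeros(geometry.shape, dtype=float)
    for ax in range(3):
        coord = geometry.origin[ax] + grids[ax] * spacing[ax]
        inside += ((coord - center[ax]) / semi[ax]) ** 2
    return BinaryMask((inside <= 1.0).astype(np.uint8), geometry.spacing, geometry.origin)


def _random_pose(rng: np.random.Generator, max_angle_deg=8.0, max_shift_mm=0.4) -> AffineTransform3D:
    """Small random rigid pose (reference → moving)."""
    angles = np.deg2rad(rng.uniform(-max_angle_deg, max_angle_deg, 3))
    cx, cy, cz = np.cos(angles)
    sx, sy, sz = np.sin(angles)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    shift = rng.uniform(-max_shift_mm, max_shift_mm, 3)
    return AffineTransform3D(rz @ ry @ rx, shift)


def _fine_geometry(spec: PhantomSpec, spacing: float) -> ImageVolume:
    shape = tuple(max(1, int(round(d / spacing))) for d in spec.domain_size_mm)
    return ImageVolume(np.zeros(shape, dtype=np.float32), (spacing,) * 3)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full phantom pipeline; returns the run manifest.

    Masks, reports and rendered images are byte-identical across reruns with
    the same config and seed (the manifest's timestamps are the only
    run-varying output).
    """
    os.makedirs(config.output_dir, exist_ok=True)
    cfg_hash = hashlib.sha256(
        json.dumps(_config_dict(config), sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    manifest = RunManifest(
        config_hash=cfg_hash,
        seed=config.seed,
        version=__version__,
        started_utc=datetime.now(timezone.utc).isoformat(),
    )
    out = lambda name: os.path.join(config.output_dir, name)

    def record(key: str, path: str) -> str:
        manifest.outputs[key] = path
        return path

    # --- phantom ---------------------------------------------------------
    tree_seed = stage_seed(config.seed, "phantom")
    manifest.stage_seeds["phantom"] = tree_seed
    spec = PhantomSpec(**{**asdict(config.phantom), "seed": tree_seed})
    tree = generate_vessel_tree(spec)
    fine_geom = _fine_geometry(spec, config.truth_spacing_mm)
    truth_frac = rasterize_tree(tree, fine_geom, fractional=True, supersample=2)
    _write_segment_table(tree, record("truth_segments", out("truth_segments.tsv")))

    ref_cfg = next(m for m in config.modalities if m.name == config.reference)
    ref_geom = _modality_geometry(fine_geom, ref_cfg.profile)
    truth_ref_mask = rasterize_tree(tree, ref_geom)
    write_metaimage(truth_ref_mask, record("truth_mask", out("truth_mask.mhd")))

    aligned_masks: dict[str, BinaryMask] = {}
    reports: dict[str, dict] = {}
    quality: dict[str, dict] = {}

    for mod in config.modalities:
        mseed = stage_seed(config.seed, f"modality:{mod.name}")
        manifest.stage_seeds[f"modality:{mod.name}"] = mseed
        rng = np.random.default_rng(mseed)
        is_ref = mod.name == config.reference

        pose = (
            AffineTransform3D.identity()
            if (is_ref or not mod.misalign)
            else _random_pose(rng)
        )

        # truth in the modality's own frame (pull via the inverse pose)
        if is_ref or not mod.misalign:
            truth_mod = truth_frac
        else:
            # moving-frame truth: M(y) = truth(pose(y)), i.e. structures move
            # from reference point x to moving point pose^{-1}(x)
            truth_mod = resample_to_reference(
                truth_frac, fine_geom, transform=pose, interpolation="linear"
            )
        image = _simulate(truth_mod, mod.profile, seed=mseed)
        if is_ref:
            ref_image = image
        write_metaimage(
            quantize_to_8bit(image), record(f"{mod.name}_image", out(f"{mod.name}_image.mhd"))
        )

        seg = mod.segmentation
        mask = threshold_segment(image, method=seg.method, threshold=seg.threshold)
        mask = morphological_cleanup(
            mask, seg.min_component_voxels, seg.closing_radius_voxels
        )
        write_metaimage(mask, record(f"{mod.name}_mask", out(f"{mod.name}_mask.mhd")))

        # ground-truth graph in the modality frame (pose, then any deformation)
        moving_graph = tree.transformed(invert(pose).apply)
        if mod.profile.deformation is not None:
            fld = DisplacementField(truth_mod, mod.profile.deformation)
            moving_graph = moving_graph.transformed(fld.displace_points)

        if is_ref:
            fitted = AffineTransform3D.identity()
            aligned = mask
            rms = 0.0
        else:
            lm_seed = stage_seed(config.seed, f"landmarks:{mod.name}")
            pairs = landmarks_from_node_pairs(
                tree, moving_graph, jitter_mm=config.landmark_jitter_mm, seed=lm_seed
            )
            fitted = fit_affine_landmarks(pairs)
            rms = landmark_rms(pairs, fitted)
            aligned = resample_to_reference(mask, ref_geom, fitted, "nearest")
        save_transform(
            record(f"{mod.name}_transform", out(f"{mod.name}_transform.mhd")), fitted
        )
        write_metaimage(
            aligned,
            record(f"aligned_{mod.name}_mask", out(f"aligned_{mod.name}_mask.mhd")),
            transform=fitted,
        )
        aligned_masks[mod.name] = aligned

        # registration quality: truth centerline vs recovered alignment
        aligned_graph = moving_graph.transformed(invert(fitted).apply)
        dev = centerline_deviation(tree, aligned_graph, landmark_rms_mm=rms)
        quality[mod.name] = {
            "landmark_rms_mm": rms,
            "mean_deviation_mm": dev.mean_mm,
            "median_deviation_mm": dev.median_mm,
            "max_deviation_mm": dev.max_mm,
            "local_window_deviation_mm": local_window_deviation(tree, aligned_graph),
        }
        if mask.voxels.any():
            tumor = ellipsoid_mask(_modality_geometry(fine_geom, mod.profile))
            rep = compute_report(mask, tumor)
            reports[mod.name] = {**asdict(rep), **{"rounded": rep.rounded()}}
        else:
            manifest.warnings.append(f"{mod.name}: empty vessel mask, no morphometry")

    # --- tabular report (Table-3 shape: parameters × modalities) ----------
    rows = [
        "tumor_volume_mm3",
        "vessel_volume_mm3",
        "perfusion_volume_pct",
        "total_vessel_length_mm",
        "n_segments",
        "longest_segment_mm",
        "mean_length_mm",
    ]
    table = pd.DataFrame(
        {name: [round(rep[r], 2) for r in rows] for name, rep in reports.items()},
        index=rows,
    )
    table.to_csv(record("report", out("report.csv")))
    with open(record("quality", out("quality.json")), "w") as fh:
        json.dump(quality, fh, indent=2, sort_keys=True)

    # --- rendering --------------------------------------------------------
    mip = depth_cued_projection(quantize_to_8bit(ref_image), group_size=config.mip_group_size)
    save_png(mip, record("depth_cued_mip", out("depth_cued_mip.png")))
    channel_order = ["red", "green", "blue"]
    fusion_input = {
        channel_order[i]: aligned_masks[name]
        for i, name in enumerate(aligned_masks)
        if i < 3
    }
    fusion = fuse_masks(fusion_input)
    save_png(fusion, record("fusion", out("fusion.png")))

    manifest.finished_utc = datetime.now(timezone.utc).isoformat()
    manifest.save(out("manifest.json"))
    return manifest


def _simulate(truth: ImageVolume, profile: ModalityProfile, seed: int) -> ImageVolume:
    from .phantom import simulate_modality

    return simulate_modality(truth, profile, seed=seed)


def _modality_geometry(fine_geom: ImageVolume, profile: ModalityProfile) -> ImageVolume:
    spacing = np.asarray(profile.spacing_mm)
    fine_spacing = np.asarray(fine_geom.spacing)
    shape = tuple(
        max(1, int(round(n * fs / s)))
        for n, fs, s in zip(fine_geom.shape, fine_spacing, spacing)
    )
    origin = np.asarray(fine_geom.origin) + 0.5 * (spacing - fine_spacing)
    return ImageVolume(np.zeros(shape, dtype=np.uint8), tuple(spacing), tuple(origin))


def _write_segment_table(tree, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("segment_id\tnode_a\tnode_b\tlength_mm\tmean_radius_mm\n")
        for i, seg in enumerate(tree.segments):
            fh.write(
                f"{i}\t{seg.node_ids[0]}\t{seg.node_ids[1]}\t"
                f"{seg.length_mm:.6f}\t{seg.mean_radius_mm:.6f}\n"
            )


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    return d
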
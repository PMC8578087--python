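"""Ground-truth validation experiments.

Self-contained studies exercising the pipeline against analytic or phantom
oracles: affine recovery from random landmark configurations, rasterized
cylinder volume against πr²L, phantom segmentation accuracy, OCTA contrast,
and an end-to-end three-modality co-registration study on a CT-resolution
reference grid.  Each returns plain numbers so reproduction scripts and the
test suite can share one implementation.
"""

from __future__ import annotations

import numpy as np

from .io_formats import ImageVolume
from .morphometry import mask_volume
from .phantom import (
    DeformationSpec,
    DisplacementField,
    PhantomSpec,
    VesselGraph,
    VesselSegment,
    ct_like,
    generate_vessel_tree,
    rasterize_tree,
    simulate_bscan_series,
    simulate_modality,
)
from .registration import (
    AffineTransform3D,
    centerline_deviation,
    fit_affine_landmarks,
    invert,
    landmark_rms,
    landmarks_from_node_pairs,
    LandmarkPairs,
    local_window_deviation,
)
from .segmentation import (
    dice_coefficient,
    morphological_cleanup,
    octa_angiogram,
    threshold_segment,
)

__all__ = [
    "straight_cylinder",
    "cylinder_geometry",
    "affine_recovery_max_error",
    "cylinder_volume_errors",
    "y_phantom_topology",
    "two_level_segmentation_dice",
    "phantom_segmentation_dice",
    "octa_contrast_ratio",
    "coregistration_study",
]


def straight_cylinder(
    radius_mm: float = 0.1,
    length_mm: float = 2.0,
    axis: int = 2,
    pad_mm: float = 0.3,
) -> VesselGraph:
    """Single straight axis-aligned vessel (the analytic-volume fixture)."""
    start = np.full(3, radius_mm + pad_mm)
    end = start.copy()
    end[axis] += length_mm
    pts = np.vstack([start, end])
    seg = VesselSegment(pts, np.full(2, radius_mm), (0, 1))
    return VesselGraph({0: start, 1: end}, [seg])


def cylinder_geometry(tree: VesselGraph, spacing_mm: float) -> ImageVolume:
    pts = tree.all_points()
    rmax = max(s.radii.max() for s in tree.segments)
    hi = pts.max(axis=0) + rmax + 0.3
    shape = tuple(int(np.ceil(h / spacing_mm)) for h in hi)
    return ImageVolume(np.zeros(shape, dtype=np.uint8), (spacing_mm,) * 3)


def cylinder_volume_errors(
    radius_mm: float = 0.1,
    length_mm: float = 2.0,
    spacings_mm: tuple[float, ...] = (0.01, 0.005),
) -> dict:
    """Relative error of rasterized vs analytic cylinder volume per spacing."""
    tree = straight_cylinder(radius_mm, length_mm)
    analytic = np.pi * radius_mm**2 * length_mm
    errors = {}
    for s in spacings_mm:
        mask = rasterize_tree(tree, cylinder_geometry(tree, s))
        errors[s] = abs(mask_volume(mask) - analytic) / analytic
    return {"analytic_mm3": analytic, "relative_errors": errors}


def y_phantom_topology(spacing_mm: float = 0.02, radius_mm: float = 0.06) -> tuple[int, int]:
    """(n_segments, n_branch_nodes) recovered from a rasterized Y of three tubes.

    Three straight tubes meet at one point; correct skeletonization must
    report exactly 3 segments and 1 branch node.
    """
    center = np.array([1.0, 1.0, 1.0])
    tips = [
        center + np.array([0.0, 0.0, -0.8]),
        center + np.array([0.6, 0.0, 0.6]),
        center + np.array([-0.6, 0.0, 0.6]),
    ]
    nodes = {0: center, **{i + 1: t for i, t in enumerate(tips)}}
    segments = [
        VesselSegment(np.vstack([center, t]), np.full(2, radius_mm), (0, i + 1))
        for i, t in enumerate(tips)
    ]
    tree = VesselGraph(nodes, segments)
    shape = tuple(int(round(2.0 / spacing_mm)) for _ in range(3))
    geom = ImageVolume(np.zeros(shape, dtype=np.uint8), (spacing_mm,) * 3)
    mask = rasterize_tree(tree, geom)
    from .morphometry import skeletonize

    graph = skeletonize(mask)
    return graph.n_segments, len(graph.branch_node_ids())


def affine_recovery_max_error(
    n_trials: int = 1000,
    n_landmarks: int = 8,
    seed: int = 0,
) -> float:
    """Worst-case parameter recovery error over random affine/landmark draws.

    Each trial draws an invertible random affine and ``n_landmarks`` random
    non-coplanar points, maps them exactly, fits, and measures the max
    absolute difference between fitted and true parameters.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    trials = 0
    while trials < n_trials:
        matrix = rng.uniform(-1.5, 1.5, (3, 3))
        if abs(np.linalg.det(matrix)) < 0.05:
            continue
        offset = rng.uniform(-5, 5, 3)
        truth = AffineTransform3D(matrix, offset)
        fixed = rng.uniform(-10, 10, (n_landmarks, 3))
        if np.linalg.matrix_rank(fixed - fixed.mean(axis=0), tol=1e-6) < 3:
            continue
        pairs = LandmarkPairs(fixed, truth(fixed))
        fitted = fit_affine_landmarks(pairs)
        err = max(
            float(np.abs(fitted.matrix - truth.matrix).max()),
            float(np.abs(fitted.offset - truth.offset).max()),
        )
        worst = max(worst, err)
        trials += 1
    return worst


def two_level_segmentation_dice(seed: int = 11) -> float:
    """Dice of Otsu segmentation on a noiseless two-level phantom volume.

    Background 10, vessels 200, no blur or noise: the histogram is exactly
    bimodal, Otsu separates it perfectly and the mask must equal the
    rasterized ground truth (Dice 1.0).
    """
    spec = PhantomSpec(
        domain_size_mm=(3.0, 3.0, 3.0), root_radius_mm=0.2, generations=2, seed=seed
    )
    tree = generate_vessel_tree(spec)
    geom = ImageVolume(
        np.zeros(tuple(int(round(d / 0.0344)) for d in spec.domain_size_mm), np.uint8),
        (0.0344,) * 3,
    )
    truth = rasterize_tree(tree, geom)
    two_level = geom.like((truth.voxels.astype(np.float32) * 190.0 + 10.0))
    mask = threshold_segment(two_level, method="otsu")
    return dice_coefficient(mask, truth)


def phantom_segmentation_dice(
    noise_sigma: float = 0.05,
    seed: int = 11,
    generations: int = 3,
) -> float:
    """Dice of Otsu+cleanup segmentation against the rasterized ground truth.

    A CT-like acquisition (34.4 μm grid) of a 3-generation tree; the truth
    mask is the same tree rasterized directly on the modality grid.
    """
    spec = PhantomSpec(
        domain_size_mm=(3.0, 3.0, 3.0),
        root_radius_mm=0.2,
        generations=generations,
        segment_length_range_mm=(0.6, 0.9),
        seed=seed,
    )
    tree = generate_vessel_tree(spec)
    profile = ct_like(noise_sigma=noise_sigma)
    fine = ImageVolume(
        np.zeros(tuple(int(round(d / 0.0172)) for d in spec.domain_size_mm), np.uint8),
        (0.0172,) * 3,
    )
    truth_frac = rasterize_tree(tree, fine, fractional=True, supersample=2)
    image = simulate_modality(truth_frac, profile, seed=seed)
    truth_ct = rasterize_tree(tree, image)
    mask = threshold_segment(image, method="otsu")
    mask = morphological_cleanup(mask, min_component_voxels=10, closing_radius_voxels=1)
    return dice_coefficient(mask, truth_ct)


def octa_contrast_ratio(seed: int = 0) -> float:
    """Flow-region vs background mean angiogram ratio on a simulated series."""
    frames = simulate_bscan_series(seed=seed)
    ang = octa_angiogram(frames, gaussian_sigma=1.0, threshold=0.0)
    yy, xx = np.mgrid[0 : ang.shape[0], 0 : ang.shape[1]]
    disk = (yy - 32) ** 2 + (xx - 32) ** 2 <= 10**2
    outside = (yy - 32) ** 2 + (xx - 32) ** 2 >= 14**2  # margin past smoothing halo
    return float(ang[disk].mean() / max(ang[outside].mean(), 1e-12))


def coregistration_study(
    seed: int = 0,
    domain_mm: float = 4.4,
    landmark_jitter_voxels: float = 0.5,
) -> dict:
    """Three-modality co-registration on a ~128³ CT-resolution reference grid.

    The reference is a CT-like frame; an MRI-like partner is related to it by
    a known affine pose, an HREM-like partner additionally by a smooth
    nonlinear deformation.  Landmarks are phantom branch points jittered by
    half a reference voxel (emulating manual placement).  For each partner
    the study fits the affine, aligns the ground-truth centerline with the
    fitted transform, and measures centerline deviation against the reference
    truth — globally and in the best local window.
    """
    rng = np.random.default_rng(seed)
    spec = PhantomSpec(
        domain_size_mm=(domain_mm,) * 3,
        root_radius_mm=0.22,
        generations=4,
        segment_length_range_mm=(0.7, 1.1),
        seed=int(rng.integers(2**31)),
    )
    tree = generate_vessel_tree(spec)
    ref_voxel = 0.0344
    jitter_mm = landmark_jitter_voxels * ref_voxel

    def random_pose():
        angles = np.deg2rad(rng.uniform(-8, 8, 3))
        cx, cy, cz = np.cos(angles)
        sx, sy, sz = np.sin(angles)
        rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
        ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
        rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
        return AffineTransform3D(rz @ ry @ rx, rng.uniform(-0.4, 0.4, 3))

    results = {"reference_voxel_mm": ref_voxel, "n_landmarks": len(tree.branch_node_ids())}

    # --- affine-only partner (MRI-like pose) -----------------------------
    pose = random_pose()
    moving_graph = tree.transformed(invert(pose).apply)
    pairs = landmarks_from_node_pairs(
        tree, moving_graph, jitter_mm=jitter_mm, seed=int(rng.integers(2**31))
    )
    fitted = fit_affine_landmarks(pairs)
    aligned = moving_graph.transformed(invert(fitted).apply)
    dev = centerline_deviation(tree, aligned, landmark_rms_mm=landmark_rms(pairs, fitted))
    results["affine_pair"] = {
        "landmark_rms_mm": dev.landmark_rms_mm,
        "mean_deviation_mm": dev.mean_mm,
        "max_deviation_mm": dev.max_mm,
        "subvoxel": dev.mean_mm < ref_voxel,
    }

    # --- deformed partner (HREM-like sectioning distortion) --------------
    pose_h = random_pose()
    deform = DeformationSpec(
        amplitude_mm=0.5, smoothness_mm=1.5, seed=int(rng.integers(2**31))
    )
    field_geom = ImageVolume(
        np.zeros((64, 64, 64), dtype=np.uint8), (domain_mm / 64,) * 3
    )
    field = DisplacementField(field_geom, deform)
    moved = tree.transformed(invert(pose_h).apply)
    deformed = moved.transformed(field.displace_points)
    pairs_h = landmarks_from_node_pairs(
        tree, deformed, jitter_mm=jitter_mm, seed=int(rng.integers(2**31))
    )
    fitted_h = fit_affine_landmarks(pairs_h)
    aligned_h = deformed.transformed(invert(fitted_h).apply)
    dev_h = centerline_deviation(tree, aligned_h, landmark_rms_mm=landmark_rms(pairs_h, fitted_h))
    local = local_window_deviation(tree, aligned_h, window_mm=1.0)
    results["deformed_pair"] = {
        "landmark_rms_mm": dev_h.landmark_rms_mm,
        "mean_deviation_mm": dev_h.mean_mm,
        "max_deviation_mm": dev_h.max_mm,
        "local_window_mean_mm": local,
        "local_better_than_global": local < dev_h.mean_mm,
    }
    return results
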
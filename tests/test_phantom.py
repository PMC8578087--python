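import numpy as np
import pytest

from vasculink.io_formats import BinaryMask, ImageVolume
from vasculink.morphometry import mask_volume
from vasculink.phantom import (
    DeformationSpec,
    DisplacementField,
    ModalityProfile,
    PhantomSpec,
    analytic_tree_volume,
    ct_like,
    generate_vessel_tree,
    mri_like,
    pat_like,
    rasterize_tree,
    simulate_modality,
)
from vasculink.segmentation import threshold_segment
from vasculink.validation import straight_cylinder, cylinder_geometry


class TestTreeGeneration:
    def test_zero_generations_single_root_segment(self):
        tree = generate_vessel_tree(PhantomSpec(generations=0, seed=1))
        assert tree.n_segments == 1
        assert tree.branch_node_ids() == []

    def test_deterministic_for_fixed_seed(self):
        a = generate_vessel_tree(PhantomSpec(seed=9))
        b = generate_vessel_tree(PhantomSpec(seed=9))
        assert a.n_segments == b.n_segments
        for sa, sb in zip(a.segments, b.segments):
            np.testing.assert_array_equal(sa.points, sb.points)
            np.testing.assert_array_equal(sa.radii, sb.radii)

    def test_different_seeds_differ(self):
        a = generate_vessel_tree(PhantomSpec(seed=1))
        b = generate_vessel_tree(PhantomSpec(seed=2))
        assert not np.allclose(a.all_points()[: 10], b.all_points()[: 10])

    def test_murray_law_child_radius_ratio(self):
        """Two equal children with exponent 3: r_child/r_parent = 2^(-1/3)."""
        tree = generate_vessel_tree(PhantomSpec(generations=1, seed=4))
        radii = sorted({float(s.radii[0]) for s in tree.segments})
        assert len(radii) == 2
        assert radii[0] / radii[1] == pytest.approx(2 ** (-1 / 3), rel=1e-12)

    def test_segment_count_matches_full_binary_tree(self):
        for g in range(4):
            tree = generate_vessel_tree(PhantomSpec(generations=g, seed=3))
            assert tree.n_segments == 2 ** (g + 1) - 1

    def test_tree_confined_to_domain(self):
        spec = PhantomSpec(domain_size_mm=(3.0, 3.0, 3.0), generations=4, seed=8)
        pts = generate_vessel_tree(spec).all_points()
        assert (pts >= 0).all() and (pts <= 3.0).all()

    def test_radius_floor_enforced(self):
        with pytest.raises(ValueError, match="floor"):
            PhantomSpec(generations=40, root_radius_mm=0.2)

    def test_tip_pruning_removes_terminal_segments(self):
        full = generate_vessel_tree(PhantomSpec(generations=3, seed=5))
        pruned = generate_vessel_tree(
            PhantomSpec(generations=3, seed=5, prune_tip_fraction=0.5)
        )
        assert pruned.n_segments < full.n_segments


class TestRasterization:
    def test_empty_tree_empty_mask(self):
        from vasculink.phantom import VesselGraph

        geom = ImageVolume(np.zeros((5, 5, 5), np.uint8), (0.1,) * 3)
        mask = rasterize_tree(VesselGraph({}, []), geom)
        assert not mask.voxels.any()

    def test_cylinder_volume_close_to_analytic(self):
        tree = straight_cylinder(radius_mm=0.1, length_mm=2.0)
        mask = rasterize_tree(tree, cylinder_geometry(tree, 0.01))
        analytic = np.pi * 0.1**2 * 2.0
        assert mask_volume(mask) == pytest.approx(analytic, rel=0.05)

    def test_volume_error_shrinks_with_spacing(self):
        tree = straight_cylinder(radius_mm=0.1, length_mm=2.0)
        analytic = np.pi * 0.1**2 * 2.0
        errs = []
        for s in (0.01, 0.005):
            mask = rasterize_tree(tree, cylinder_geometry(tree, s))
            errs.append(abs(mask_volume(mask) - analytic) / analytic)
        assert errs[1] < errs[0]

    def test_subvoxel_tube_partial_volume_below_one(self):
        tree = straight_cylinder(radius_mm=0.024, length_mm=2.0)  # diameter ~ half voxel
        geom = cylinder_geometry(tree, 0.1)
        occ = rasterize_tree(tree, geom, fractional=True, supersample=4)
        assert 0 < occ.voxels.max() < 1.0

    def test_analytic_volume_cylinder_and_additivity(self):
        tree = straight_cylinder(radius_mm=0.1, length_mm=2.0)
        single = analytic_tree_volume(tree)
        assert single == pytest.approx(np.pi * 0.1**2 * 2.0, rel=1e-12)

        from vasculink.phantom import VesselGraph

        other = straight_cylinder(radius_mm=0.1, length_mm=2.0)
        shift = np.array([5.0, 0.0, 0.0])
        moved = other.transformed(lambda p: p + shift)
        both = VesselGraph(
            {0: tree.nodes[0], 1: tree.nodes[1], 2: moved.nodes[0], 3: moved.nodes[1]},
            [
                tree.segments[0],
                type(tree.segments[0])(
                    moved.segments[0].points, moved.segments[0].radii, (2, 3)
                ),
            ],
        )
        assert analytic_tree_volume(both) == pytest.approx(2 * single, rel=1e-12)

        assert analytic_tree_volume(VesselGraph({}, [])) == 0.0


class TestModalitySimulation:
    def test_identity_profile_proportional_to_input(self, small_mask):
        profile = ModalityProfile(
            name="ideal", spacing_mm=small_mask.spacing, psf_fwhm_mm=0.0, noise_sigma=0.0
        )
        out = simulate_modality(small_mask, profile, seed=0)
        np.testing.assert_allclose(out.voxels, small_mask.voxels.astype(np.float32))

    def test_finer_output_spacing_rejected(self, small_mask):
        profile = ModalityProfile(name="x", spacing_mm=(0.01, 0.01, 0.01))
        with pytest.raises(ValueError, match="finer"):
            simulate_modality(small_mask, profile, seed=0)

    def test_mri_profile_censors_thin_but_not_thick_vessels(self):
        """Vessels below ~100 μm diameter sink into the noise; larger ones stand out."""
        from scipy.spatial import cKDTree

        profile = mri_like()
        results = {}
        for radius in (0.02, 0.15):
            tree = straight_cylinder(radius_mm=radius, length_mm=2.0, pad_mm=0.4)
            geom = cylinder_geometry(tree, 0.02)
            frac = rasterize_tree(tree, geom, fractional=True, supersample=2)
            img = simulate_modality(frac, profile, seed=7)
            # in-vessel voxels: centers near the true centerline (at least one
            # voxel wide so sub-voxel vessels still define an in-vessel region)
            idx = np.argwhere(np.ones(img.shape, dtype=bool))
            centers = img.physical_coordinates(idx)
            kdt = cKDTree(tree.all_points(step_mm=0.02))
            d, _ = kdt.query(centers)
            margin = max(radius, max(img.spacing) / 2)
            inside = img.voxels.ravel()[d <= margin]
            background = img.voxels.ravel()[d > margin + 0.3]
            results[radius] = (inside.mean() - background.mean()) / profile.noise_sigma
        assert results[0.02] < 2.0
        assert results[0.15] > 2.0

    def test_pat_depth_attenuation_kills_deep_vessels(self):
        """Beyond the 3 mm penetration limit, vessels drop below threshold."""
        profile = pat_like(noise_sigma=0.0)
        tree = straight_cylinder(radius_mm=0.15, length_mm=5.5, axis=2, pad_mm=0.2)
        geom = cylinder_geometry(tree, 0.04)
        frac = rasterize_tree(tree, geom, fractional=True, supersample=2)
        img = simulate_modality(frac, profile, seed=0)
        mask = threshold_segment(img, method="fixed", threshold=0.5)
        z_mm = np.arange(img.shape[2]) * img.spacing[2]
        foreground_per_slice = mask.voxels.sum(axis=(0, 1))
        assert foreground_per_slice[z_mm < 2.5].sum() > 0
        assert foreground_per_slice[z_mm > 4.0].sum() == 0

    def test_simulation_deterministic_per_seed(self, small_mask):
        profile = ct_like(spacing_mm=(0.2, 0.2, 0.2), psf_fwhm_mm=0.3)
        a = simulate_modality(small_mask, profile, seed=3)
        b = simulate_modality(small_mask, profile, seed=3)
        c = simulate_modality(small_mask, profile, seed=4)
        np.testing.assert_array_equal(a.voxels, b.voxels)
        assert not np.array_equal(a.voxels, c.voxels)


class TestDeformation:
    def test_displacement_bounded_by_amplitude(self):
        geom = ImageVolume(np.zeros((32, 32, 32), np.uint8), (0.1,) * 3)
        spec = DeformationSpec(amplitude_mm=0.7, smoothness_mm=0.8, seed=2)
        field = DisplacementField(geom, spec)
        pts = np.random.default_rng(0).uniform(0, 3.1, (500, 3))
        moved = field.displace_points(pts)
        disp = np.linalg.norm(moved - pts, axis=1)
        assert disp.max() <= 0.7 + 1e-9
        assert disp.max() > 0.1  # field actually does something

    def test_deformation_reaches_stated_amplitude_on_grid(self):
        geom = ImageVolume(np.zeros((24, 24, 24), np.uint8), (0.1,) * 3)
        field = DisplacementField(geom, DeformationSpec(amplitude_mm=0.5, seed=1))
        mags = np.linalg.norm(field.displacement_mm, axis=-1)
        assert mags.max() == pytest.approx(0.5, rel=1e-6)


def test_censoring_monotone_in_detectability_limit():
    """Recovered centerline fraction never increases as the modality's
    detectability limit grows (coarser modalities see fewer vessels)."""
    from scipy.spatial import cKDTree

    spec = PhantomSpec(
        domain_size_mm=(3.0, 3.0, 3.0),
        root_radius_mm=0.15,
        generations=3,
        segment_length_range_mm=(0.5, 0.8),
        seed=21,
    )
    tree = generate_vessel_tree(spec)
    fine = ImageVolume(np.zeros((150, 150, 150), np.uint8), (0.02,) * 3)
    frac = rasterize_tree(tree, fine, fractional=True, supersample=2)
    truth_pts = tree.all_points(step_mm=0.05)

    fractions = []
    for min_r, fwhm in ((0.02, 0.05), (0.05, 0.12), (0.08, 0.2)):
        profile = ModalityProfile(
            name=f"m{min_r}",
            spacing_mm=(0.05, 0.05, 0.05),
            psf_fwhm_mm=fwhm,
            noise_sigma=0.05,
            min_detectable_radius_mm=min_r,
        )
        img = simulate_modality(frac, profile, seed=2)
        mask = threshold_segment(img, method="fixed", threshold=0.3)
        fg = np.argwhere(mask.voxels)
        if len(fg) == 0:
            fractions.append(0.0)
            continue
        kdt = cKDTree(mask.physical_coordinates(fg))
        d, _ = kdt.query(truth_pts)
        fractions.append(float((d < 0.1).mean()))
    assert fractions[0] >= fractions[1] >= fractions[2]
    assert fractions[0] > fractions[2]  # strictly censoring overall
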
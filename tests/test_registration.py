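import numpy as np
import pytest

from vasculink.io_formats import BinaryMask, ImageVolume
from vasculink.phantom import PhantomSpec, generate_vessel_tree
from vasculink.registration import (
    AffineTransform3D,
    LandmarkPairs,
    centerline_deviation,
    compose,
    fit_affine_landmarks,
    invert,
    landmarks_from_node_pairs,
    load_transform,
    resample_to_reference,
    save_transform,
)
from vasculink.validation import affine_recovery_max_error, straight_cylinder


def _random_affine(rng):
    while True:
        m = rng.uniform(-1.5, 1.5, (3, 3))
        if abs(np.linalg.det(m)) > 0.05:
            return AffineTransform3D(m, rng.uniform(-3, 3, 3))


class TestFitAffine:
    def test_identity_correspondence(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1.0]])
        t = fit_affine_landmarks(LandmarkPairs(pts, pts))
        np.testing.assert_allclose(t.matrix, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(t.offset, 0, atol=1e-12)

    def test_pure_translation(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        t = fit_affine_landmarks(LandmarkPairs(pts, pts + [1, 2, 3]))
        np.testing.assert_allclose(t.matrix, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(t.offset, [1, 2, 3], atol=1e-12)

    def test_exact_recovery_of_random_affines(self):
        assert affine_recovery_max_error(n_trials=200, seed=5) < 1e-9

    def test_too_few_pairs_rejected(self):
        pts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0.0]])
        with pytest.raises(ValueError, match=">= 4"):
            fit_affine_landmarks(LandmarkPairs(pts, pts))

    def test_coplanar_fixed_points_rejected(self):
        rng = np.random.default_rng(0)
        pts = np.hstack([rng.uniform(-1, 1, (8, 2)), np.zeros((8, 1))])
        with pytest.raises(ValueError, match="degenerate"):
            fit_affine_landmarks(LandmarkPairs(pts, pts))


class TestComposeInvert:
    def test_compose_with_identity(self):
        t = _random_affine(np.random.default_rng(1))
        c = compose(AffineTransform3D.identity(), t)
        np.testing.assert_allclose(c.matrix, t.matrix)
        np.testing.assert_allclose(c.offset, t.offset)

    def test_inverse_roundtrip_is_identity(self):
        t = _random_affine(np.random.default_rng(2))
        c = compose(invert(t), t)
        np.testing.assert_allclose(c.matrix, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(c.offset, 0, atol=1e-12)

    def test_composition_matches_pointwise_application(self):
        rng = np.random.default_rng(3)
        a, b = _random_affine(rng), _random_affine(rng)
        pts = rng.uniform(-5, 5, (100, 3))
        np.testing.assert_allclose(compose(a, b)(pts), a(b(pts)), atol=1e-12)

    def test_singular_matrix_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            AffineTransform3D(np.zeros((3, 3)), np.zeros(3))


class TestResample:
    def test_identity_transform_same_grid_is_identity(self, small_volume, small_mask):
        for vol, interp in ((small_volume, "linear"), (small_mask, "nearest")):
            out = resample_to_reference(vol, vol, AffineTransform3D.identity(), interp)
            np.testing.assert_allclose(out.voxels, vol.voxels.astype(out.voxels.dtype))

    def test_2x_downsampling_yields_34_4_micron_grid(self):
        """Halving a 17.2 μm grid gives the 34.4 μm alignment resolution."""
        fine = ImageVolume(np.zeros((64, 64, 64), np.float32), (0.0172,) * 3)
        ref = ImageVolume(np.zeros((32, 32, 32), np.float32), (0.0344,) * 3)
        out = resample_to_reference(fine, ref, interpolation="linear")
        assert out.spacing == (0.0344, 0.0344, 0.0344)

    def test_mask_resampling_stays_binary(self, small_mask):
        rng = np.random.default_rng(4)
        t = AffineTransform3D(np.eye(3) * 1.1, rng.uniform(-0.05, 0.05, 3))
        out = resample_to_reference(small_mask, small_mask, t, "nearest")
        assert isinstance(out, BinaryMask)
        assert set(np.unique(out.voxels)) <= {0, 1}

    def test_mask_linear_interpolation_rejected(self, small_mask):
        with pytest.raises(ValueError, match="nearest"):
            resample_to_reference(small_mask, small_mask, None, "linear")

    def test_mask_support_confined_to_dilated_input_image(self, small_mask):
        """Resampled foreground stays within one voxel of the mapped support."""
        from scipy import ndimage

        t = AffineTransform3D(np.eye(3), np.array([0.15, 0.0, 0.0]))
        out = resample_to_reference(small_mask, small_mask, t, "nearest")
        # map input support into reference space via the inverse
        idx = np.argwhere(small_mask.voxels)
        ref_pts = invert(t)(small_mask.physical_coordinates(idx))
        ref_idx = np.round(small_mask.index_coordinates(ref_pts)).astype(int)
        support = np.zeros(small_mask.shape, bool)
        keep = ((ref_idx >= 0) & (ref_idx < np.array(small_mask.shape))).all(axis=1)
        support[tuple(ref_idx[keep].T)] = True
        support = ndimage.binary_dilation(support, iterations=1)
        assert not (out.voxels.astype(bool) & ~support).any()


class TestCenterlineDeviation:
    def test_identical_graphs_zero(self):
        tree = generate_vessel_tree(PhantomSpec(generations=2, seed=6))
        q = centerline_deviation(tree, tree)
        assert q.mean_mm == 0.0 and q.max_mm == 0.0

    def test_perpendicular_translation_recovered(self):
        line = straight_cylinder(radius_mm=0.05, length_mm=3.0, axis=0)
        shifted = line.transformed(lambda p: p + np.array([0.0, 0.5, 0.0]))
        q = centerline_deviation(line, shifted)
        assert q.mean_mm == pytest.approx(0.5, rel=1e-6)
        assert q.max_mm == pytest.approx(0.5, rel=1e-6)

    def test_empty_graph_rejected(self):
        from vasculink.phantom import VesselGraph

        tree = generate_vessel_tree(PhantomSpec(generations=1, seed=1))
        with pytest.raises(ValueError, match="non-empty"):
            centerline_deviation(tree, VesselGraph({}, []))

    def test_affine_recovery_experiment_subvoxel(self):
        """Phantom pair under a known affine: fit + align leaves sub-voxel residual."""
        rng = np.random.default_rng(8)
        tree = generate_vessel_tree(PhantomSpec(generations=3, seed=8))
        pose = _random_affine(rng)
        moving = tree.transformed(invert(pose).apply)
        pairs = landmarks_from_node_pairs(tree, moving, jitter_mm=0.0)
        fitted = fit_affine_landmarks(pairs)
        aligned = moving.transformed(invert(fitted).apply)
        q = centerline_deviation(tree, aligned)
        assert q.mean_mm < 0.0344  # one CT-resolution voxel


class TestTransformPersistence:
    def test_round_trip_bit_exact(self, tmp_path):
        t = _random_affine(np.random.default_rng(9))
        save_transform(tmp_path / "t.mhd", t)
        back = load_transform(tmp_path / "t.mhd")
        assert (back.matrix == t.matrix).all()
        assert (back.offset == t.offset).all()

    def test_identity_serialization(self, tmp_path):
        save_transform(tmp_path / "i.mhd", AffineTransform3D.identity())
        text = (tmp_path / "i.mhd").read_text()
        line = next(l for l in text.splitlines() if l.startswith("TransformMatrix"))
        assert [float(v) for v in line.split("=")[1].split()] == [1, 0, 0, 0, 1, 0, 0, 0, 1]

    def test_malformed_field_counts_rejected(self, tmp_path):
        (tmp_path / "bad.mhd").write_text("TransformMatrix = 1 0 0\nOffset = 0 0 0\n")
        with pytest.raises(ValueError, match="9 entries"):
            load_transform(tmp_path / "bad.mhd")


def test_landmark_csv_round_trip(tmp_path):
    rng = np.random.default_rng(10)
    pairs = LandmarkPairs(rng.uniform(0, 5, (6, 3)), rng.uniform(0, 5, (6, 3)))
    pairs.write_csv(tmp_path / "lm.csv")
    back = LandmarkPairs.read_csv(tmp_path / "lm.csv")
    np.testing.assert_array_equal(back.fixed_points, pairs.fixed_points)
    np.testing.assert_array_equal(back.moving_points, pairs.moving_points)
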
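import numpy as np
import pytest

from vasculink.io_formats import BinaryMask, ImageVolume
from vasculink.morphometry import (
    compute_report,
    mask_volume,
    perfusion_volume,
    segment_statistics,
    skeletonize,
)
from vasculink.phantom import (
    PhantomSpec,
    VesselGraph,
    VesselSegment,
    generate_vessel_tree,
    rasterize_tree,
)
from vasculink.validation import straight_cylinder, cylinder_geometry
from tests.conftest import make_tube_mask


class TestMaskVolume:
    def test_empty_mask_zero(self):
        mask = BinaryMask(np.zeros((4, 4, 4), np.uint8), (0.1,) * 3)
        assert mask_volume(mask) == 0.0

    def test_counting_arithmetic(self):
        vox = np.zeros((10, 10, 10), np.uint8)
        vox.ravel()[:1000] = 1
        assert mask_volume(BinaryMask(vox, (0.1,) * 3)) == pytest.approx(1.0)

    def test_cylinder_against_analytic(self):
        tree = straight_cylinder(0.1, 2.0)
        mask = rasterize_tree(tree, cylinder_geometry(tree, 0.01))
        assert mask_volume(mask) == pytest.approx(np.pi * 0.01 * 2.0, rel=0.05)


class TestPerfusionVolume:
    @pytest.mark.parametrize(
        "vessel,tumor,expected",
        [(7.13, 990.0, 0.72), (0.25, 922.0, 0.03), (0.0, 500.0, 0.0)],
    )
    def test_ratio_definition(self, vessel, tumor, expected):
        assert round(perfusion_volume(vessel, tumor), 2) == expected

    def test_nonpositive_tumor_rejected(self):
        with pytest.raises(ValueError):
            perfusion_volume(1.0, 0.0)


class TestSkeletonize:
    def test_straight_tube_single_segment(self):
        graph = skeletonize(make_tube_mask())
        assert graph.n_segments == 1
        assert graph.branch_node_ids() == []
        assert len(graph.nodes) == 2

    def test_straight_tube_length_within_one_voxel(self):
        spacing = 0.1
        mask = make_tube_mask(shape=(40, 9, 9), spacing=spacing)
        graph = skeletonize(mask)
        total, n, longest, mean = segment_statistics(graph)
        # centerline spans most of the 40-voxel extent minus thinning end-erosion
        expected_max = 39 * spacing
        assert n == 1
        assert longest <= expected_max + spacing
        assert longest >= expected_max - 2 * 2.5 * spacing  # ends erode ~tube radius

    def test_y_junction_three_segments_one_branch(self):
        vox = np.zeros((40, 40, 9), np.uint8)
        yy, xx = np.mgrid[0:40, 0:40]

        def tube2d(x0, y0, x1, y1, r=2.2):
            # distance from pixel to segment
            vx, vy = x1 - x0, y1 - y0
            t = np.clip(((xx - x0) * vx + (yy - y0) * vy) / (vx**2 + vy**2), 0, 1)
            d2 = (xx - (x0 + t * vx)) ** 2 + (yy - (y0 + t * vy)) ** 2
            return d2 <= r**2

        shape2d = tube2d(20, 4, 20, 20) | tube2d(20, 20, 8, 34) | tube2d(20, 20, 32, 34)
        for z in range(3, 6):
            vox[..., z] = shape2d.T
        graph = skeletonize(BinaryMask(vox, (0.1,) * 3))
        assert graph.n_segments == 3
        assert len(graph.branch_node_ids()) == 1
        endpoint_ids = [
            nid
            for nid in graph.nodes
            if sum(nid in s.node_ids for s in graph.segments) == 1
        ]
        assert len(endpoint_ids) == 3

    def test_empty_mask_empty_graph(self):
        graph = skeletonize(BinaryMask(np.zeros((5, 5, 5), np.uint8), (0.1,) * 3))
        assert graph.n_segments == 0

    def test_skeleton_is_subset_of_mask(self):
        tree = generate_vessel_tree(
            PhantomSpec(domain_size_mm=(2, 2, 2), generations=2, root_radius_mm=0.15,
                        segment_length_range_mm=(0.4, 0.6), seed=3)
        )
        geom = ImageVolume(np.zeros((100, 100, 100), np.uint8), (0.02,) * 3)
        mask = rasterize_tree(tree, geom)
        graph = skeletonize(mask)
        for seg in graph.segments:
            idx = np.round(mask.index_coordinates(seg.points[1:-1])).astype(int)
            assert mask.voxels[idx[:, 0], idx[:, 1], idx[:, 2]].all()


class TestSegmentStatistics:
    def _graph_with_lengths(self, lengths):
        nodes, segments = {}, []
        nid = 0
        for i, L in enumerate(lengths):
            a = np.array([0.0, 0.0, 10.0 * i])
            b = a + np.array([L, 0.0, 0.0])
            nodes[nid] = a
            nodes[nid + 1] = b
            segments.append(VesselSegment(np.vstack([a, b]), np.full(2, 0.05), (nid, nid + 1)))
            nid += 2
        return VesselGraph(nodes, segments)

    def test_known_lengths(self):
        total, n, longest, mean = segment_statistics(self._graph_with_lengths([1, 2, 3]))
        assert (total, n, longest, mean) == (6.0, 3, 3.0, 2.0)

    def test_single_segment_degenerate(self):
        total, n, longest, mean = segment_statistics(self._graph_with_lengths([4.2]))
        assert total == longest == mean == pytest.approx(4.2)
        assert n == 1

    def test_empty_graph_zeros_with_warning(self):
        with pytest.warns(UserWarning, match="empty"):
            total, n, longest, mean = segment_statistics(VesselGraph({}, []))
        assert (total, n, longest, mean) == (0.0, 0, 0.0, 0.0)

    def test_phantom_total_length_within_10pct_at_ct_resolution(self):
        spec = PhantomSpec(
            domain_size_mm=(3, 3, 3), root_radius_mm=0.18, generations=2,
            segment_length_range_mm=(0.7, 1.0), seed=13,
        )
        tree = generate_vessel_tree(spec)
        geom = ImageVolume(
            np.zeros(tuple(int(3 / 0.0344) for _ in range(3)), np.uint8), (0.0344,) * 3
        )
        mask = rasterize_tree(tree, geom)
        graph = skeletonize(mask)
        total, *_ = segment_statistics(graph)
        assert total == pytest.approx(tree.total_length_mm(), rel=0.10)


class TestComputeReport:
    def test_report_internal_consistency(self):
        spec = PhantomSpec(domain_size_mm=(2.5, 2.5, 2.5), generations=2,
                           root_radius_mm=0.15, segment_length_range_mm=(0.5, 0.7), seed=5)
        tree = generate_vessel_tree(spec)
        geom = ImageVolume(np.zeros((72, 72, 72), np.uint8), (0.0344,) * 3)
        vessel = rasterize_tree(tree, geom)
        report = compute_report(vessel, tumor=10.0)
        assert report.perfusion_volume_pct == pytest.approx(
            100 * report.vessel_volume_mm3 / report.tumor_volume_mm3
        )
        assert report.mean_length_mm == pytest.approx(
            report.total_vessel_length_mm / report.n_segments
        )
        assert report.longest_segment_mm <= report.total_vessel_length_mm

    def test_noiseless_tree_segment_count_exact(self):
        """A clean 2-generation binary tree yields exactly 2^3-1 = 7 segments."""
        spec = PhantomSpec(domain_size_mm=(3, 3, 3), generations=2, root_radius_mm=0.12,
                           segment_length_range_mm=(0.7, 0.9), tortuosity_deg=3.0, seed=2)
        tree = generate_vessel_tree(spec)
        geom = ImageVolume(np.zeros((120, 120, 120), np.uint8), (0.025,) * 3)
        vessel = rasterize_tree(tree, geom)
        report = compute_report(vessel, tumor=27.0)
        assert report.n_segments == tree.n_segments == 7

    def test_vessel_equal_tumor_gives_100pct(self, small_mask):
        report = compute_report(small_mask, small_mask)
        assert report.perfusion_volume_pct == pytest.approx(100.0)

    def test_empty_vessel_mask_all_zero_with_flag(self, small_mask):
        empty = small_mask.like(np.zeros_like(small_mask.voxels))
        report = compute_report(empty, small_mask)
        assert report.vessel_volume_mm3 == 0
        assert report.n_segments == 0
        assert report.empty

    def test_geometry_mismatch_rejected(self, small_mask):
        other = BinaryMask(small_mask.voxels.copy(), (0.2, 0.2, 0.2))
        with pytest.raises(ValueError, match="geometry"):
            compute_report(small_mask, other)

    def test_rounding_matches_print_precision(self):
        from vasculink.morphometry import MorphometryReport

        rep = MorphometryReport(990.0, 7.13, 0.7202020202, 68.0, 321, 4.0, 0.5)
        assert rep.rounded()["perfusion_volume_pct"] == 0.72
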
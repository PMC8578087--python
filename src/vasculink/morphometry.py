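"""Skeleton-based vascular morphometry.

Computes the structural parameter set used to compare tumor vasculature
across modalities: tumor volume, vessel volume, perfusion volume (vessel
volume as a percentage of tumor volume), total vessel length, number of
segments, longest segment and mean segment length.  Lengths come from a
one-voxel-wide centerline obtained by 3D topological thinning; a *segment*
is a maximal centerline path between branch points and/or endpoints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _skimage_skeletonize

from .io_formats import BinaryMask, ImageVolume, same_geometry
from .phantom import VesselGraph, VesselSegment

__all__ = [
    "MorphometryReport",
    "mask_volume",
    "skeletonize",
    "segment_statistics",
    "perfusion_volume",
    "compute_report",
]


@dataclass
class MorphometryReport:
    """Per-(modality, tumor) structural parameter set."""

    tumor_volume_mm3: float
    vessel_volume_mm3: float
    perfusion_volume_pct: float
    total_vessel_length_mm: float
    n_segments: int
    longest_segment_mm: float
    mean_length_mm: float
    empty: bool = False          # flagged when the vessel mask has no segments

    def rounded(self, ndigits: int = 2) -> dict:
        """Report rounded to print precision; raw values stay on the object."""
        out = {}
        for k, v in asdict(self).items():
            out[k] = round(v, ndigits) if isinstance(v, float) else v
        return out


def mask_volume(mask: BinaryMask) -> float:
    """Mask volume in mm³: foreground voxel count × voxel volume."""
    return float(mask.voxels.astype(bool).sum()) * mask.voxel_volume_mm3


def perfusion_volume(vessel_volume_mm3: float, tumor_volume_mm3: float) -> float:
    """Vessel volume as a percentage of total tumor volume."""
    if tumor_volume_mm3 <= 0:
        raise ValueError(f"tumor volume must be > 0, got {tumor_volume_mm3}")
    if vessel_volume_mm3 < 0:
        raise ValueError("vessel volume must be >= 0")
    return 100.0 * vessel_volume_mm3 / tumor_volume_mm3


# ---------------------------------------------------------------------------
# Skeletonization and graph extraction
# ---------------------------------------------------------------------------

_NEIGHBOR_OFFSETS = np.array(
    [
        (i, j, k)
        for i in (-1, 0, 1)
        for j in (-1, 0, 1)
        for k in (-1, 0, 1)
        if (i, j, k) != (0, 0, 0)
    ]
)


def skeletonize(
    mask: BinaryMask,
    prune_spur_voxels: int = 2,
    spur_radius_factor: float = 2.0,
) -> VesselGraph:
    """Thin a vessel mask to a centerline graph.

    3D topological thinning (Lee et al. 1994, via scikit-image) reduces the
    mask to a one-voxel-wide skeleton.  Skeleton voxels with ≠ 2 neighbors
    (26-connectivity) become graph nodes — endpoints and branch points;
    adjacent node voxels are merged into a single node.  Maximal chains of
    degree-2 voxels between nodes become polyline segments in physical mm.

    Thinning-artifact control: terminal spurs shorter than
    ``prune_spur_voxels`` voxels or shorter than ``spur_radius_factor`` ×
    the local vessel radius (from the mask's Euclidean distance transform)
    are pruned — thick tube ends and junctions shed spurs on that scale —
    always keeping the longest branch of a fork; chains through the removed
    junctions are merged back into single segments.
    """
    skel = _skimage_skeletonize(mask.voxels.astype(bool))
    graph = _skeleton_to_graph(skel, mask)
    if graph.segments:
        min_len = prune_spur_voxels * float(np.max(mask.spacing))
        graph = _simplify_graph(graph, mask, min_len, spur_radius_factor)
    return graph


def _mean_polyline_distance(a: np.ndarray, b: np.ndarray) -> float:
    from scipy.spatial import cKDTree

    d, _ = cKDTree(b).query(a)
    return float(d.mean())


def _simplify_graph(
    graph: VesselGraph,
    mask: BinaryMask,
    min_len_mm: float,
    spur_radius_factor: float,
) -> VesselGraph:
    """Prune thinning spurs and merge the resulting degree-2 chain nodes."""
    edt = ndimage.distance_transform_edt(mask.voxels.astype(bool), sampling=mask.spacing)
    shape = np.asarray(mask.shape)

    def local_radius(point_mm: np.ndarray) -> float:
        idx = np.clip(np.round(mask.index_coordinates(point_mm)).astype(int), 0, shape - 1)
        return float(edt[tuple(idx)])

    nodes = dict(graph.nodes)
    segments = list(graph.segments)
    changed = True
    while changed:
        changed = False
        degree: dict[int, int] = {}
        for seg in segments:
            for nid in seg.node_ids:
                degree[nid] = degree.get(nid, 0) + 1

        # drop short self-loops and the shorter of short parallel duplicates
        by_pair: dict[frozenset, list[VesselSegment]] = {}
        for seg in segments:
            by_pair.setdefault(frozenset(seg.node_ids), []).append(seg)
        drop: set[int] = set()
        for pair, segs in by_pair.items():
            if len(pair) == 1:
                for s in segs:
                    if s.length_mm < max(min_len_mm, 4 * local_radius(s.points[0])):
                        drop.add(id(s))
            elif len(segs) > 1:
                segs_sorted = sorted(segs, key=lambda s: s.length_mm)
                for s in segs_sorted[:-1]:
                    thr = max(min_len_mm, 4 * local_radius(s.points[0]))
                    if s.length_mm < thr:
                        drop.add(id(s))
        if drop:
            segments = [s for s in segments if id(s) not in drop]
            changed = True
            continue

        # collapse "fishtail" forks: two terminal spurs at one junction that
        # run inside the same vessel (mean separation below the local
        # diameter) are one centerline thinned into two; keep the longer
        incident_spurs: dict[int, list[VesselSegment]] = {}
        for seg in segments:
            a, b = seg.node_ids
            if degree.get(a) == 1 and degree.get(b, 0) >= 3:
                incident_spurs.setdefault(b, []).append(seg)
            elif degree.get(b) == 1 and degree.get(a, 0) >= 3:
                incident_spurs.setdefault(a, []).append(seg)
        fishtail_drop = []
        for junction, spurs in incident_spurs.items():
            if len(spurs) < 2:
                continue
            # fishtail arms stay inside the parent tube (separation on the
            # order of the local radius); genuine siblings diverge beyond it
            sep_limit = 1.25 * local_radius(nodes[junction])
            spurs = sorted(spurs, key=lambda s: s.length_mm)
            for i, short in enumerate(spurs[:-1]):
                for long in spurs[i + 1 :]:
                    d = _mean_polyline_distance(short.points, long.points)
                    if d < sep_limit:
                        fishtail_drop.append(short)
                        break
        if fishtail_drop:
            segments = [s for s in segments if s not in fishtail_drop]
            changed = True
            continue

        # prune spurs, shortest first, keeping the last branch of any fork
        spur_candidates = []
        for seg in segments:
            a, b = seg.node_ids
            if degree[a] == 1 and degree[b] == 1:
                continue  # isolated segment, never a spur
            if degree[a] == 1 or degree[b] == 1:
                tip, junction = (a, b) if degree[a] == 1 else (b, a)
                thr = max(min_len_mm, spur_radius_factor * local_radius(nodes[junction]))
                if seg.length_mm < thr:
                    spur_candidates.append((seg.length_mm, junction, seg))
        for _, junction, seg in sorted(spur_candidates, key=lambda t: t[0]):
            if degree[junction] >= 3:
                segments.remove(seg)
                degree[junction] -= 1
                for nid in seg.node_ids:
                    if nid != junction:
                        degree[nid] -= 1
                changed = True
        if changed:
            continue

        # merge chains through degree-2 nodes
        incident: dict[int, list[VesselSegment]] = {}
        for seg in segments:
            for nid in set(seg.node_ids):
                incident.setdefault(nid, []).append(seg)
        for nid, segs in incident.items():
            if len(segs) != 2 or segs[0] is segs[1]:
                continue
            s1, s2 = segs
            if s1.node_ids[0] == s1.node_ids[1] or s2.node_ids[0] == s2.node_ids[1]:
                continue
            p1 = s1.points if s1.node_ids[1] == nid else s1.points[::-1]
            r1 = s1.radii if s1.node_ids[1] == nid else s1.radii[::-1]
            a = s1.node_ids[0] if s1.node_ids[1] == nid else s1.node_ids[1]
            p2 = s2.points if s2.node_ids[0] == nid else s2.points[::-1]
            r2 = s2.radii if s2.node_ids[0] == nid else s2.radii[::-1]
            b = s2.node_ids[1] if s2.node_ids[0] == nid else s2.node_ids[0]
            merged = VesselSegment(
                np.vstack([p1, p2[1:]]), np.concatenate([r1, r2[1:]]), (a, b)
            )
            segments = [s for s in segments if s is not s1 and s is not s2]
            segments.append(merged)
            changed = True
            break  # adjacency changed; rebuild

    used = {nid for s in segments for nid in s.node_ids}
    nodes = {nid: p for nid, p in nodes.items() if nid in used}
    out = VesselGraph(nodes, segments)
    _label_components(out)
    return out


def _skeleton_to_graph(skel: np.ndarray, geom: ImageVolume) -> VesselGraph:
    coords = np.argwhere(skel)
    if len(coords) == 0:
        return VesselGraph({}, [])
    voxel_set = {tuple(c) for c in coords}

    def neighbors(v):
        return [
            tuple(np.add(v, off))
            for off in _NEIGHBOR_OFFSETS
            if tuple(np.add(v, off)) in voxel_set
        ]

    degree = {v: len(neighbors(v)) for v in voxel_set}
    node_voxels = {v for v, d in degree.items() if d != 2}

    # merge 26-adjacent node voxels into single graph nodes
    node_id_of: dict[tuple, int] = {}
    node_points: dict[int, np.ndarray] = {}
    next_id = 0
    unassigned = set(node_voxels)
    while unassigned:
        seed = unassigned.pop()
        cluster = [seed]
        stack = [seed]
        while stack:
            v = stack.pop()
            for nb in neighbors(v):
                if nb in unassigned:
                    unassigned.remove(nb)
                    cluster.append(nb)
                    stack.append(nb)
        for v in cluster:
            node_id_of[v] = next_id
        centroid_idx = np.mean(np.asarray(cluster, dtype=float), axis=0)
        node_points[next_id] = geom.physical_coordinates(centroid_idx)
        next_id += 1

    segments: list[VesselSegment] = []
    visited_edges: set[frozenset] = set()
    radius_placeholder = float(np.max(geom.spacing)) / 2.0

    def trace(start_voxel, first_step):
        """Follow a degree-2 chain from a node voxel until the next node voxel."""
        path = [start_voxel, first_step]
        prev, cur = start_voxel, first_step
        while cur not in node_voxels:
            nbs = [n for n in neighbors(cur) if n != prev]
            if not nbs:
                break  # chain dead-ends on an isolated degree-1 voxel
            prev, cur = cur, nbs[0]
            path.append(cur)
        return path

    for v in sorted(node_voxels):
        for nb in neighbors(v):
            edge = frozenset((v, nb))
            if edge in visited_edges:
                continue
            if nb in node_voxels and node_id_of[nb] == node_id_of[v]:
                visited_edges.add(edge)
                continue  # internal to a merged node cluster
            path = trace(v, nb)
            for a, b in zip(path[:-1], path[1:]):
                visited_edges.add(frozenset((a, b)))
            end = path[-1]
            if end not in node_voxels:
                continue
            a_id, b_id = node_id_of[v], node_id_of[end]
            pts_idx = np.asarray(path, dtype=float)
            pts = geom.physical_coordinates(pts_idx)
            # snap ends to the merged node centroids so endpoints coincide
            pts = np.vstack([node_points[a_id], pts[1:-1], node_points[b_id]])
            if len(pts) < 2:
                pts = np.vstack([node_points[a_id], node_points[b_id]])
            if a_id == b_id and np.allclose(pts[0], pts[-1]) and len(pts) < 3:
                continue
            radii = np.full(len(pts), radius_placeholder)
            segments.append(VesselSegment(pts, radii, (a_id, b_id)))

    # pure cycles (all degree-2) have no node voxel; give each one a node
    chain_voxels = voxel_set - {v for p in visited_edges for v in p} - node_voxels
    remaining = set()
    for v in voxel_set - node_voxels:
        if all(frozenset((v, n)) not in visited_edges for n in neighbors(v)):
            remaining.add(v)
    while remaining:
        seed = next(iter(remaining))
        path = [seed]
        prev, cur = None, seed
        while True:
            nbs = [n for n in neighbors(cur) if n != prev]
            if not nbs:
                break
            prev, cur = cur, nbs[0]
            if cur == seed:
                path.append(cur)
                break
            path.append(cur)
        remaining -= set(path)
        if len(path) < 2:
            continue
        a_id = next_id
        node_points[a_id] = geom.physical_coordinates(np.asarray(path[0], dtype=float))
        next_id += 1
        if path[-1] == path[0]:
            b_id = a_id
            pts = geom.physical_coordinates(np.asarray(path, dtype=float))
        else:
            b_id = next_id
            node_points[b_id] = geom.physical_coordinates(np.asarray(path[-1], dtype=float))
            next_id += 1
            pts = geom.physical_coordinates(np.asarray(path, dtype=float))
        segments.append(
            VesselSegment(pts, np.full(len(pts), radius_placeholder), (a_id, b_id))
        )

    used = {nid for s in segments for nid in s.node_ids}
    # keep isolated single-voxel nodes out of the graph
    node_points = {nid: p for nid, p in node_points.items() if nid in used}
    graph = VesselGraph(node_points, segments)
    _label_components(graph)
    return graph


def _label_components(graph: VesselGraph) -> None:
    parent = {nid: nid for nid in graph.nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for seg in graph.segments:
        a, b = (find(n) for n in seg.node_ids)
        if a != b:
            parent[a] = b
    roots = {}
    labels = []
    for seg in graph.segments:
        r = find(seg.node_ids[0])
        labels.append(roots.setdefault(r, len(roots)))
    graph.component_labels = labels


def segment_statistics(graph: VesselGraph) -> tuple[float, int, float, float]:
    """(total length mm, n segments, longest mm, mean mm) of a centerline graph.

    An empty graph reports zeros (mean undefined → 0) with a warning.
    """
    if not graph.segments:
        warnings.warn("empty vessel graph: statistics reported as zeros")
        return 0.0, 0, 0.0, 0.0
    lengths = np.array([seg.length_mm for seg in graph.segments])
    total = float(lengths.sum())
    return total, len(lengths), float(lengths.max()), total / len(lengths)


def compute_report(
    vessel_mask: BinaryMask,
    tumor: BinaryMask | float,
    prune_spur_voxels: int = 2,
) -> MorphometryReport:
    """Full structural parameter set for one (modality, tumor) pair.

    ``tumor`` is either a tumor mask sharing the vessel mask's geometry or a
    declared tumor volume in mm³ (the VOI case, where only a sub-volume of
    the tumor was imaged at high resolution).
    """
    if isinstance(tumor, BinaryMask):
        if not same_geometry(vessel_mask, tumor):
            raise ValueError("vessel and tumor masks must share geometry")
        tumor_volume = mask_volume(tumor)
    else:
        tumor_volume = float(tumor)
    vessel_volume = mask_volume(vessel_mask)
    if vessel_volume == 0:
        return MorphometryReport(
            tumor_volume_mm3=tumor_volume,
            vessel_volume_mm3=0.0,
            perfusion_volume_pct=0.0 if tumor_volume > 0 else 0.0,
            total_vessel_length_mm=0.0,
            n_segments=0,
            longest_segment_mm=0.0,
            mean_length_mm=0.0,
            empty=True,
        )
    graph = skeletonize(vessel_mask, prune_spur_voxels=prune_spur_voxels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        total, n, longest, mean = segment_statistics(graph)
    return MorphometryReport(
        tumor_volume_mm3=tumor_volume,
        vessel_volume_mm3=vessel_volume,
        perfusion_volume_pct=perfusion_volume(vessel_volume, tumor_volume),
        total_vessel_length_mm=total,
        n_segments=n,
        longest_segment_mm=longest,
        mean_length_mm=mean,
        empty=n == 0,
    )
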
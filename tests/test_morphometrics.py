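"""Erosion, skeleton analysis, node/degree semantics and feature vectors."""

import itertools

import networkx as nx
import numpy as np
import pytest

from mitoganglia.io import VoxelGeometry
from mitoganglia.morphometrics import (
    analyze_skeleton,
    component_shape,
    detect_nodes,
    erode_6conn,
    ganglion_features,
    ganglion_volume,
    skeletonize3d,
)
from mitoganglia.segmentation import MitoComponent

UNIT = VoxelGeometry(1.0, 1.0, 1.0)


def erode_oracle(mask):
    """Exhaustive per-voxel 6-neighbour check."""
    out = np.zeros_like(mask)
    nz, ny, nx = mask.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x]:
                    continue
                ok = True
                for dz, dy, dx in [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]:
                    w = (z + dz, y + dy, x + dx)
                    if not (0 <= w[0] < nz and 0 <= w[1] < ny and 0 <= w[2] < nx) or not mask[w]:
                        ok = False
                        break
                out[z, y, x] = ok
    return out


class TestErosion:
    def test_hand_cases(self):
        single = np.zeros((3, 3, 3), bool)
        single[1, 1, 1] = True
        assert erode_6conn(single).sum() == 0

        cube = np.zeros((5, 5, 5), bool)
        cube[1:4, 1:4, 1:4] = True
        body = erode_6conn(cube)
        assert body.sum() == 1 and body[2, 2, 2]

        rod = np.zeros((3, 3, 12), bool)
        rod[1, 1, 1:11] = True
        assert erode_6conn(rod).sum() == 0  # no lateral face neighbours

    def test_matches_exhaustive_oracle_on_random_masks(self, rng):
        for _ in range(20):
            mask = rng.random((5, 6, 6)) < 0.5
            assert np.array_equal(erode_6conn(mask), erode_oracle(mask))

    def test_border_voxels_are_surface(self):
        full = np.ones((4, 4, 4), bool)
        body = erode_6conn(full)
        assert not body[0].any() and not body[:, 0].any() and not body[:, :, 0].any()
        assert body.sum() == 8  # 2x2x2 interior


class TestSkeletonize:
    def test_fixed_points(self):
        single = np.zeros((3, 3, 3), bool)
        single[1, 1, 1] = True
        assert np.array_equal(skeletonize3d(single), single)

        rod = np.zeros((3, 3, 12), bool)
        rod[1, 1, 1:11] = True
        assert np.array_equal(skeletonize3d(rod), rod)

    def test_thick_rod_thins_to_single_path(self):
        thick = np.zeros((5, 5, 11), bool)
        thick[1:4, 1:4, 1:10] = True
        skel = skeletonize3d(thick)
        res = analyze_skeleton(skel)
        # one connected path: exactly 2 endpoints, no branchpoints
        assert res.node_count == 2
        assert sorted(res.graph_degrees) == [1, 1]
        # endpoints near the rod end faces
        xs = np.argwhere(skel)[:, 2]
        assert xs.min() <= 2 and xs.max() >= 8

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            skeletonize3d(np.zeros((2, 2, 2), bool))


def skeleton_graph_oracle(coords):
    """Independent node/degree computation via an explicit graph.

    Builds the 26-adjacency graph, takes vertices of graph degree != 2 as
    nodes (isolated voxels included), removes them, and counts each residual
    chain (plus the far terminal node) once per incident node.
    """
    pts = [tuple(p) for p in coords]
    G = nx.Graph()
    G.add_nodes_from(pts)
    for a, b in itertools.combinations(pts, 2):
        if max(abs(a[0] - b[0]), abs(a[1] - b[1]), abs(a[2] - b[2])) == 1:
            G.add_edge(a, b)
    nodes = [v for v in G if G.degree(v) != 2]
    H = G.copy()
    H.remove_nodes_from(nodes)
    chains = [set(c) for c in nx.connected_components(H)]
    degrees = {}
    for v in nodes:
        total = 0
        for chain in chains:
            if any(G.has_edge(v, c) for c in chain):
                # interior voxels plus the node at the chain's far end
                far = set()
                for w in nodes:
                    if w != v and any(G.has_edge(w, c) for c in chain):
                        far.add(w)
                total += len(chain) + len(far)
        total += sum(1 for w in G.neighbors(v) if w in nodes)
        degrees[v] = total
    return len(nodes), sorted(degrees.values())


def grow_random_tree(rng, n_arms=4, max_len=6):
    """Grow a random skeleton tree in Z^3 whose 26-adjacency graph is exactly
    the intended tree: each new voxel touches only its chain predecessor."""
    pts = {(8, 8, 8)}
    ordered = [(8, 8, 8)]
    dirs = [d for d in itertools.product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]
    for _ in range(n_arms):
        for _attempt in range(50):
            start = ordered[int(rng.integers(len(ordered)))]
            d = dirs[int(rng.integers(len(dirs)))]
            arm = []
            cur = start
            for _step in range(int(rng.integers(2, max_len))):
                cur = (cur[0] + d[0], cur[1] + d[1], cur[2] + d[2])
                touching = {
                    p
                    for p in pts | set(arm)
                    if max(abs(p[0] - cur[0]), abs(p[1] - cur[1]), abs(p[2] - cur[2])) <= 1
                }
                prev = arm[-1] if arm else start
                if touching != {prev} or cur in pts:
                    arm = None
                    break
                arm.append(cur)
            if arm:
                pts.update(arm)
                ordered.extend(arm)
                break
    return np.array(sorted(pts))


class TestDetectNodes:
    def test_straight_path_two_endpoints_degree_nine(self):
        coords = np.array([(0, 0, x) for x in range(10)])
        n, degrees = detect_nodes(coords)
        assert n == 2
        assert degrees == [9, 9]

    def test_y_shape_four_nodes_branchpoint_degree_nine(self):
        # branchpoint at origin; three 3-voxel arms along corner diagonals,
        # the only unit directions that stay pairwise non-adjacent under
        # 26-adjacency
        coords = [(0, 0, 0)]
        for d in [(1, 1, 1), (-1, -1, 1), (1, -1, -1)]:
            coords += [(k * d[0], k * d[1], k * d[2]) for k in (1, 2, 3)]
        n, degrees = detect_nodes(np.array(coords) + 5)
        assert n == 4
        assert sorted(degrees) == [3, 3, 3, 9]

    def test_isolated_voxel_is_one_node_degree_zero(self):
        n, degrees = detect_nodes(np.array([[2, 2, 2]]))
        assert (n, degrees) == (1, [0])
        assert analyze_skeleton(np.array([[2, 2, 2]])).length_um == 0.0

    def test_random_trees_match_graph_oracle(self, rng):
        for _ in range(40):
            coords = grow_random_tree(rng)
            n, degrees = detect_nodes(coords)
            n_ref, degrees_ref = skeleton_graph_oracle(coords)
            assert n == n_ref
            assert sorted(degrees) == degrees_ref


class TestComponentShape:
    def test_2x2x2_cube(self):
        comp = MitoComponent(1, np.argwhere(np.ones((2, 2, 2), bool)))
        s = component_shape(comp, UNIT)
        assert (s.volume_vox, s.body_vox, s.surface_vox) == (8, 0, 8)

    def test_partition_identity_random_components(self, rng):
        for _ in range(50):
            mask = rng.random((4, 5, 5)) < 0.6
            if not mask.any():
                continue
            comp = MitoComponent(1, np.argwhere(mask))
            s = component_shape(comp, UNIT)
            assert s.surface_vox + s.body_vox == s.volume_vox == comp.voxel_count

    def test_rod_volume_and_length_with_anisotropic_geometry(self, geometry):
        comp = MitoComponent(1, np.array([(0, 0, x) for x in range(10)]))
        s = component_shape(comp, geometry)
        assert s.volume_um3 == pytest.approx(10 * 0.1 * 0.1 * 0.18)
        # 9 steps of dx = 0.1 along x
        assert s.skeleton_length_um == pytest.approx(0.9)

    def test_translation_and_rotation_invariance(self, rng):
        mask = rng.random((5, 6, 6)) < 0.5
        mask[2, 3, 3] = True
        coords = np.argwhere(mask)
        base = component_shape(MitoComponent(1, coords), UNIT)
        shifted = component_shape(MitoComponent(1, coords + [3, 7, 11]), UNIT)
        # translation leaves everything unchanged, skeleton included
        assert shifted.volume_vox == base.volume_vox
        assert shifted.surface_vox == base.surface_vox
        assert shifted.node_count == base.node_count
        assert shifted.skeleton_length_um == pytest.approx(base.skeleton_length_um)
        # erosion-based features are symmetric under axis-aligned rotation;
        # thinning is only approximately so and is not asserted here
        rotated_mask = np.rot90(mask, axes=(1, 2))  # 90 deg about z
        rotated = component_shape(MitoComponent(1, np.argwhere(rotated_mask)), UNIT)
        assert rotated.volume_vox == base.volume_vox
        assert rotated.surface_vox == base.surface_vox
        assert rotated.body_vox == base.body_vox


class TestGanglionFeatures:
    def test_volume_arithmetic(self, geometry):
        mask = np.zeros((10, 10, 10), bool)
        mask.ravel()[:1000] = True
        assert ganglion_volume(mask, geometry) == pytest.approx(1.8)
        double_z = VoxelGeometry(0.1, 0.1, 0.36)
        assert ganglion_volume(mask, double_z) == pytest.approx(3.6)
        with pytest.raises(ValueError):
            ganglion_volume(np.zeros((2, 2, 2), bool), geometry)

    def test_feature_arithmetic(self):
        from mitoganglia.morphometrics import ComponentShape

        def shape(vol):
            return ComponentShape(10, vol, 8, 2, 5, 0.5, 2, [4, 4], [1, 1])

        feats = ganglion_features([shape(0.01), shape(0.03)], 10.0)
        assert feats["MitoCount"] == pytest.approx(0.2)
        assert feats["MitoVolumeTotal"] == pytest.approx(0.004)
        assert feats["MitoVolumeMean"] == pytest.approx(0.02)
        # doubling object volumes doubles means/totals, leaves count alone
        feats2 = ganglion_features([shape(0.02), shape(0.06)], 10.0)
        assert feats2["MitoVolumeMean"] == pytest.approx(0.04)
        assert feats2["MitoVolumeTotal"] == pytest.approx(0.008)
        assert feats2["MitoCount"] == feats["MitoCount"]

    def test_empty_ganglion_contract(self):
        feats = ganglion_features([], 5.0)
        assert feats["MitoCount"] == 0.0 and feats["MitoVolumeTotal"] == 0.0
        assert np.isnan(feats["MitoVolumeMean"])
        assert np.isnan(feats["MitoNodesMean"])
        with pytest.raises(ValueError):
            ganglion_features([], 0.0)
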
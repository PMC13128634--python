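import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import splatphen as sp
from splatphen.cluster import (ClusterFeatures, build_descriptors, default_min_samples,
                               nn_retain, optics_cluster_merge, robust_z)

from conftest import random_splats


class TestRobustZ:
    def test_hand_computed_oracle(self):
        z, flag = robust_z([1.0, 2.0, 3.0])
        assert np.allclose(z, [-1, 0, 1])
        assert not flag

    def test_constant_sequence_flagged(self):
        z, flag = robust_z(np.full(7, 4.2))
        assert np.all(z == 0) and flag

    @given(a=st.floats(0.1, 50), b=st.floats(-100, 100))
    @settings(max_examples=30, deadline=None)
    def test_affine_invariance(self, a, b):
        x = np.array([0.3, 1.7, -2.0, 5.5, 0.9])
        z1, _ = robust_z(x)
        z2, _ = robust_z(a * x + b)
        assert np.allclose(z1, z2, atol=1e-9)

    def test_median_zero_mad_one(self, rng):
        for _ in range(100):
            z, flag = robust_z(rng.normal(rng.uniform(-5, 5), rng.uniform(0.1, 10), 51))
            assert not flag
            assert abs(np.median(z)) < 1e-9
            assert abs(np.median(np.abs(z - np.median(z))) - 1) < 1e-9

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            robust_z([1.0, np.inf])


class TestDescriptors:
    def test_single_camera_distance(self):
        splats = sp.SplatSet(positions=[[0, 0, 2.0]], log_scales=[[-3] * 3],
                             rotations=[[1, 0, 0, 0]], opacity_logits=[0.0],
                             dc_color=[[0, 0, 0]])
        cam = sp.CameraView(intrinsics=[[50, 0, 16], [0, 50, 12], [0, 0, 1]],
                            rotation=np.eye(3), translation=np.zeros(3), image_size=(32, 24))
        feat = build_descriptors(np.array([0]), splats, [cam])
        assert feat.mean_cam_dist[0] == pytest.approx(2.0)

    def test_two_camera_symmetry(self):
        splats = sp.SplatSet(positions=[[0, 0, 0.0]], log_scales=[[-3] * 3],
                             rotations=[[1, 0, 0, 0]], opacity_logits=[0.0],
                             dc_color=[[0, 0, 0]])
        cams = [sp.look_at_camera([sgn, 0, 0], [0, 0, 0], fx=50, image_size=(32, 24))
                for sgn in (-1.0, 1.0)]
        feat = build_descriptors(np.array([0]), splats, cams)
        assert feat.mean_cam_dist[0] == pytest.approx(1.0)

    def test_collinear_foreground_standardized(self, rng):
        splats = random_splats(rng, n=3)
        splats.positions[:] = [[0, 0, 0], [1, 0, 0], [2, 0, 0]]
        cam = sp.look_at_camera([1, 0, -5.0], [1, 0, 0], fx=50, image_size=(64, 48))
        feat = build_descriptors(np.arange(3), splats, [cam])
        assert np.allclose(sorted(feat.descriptor[:, 0]), [-1, 0, 1])


def _features_from_points(points, cam_dist=None):
    points = np.asarray(points, dtype=np.float64)
    cols = [robust_z(points[:, i])[0] for i in range(3)]
    d = np.full(len(points), 1.0) if cam_dist is None else np.asarray(cam_dist, float)
    cols.append(robust_z(d)[0])
    return ClusterFeatures(descriptor=np.stack(cols, axis=1), mean_cam_dist=d,
                           visible_cams=[np.array([0])] * len(points),
                           foreground=np.arange(len(points)))


class TestOpticsMerge:
    def test_cued_blob_selected_far_blob_dropped(self, rng):
        a = rng.normal(0, 0.05, (120, 3))
        b = rng.normal(0, 0.05, (120, 3)) + [12, 0, 0]
        depths = np.concatenate([np.full(120, 1.0), np.full(120, 2.0)])  # 100% apart
        feat = _features_from_points(np.vstack([a, b]), depths)
        support = np.concatenate([np.full(120, 0.9), np.full(120, 0.1)])
        out = optics_cluster_merge(feat, support, min_samples=20)
        assert set(out.kept) <= set(range(120))
        assert len(out.kept) >= 100

    def test_adjacent_equal_depth_subclusters_merge(self, rng):
        # one blob OPTICS may split; equal depths and close centroids merge back
        a = rng.normal(0, 0.3, (150, 3))
        b = rng.normal(0, 0.3, (150, 3)) + [0.5, 0, 0]
        feat = _features_from_points(np.vstack([a, b]))
        support = np.full(300, 0.5)
        out = optics_cluster_merge(feat, support, min_samples=20)
        assert len(out.kept) == 300  # everything retained (single or merged clusters)

    def test_merge_rules_on_explicit_clusters(self, rng):
        """Direct check of the centroid-P90 and 15%-depth merge rules."""
        from splatphen.cluster import merge_clusters

        sel = rng.normal(0, 0.5, (200, 3))
        near_same_depth = rng.normal(0, 0.05, (50, 3)) + [0.3, 0, 0]
        near_deep = rng.normal(0, 0.05, (50, 3)) + [0.3, 0, 0]
        far = rng.normal(0, 0.05, (50, 3)) + [50, 0, 0]
        pts = np.vstack([sel, near_same_depth, near_deep, far])
        depths = np.concatenate([np.full(200, 1.0), np.full(50, 1.0),
                                 np.full(50, 1.5), np.full(50, 1.0)])
        feat = ClusterFeatures(descriptor=np.column_stack([pts, np.zeros(len(pts))]),
                               mean_cam_dist=depths,
                               visible_cams=[np.array([0])] * len(pts),
                               foreground=np.arange(len(pts)))
        labels = np.concatenate([np.full(200, 0), np.full(50, 1),
                                 np.full(50, 2), np.full(50, 3)])
        keep, logm = merge_clusters(feat, labels, selected=0)
        reasons = dict(logm)
        assert keep[:250].all()          # near cluster, same depth: merged
        assert not keep[250:300].any()   # depth ratio 0.5 >= 0.15: blocked
        assert not keep[300:].any()      # centroid beyond P90: blocked
        assert reasons[1].startswith("merged")
        assert reasons[2].startswith("dropped")
        assert reasons[3].startswith("dropped")

    def test_min_samples_default(self):
        assert default_min_samples(100) == 15
        assert default_min_samples(10_000) == 50


class TestNNRetain:
    def _scene(self, positions):
        n = len(positions)
        return sp.SplatSet(positions=positions, log_scales=np.full((n, 3), -3.0),
                           rotations=np.tile([1.0, 0, 0, 0], (n, 1)),
                           opacity_logits=np.zeros(n), dc_color=np.zeros((n, 3)))

    def test_radius_boundary(self):
        # kept pair with spacing 1 -> d_1nn = 1, r_nr = 2
        pos = np.array([[0, 0, 0], [1, 0, 0], [2.9, 0, 0], [3.1, 0, 0.0]])
        scene = self._scene(pos)
        kept = nn_retain(np.array([0, 1]), scene, beta=2.0)
        assert 2 in kept      # at distance 1.9 from splat 1
        assert 3 not in kept  # at distance 2.1

    def test_grid_hole_restored_far_splat_not(self):
        grid = np.array([[i, j, 0.0] for i in range(5) for j in range(5)])
        hole = 12  # interior point
        far = np.array([[10.0, 10.0, 0.0]])
        scene = self._scene(np.vstack([grid, far]))
        kept = np.setdiff1d(np.arange(25), [hole])
        out = nn_retain(kept, scene, beta=2.0)
        # brute-force oracle
        d1nn = np.median([np.min([np.linalg.norm(grid[i] - grid[j])
                                  for j in kept if j != i]) for i in kept])
        assert hole in out
        assert 25 not in out
        assert d1nn == 1.0

    def test_single_pass_no_chaining(self):
        # chain 0-1 kept; 2 within r of 1; 3 within r of 2 but not of kept
        pos = np.array([[0, 0, 0], [1, 0, 0], [2.5, 0, 0], [4.2, 0, 0.0]])
        scene = self._scene(pos)
        out = nn_retain(np.array([0, 1]), scene, beta=2.0)
        assert 2 in out and 3 not in out
        # second pass with the same original kept set adds the same splats
        out2 = nn_retain(np.array([0, 1]), scene, beta=2.0)
        assert np.array_equal(out, out2)

    def test_tiny_kept_skipped(self, caplog):
        scene = self._scene(np.array([[0, 0, 0], [1, 0, 0.0]]))
        out = nn_retain(np.array([0]), scene)
        assert np.array_equal(out, [0])


def test_clustering_invariant_to_translation_and_scaling(rng, suite):
    """Translation + uniform scaling of the scene (cameras included) leaves
    the standardized descriptors and the selected set unchanged.

    (Per-axis median/MAD standardization is equivariant to axis-aligned
    similarity transforms; a general rotation re-mixes the axes.)
    """
    bundle, cues, lift = suite[0]
    fg = sp.foreground_select(lift, 0.88)
    feat1 = build_descriptors(fg, bundle.scene, bundle.cameras)
    out1 = optics_cluster_merge(feat1, lift.support)

    scale = 3.7
    shift = np.array([5.0, -2.0, 1.0])
    scene2 = sp.SplatSet(
        positions=scale * bundle.scene.positions + shift,
        log_scales=bundle.scene.log_scales + np.log(scale),
        rotations=bundle.scene.rotations, opacity_logits=bundle.scene.opacity_logits,
        dc_color=bundle.scene.dc_color)
    cams2 = []
    for v in bundle.cameras:
        c2 = scale * v.center + shift
        cams2.append(sp.CameraView(v.intrinsics, v.rotation, -v.rotation @ c2,
                                   v.image_size, sharpness=v.sharpness,
                                   view_index=v.view_index))
    feat2 = build_descriptors(fg, scene2, cams2)
    out2 = optics_cluster_merge(feat2, lift.support)
    assert np.allclose(feat1.descriptor, feat2.descriptor, atol=1e-6)
    assert set(out1.kept) == set(out2.kept)
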
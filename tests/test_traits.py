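import numpy as np
import pytest

import splatphen as sp
from splatphen.geometry import alpha_shape_area, farthest_point_sample
from splatphen.traits import MetricFrame, internode_stats, leaf_area


def test_plot_area_from_canopy_diameter():
    assert round(sp.plot_area_from_diameter(0.214), 3) == 0.036


class TestMetricScaleAlign:
    def test_scale_ratio(self, rng):
        pts = rng.normal(0, 1, (200, 3))
        ref = np.array([[0, 0, 0], [0.5, 0, 0.0]])
        _, frame = sp.metric_scale_align(pts, ref, 0.42,
                                         alignment=MetricFrame(1.0, np.eye(3), np.zeros(3)))
        assert frame.scale_s == pytest.approx(1.0)  # provided frame reused
        _, frame2 = sp.metric_scale_align(pts, ref, 0.42)
        assert frame2.scale_s == pytest.approx(0.84)

    def test_estimated_rotation_near_identity_on_aligned_scene(self, small_scene):
        scene = small_scene.scene
        ref = scene.positions[small_scene.ref_pair_index]
        _, frame = sp.metric_scale_align(scene.positions, ref, 0.42)
        angle = np.degrees(np.arccos(np.clip((np.trace(frame.rotation_R) - 1) / 2, -1, 1)))
        assert angle < 1.0

    def test_idempotence_on_aligned_scene(self, rng):
        pts = rng.normal(0, 1, (300, 3))
        pts[:, 2] = np.abs(pts[:, 2])
        ground = rng.uniform(-2, 2, (100, 3)) * [1, 1, 0]
        allpts = np.vstack([ground, pts])
        ref = np.array([[0, 0, 0], [1, 0, 0.0]])
        aligned, frame = sp.metric_scale_align(allpts, ref, 1.0)
        ref2 = aligned[[0, 1]]
        ref2 = np.array([[0, 0, 0], [1, 0, 0.0]])
        again, frame2 = sp.metric_scale_align(aligned, ref2, 1.0)
        assert np.abs(again - aligned).max() < 1e-6

    def test_coincident_reference_rejected(self, rng):
        with pytest.raises(ValueError, match="coincident"):
            sp.metric_scale_align(rng.normal(0, 1, (60, 3)),
                                  np.zeros((2, 3)), 0.42)

    def test_scale_covariance_of_traits(self, rng):
        """Scaling the scene and the reference together leaves metric output fixed."""
        pts = rng.normal(0, 1, (200, 3))
        ref = np.array([[0, 0, 0], [0.5, 0, 0.0]])
        frame_a = sp.metric_scale_align(pts, ref, 0.42)[1]
        frame_b = sp.metric_scale_align(3 * pts, 3 * ref, 0.42)[1]
        assert np.allclose(frame_a.apply(pts), frame_b.apply(3 * pts), atol=1e-9)


class TestPlantHeight:
    def test_apex_recovered(self, rng):
        pts = rng.uniform(-0.1, 0.1, (500, 3))
        pts[:, 2] = rng.uniform(0, 0.39, 500)
        pts[0] = [0, 0, 0.40]
        cell = 0.01
        h = sp.plant_height(pts, cell=cell)
        assert h == pytest.approx(0.40, abs=0.5 * cell)

    def test_opening_suppresses_spurious_peaks(self, rng):
        # smooth canopy dome with apex plateau at 0.40 m + 5 isolated high outliers
        xy = rng.uniform(-0.1, 0.1, (3000, 2))
        r2 = (xy**2).sum(axis=1)
        z = np.clip(0.40 * (1 - r2 / 0.02), 0, None)
        pts = np.column_stack([xy, z])
        spurious = np.array([[0.3 + 0.05 * i, 0.3, 0.50] for i in range(5)])
        noisy = np.vstack([pts, spurious])
        cell = 0.01
        h = sp.plant_height(noisy, cell=cell, operator="opening")
        assert h == pytest.approx(0.40, abs=2 * cell)
        # the default closing operator keeps the bright peak
        assert sp.plant_height(noisy, cell=cell, operator="closing") >= 0.49

    def test_single_point(self):
        assert sp.plant_height(np.array([[0, 0, 0.27]])) == pytest.approx(0.27)


class TestAlphaShape:
    def test_unit_disc_area(self, rng):
        u = rng.uniform(0, 1, 5000)
        theta = rng.uniform(0, 2 * np.pi, 5000)
        pts = np.stack([np.sqrt(u) * np.cos(theta), np.sqrt(u) * np.sin(theta)], axis=1)
        area = alpha_shape_area(pts, alpha=10.0)
        assert area == pytest.approx(np.pi, rel=0.03)

    def test_small_alpha_carves_voids(self, rng):
        # two separated clusters: large alpha bridges, small alpha does not
        a = rng.uniform(0, 1, (300, 2))
        b = rng.uniform(0, 1, (300, 2)) + [5, 0]
        pts = np.vstack([a, b])
        assert alpha_shape_area(pts, alpha=0.3) < alpha_shape_area(pts, alpha=100.0) / 2

    def test_degenerate_inputs(self):
        assert alpha_shape_area(np.zeros((2, 2)), 1.0) == 0.0
        assert alpha_shape_area(np.array([[0, 0], [1, 1], [2, 2.0]]), 1.0) == 0.0


class TestLeafArea:
    def test_flat_disc_recovered_within_15pct(self, small_scene):
        bundle = small_scene
        tgt = bundle.target_index
        leaf_ids = bundle.gt_leaf_id[tgt]
        errors = []
        for j, true_area in enumerate(np.asarray(bundle.gt_traits.per_leaf_areas_cm2) / 1e4):
            members = tgt[(bundle.gt_organ_class[tgt] == "leaf") & (leaf_ids == j)]
            est = leaf_area(bundle.scene, members) / bundle.recipe.recon_scale**2
            errors.append(abs(est / true_area - 1))
        assert np.mean(errors) < 0.15

    def test_collinear_members_zero(self, rng):
        splats = sp.SplatSet(positions=[[i, 0, 0] for i in range(5)],
                             log_scales=np.full((5, 3), -8.0),
                             rotations=np.tile([1.0, 0, 0, 0], (5, 1)),
                             opacity_logits=np.ones(5), dc_color=np.zeros((5, 3)))
        assert leaf_area(splats, np.arange(5)) == 0.0

    def test_lai_is_lsa_over_plot_area(self, small_scene):
        bundle = small_scene
        tgt = bundle.target_index
        leaves = [tgt[(bundle.gt_organ_class[tgt] == "leaf") & (bundle.gt_leaf_id[tgt] == j)]
                  for j in range(bundle.gt_traits.leaf_count)]
        areas, lsa, lai = sp.leaf_area_lai(bundle.scene, leaves, a_plot_m2=0.036)
        assert lai == pytest.approx(lsa / 0.036)
        assert all(a >= 0 for a in areas)


class TestLeafCount:
    def test_fragment_merge(self):
        count, groups = sp.leaf_count([5e-4, 5e-4], np.array([[0, 0, 0], [0.004, 0, 0]]),
                                      d_med=0.01)
        assert count == 1

    def test_small_speck_removed(self):
        count, _ = sp.leaf_count([0.5e-4], np.array([[0, 0, 0.0]]), d_med=0.01)
        assert count == 0

    def test_distinct_leaves_kept(self):
        areas = [30e-4] * 7
        cents = np.array([[0.1 * i, 0, 0.0] for i in range(7)])
        count, _ = sp.leaf_count(areas, cents, d_med=0.01)
        assert count == 7


class TestStemSkeleton:
    def _cylinder(self, rng, n=600, radius=0.01, height=0.5):
        theta = rng.uniform(0, 2 * np.pi, n)
        r = radius * np.sqrt(rng.uniform(0, 1, n))
        z = rng.uniform(0, height, n)
        return np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)

    def test_straight_cylinder_nodes_near_axis(self, rng):
        # kNN-mean contraction has a radial noise floor ~ r/sqrt(k); nodes
        # land well inside the cylinder but not exactly on the axis
        pts = self._cylinder(rng)
        nodes = sp.stem_skeleton(pts, k=40)
        resid = np.linalg.norm(nodes[:, :2], axis=1)
        assert np.max(resid) < 0.5 * 0.01
        assert np.mean(resid) < 0.25 * 0.01

    def test_contraction_shrinks_variance(self, rng):
        pts = self._cylinder(rng)
        prev = np.var(pts, axis=0).sum()
        from scipy.spatial import cKDTree
        cur = pts.copy()
        for _ in range(5):
            tree = cKDTree(cur)
            _, nbr = tree.query(cur, k=13)
            cur = 0.5 * cur + 0.5 * cur[nbr].mean(axis=1)
            v = np.var(cur, axis=0).sum()
            assert v <= prev
            prev = v

    def test_lambda_zero_is_farthest_point_subsample(self, rng):
        pts = self._cylinder(rng, n=100)
        nodes = sp.stem_skeleton(pts, lam=0.0, node_spacing=0.05)
        expected = pts[farthest_point_sample(pts, 0.05)]
        assert np.allclose(np.sort(nodes, axis=0), np.sort(expected, axis=0))

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            sp.stem_skeleton(np.zeros((5, 3)))


class TestInternodeStats:
    def _branched_stem(self, n_branches=5, spacing=0.05):
        nodes = [[0, 0, 0.01 * i] for i in range(int(n_branches * spacing / 0.01) + 3)]
        hints = []
        for b in range(n_branches):
            z = (b + 1) * spacing
            for k in range(1, 4):
                nodes.append([0.012 * k, 0, z])
            hints.append([0.05, 0, z])
        return np.asarray(nodes, dtype=float), np.asarray(hints)

    def test_straight_stem_equal_internodes(self):
        nodes, hints = self._branched_stem(5, 0.05)
        count, lengths = internode_stats(nodes, attachment_hints=hints)
        assert count == 5
        assert len(lengths) == 4
        assert np.allclose(lengths, 0.05, rtol=0.10)

    def test_curved_stem_geodesic_exceeds_chord(self):
        # quarter arc of radius r; side branches in +y at two interior
        # vertices define the junction pair
        r = 0.3
        t = np.linspace(0, np.pi / 2, 60)
        axis = np.stack([r * np.cos(t), np.zeros_like(t), r * np.sin(t)], axis=1)
        j1, j2 = 5, 54
        branches = [axis[j] + np.array([0, 0.02 * k, 0.0])
                    for j in (j1, j2) for k in range(1, 4)]
        nodes = np.vstack([axis, branches])
        count, lengths = internode_stats(nodes)
        arc = r * (t[j2] - t[j1])
        chord = np.linalg.norm(axis[j2] - axis[j1])
        assert count == 2
        assert lengths[0] > chord
        assert lengths[0] == pytest.approx(arc, rel=0.05)

    def test_no_branches_no_nodes(self):
        nodes = np.array([[0, 0, 0.01 * i] for i in range(20)], dtype=float)
        count, lengths = internode_stats(nodes)
        assert count == 0 and lengths == []

    def test_scale_applied(self):
        nodes, hints = self._branched_stem(3, 0.05)
        _, l1 = internode_stats(nodes, attachment_hints=hints, scale_s=1.0)
        _, l2 = internode_stats(nodes, attachment_hints=hints, scale_s=2.0)
        assert np.allclose(np.asarray(l2), 2 * np.asarray(l1))


def test_trait_recovery_on_synthetic_plants(suite):
    """Height/leaf count/internode/LSA recovered from labeled organs."""
    h_err, lsa_err, int_err, leaf_exact, node_exact = [], [], [], 0, 0
    for bundle, _, _ in suite:
        scene = bundle.scene
        ref = scene.positions[bundle.ref_pair_index]
        _, frame = sp.metric_scale_align(scene.positions, ref, 0.42)
        aligned = frame.apply_splats(scene)
        tgt = bundle.target_index
        stem = tgt[bundle.gt_organ_class[tgt] == "stem"]
        leaves = [tgt[(bundle.gt_organ_class[tgt] == "leaf") & (bundle.gt_leaf_id[tgt] == j)]
                  for j in range(bundle.gt_traits.leaf_count)]
        rec = sp.compute_traits(aligned, stem, leaves)
        gt = bundle.gt_traits
        h_err.append(abs(rec.height_cm / gt.height_cm - 1))
        lsa_err.append(abs(rec.lsa_cm2 / gt.lsa_cm2 - 1))
        int_err.append(abs(rec.mean_internode_cm / gt.mean_internode_cm - 1))
        leaf_exact += rec.leaf_count == gt.leaf_count
        node_exact += rec.node_count == gt.node_count
    assert max(h_err) < 0.03
    assert leaf_exact >= 4
    assert max(int_err) < 0.10
    assert max(lsa_err) < 0.15
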
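import numpy as np
import pytest

import splatphen as sp
from splatphen.organs import (NormalizedCloud, mean_knn_spacing, remap_to_splats,
                              toy_geometric_classifier)


class TestNormalizeCloud:
    def test_already_at_target_spacing_is_identity(self, rng):
        pts = rng.normal(0, 1, (200, 3))
        s = mean_knn_spacing(pts, 8)
        cloud = sp.normalize_cloud(pts, delta=s)
        assert np.allclose(cloud.points, pts, atol=1e-9)

    def test_unit_grid_halved(self):
        grid = np.array([[i, j, k] for i in range(4) for j in range(4) for k in range(4)],
                        dtype=float)
        cloud = sp.normalize_cloud(grid, k=6, delta=0.5 * mean_knn_spacing(grid, 6))
        d = np.linalg.norm(cloud.points[0] - cloud.points[-1])
        assert d == pytest.approx(0.5 * np.linalg.norm(grid[0] - grid[-1]))

    def test_translation_equivariance(self, rng):
        pts = rng.normal(0, 1, (100, 3))
        c1 = sp.normalize_cloud(pts)
        c2 = sp.normalize_cloud(pts + [10, -5, 3])
        assert np.allclose(c2.points - c2.centroid_c, c1.points - c1.centroid_c, atol=1e-9)

    def test_inverse_round_trip(self, rng):
        pts = rng.normal(0, 1, (100, 3))
        cloud = sp.normalize_cloud(pts)
        assert np.allclose(cloud.to_world(), pts, atol=1e-9)

    def test_duplicated_cloud_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            sp.normalize_cloud(np.zeros((20, 3)))


def _cloud(points, delta=0.02):
    points = np.asarray(points, dtype=np.float64)
    return NormalizedCloud(points=points, centroid_c=np.median(points, axis=0),
                           spacing_s=delta, delta=delta)


class TestGroupInstances:
    def test_separated_blobs_and_internal_gap(self, rng):
        r = 2.5 * 0.02
        a = rng.normal(0, 0.005, (60, 3))
        b = rng.normal(0, 0.005, (60, 3)) + [10 * r, 0, 0]
        cloud = _cloud(np.vstack([a, b]))
        classes = np.array(["leaf"] * 120)
        logits = np.tile([0.1, 0.9], (120, 1))
        inst = sp.group_instances(cloud, classes, logits, min_points=10)
        assert len(inst) == 2
        # bridge the gap with points spaced < r -> single instance
        bridge = np.linspace([0, 0, 0], [10 * r, 0, 0], 30)
        cloud2 = _cloud(np.vstack([a, b, bridge]))
        inst2 = sp.group_instances(cloud2, np.array(["leaf"] * 150),
                                   np.tile([0.1, 0.9], (150, 1)), min_points=10)
        assert len(inst2) == 1

    @pytest.mark.parametrize("seed", [3, 13, 23, 33, 43])
    def test_matches_brute_force_components(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.uniform(0, 1, (500, 3)) * [1, 1, 0.3]
        classes = np.where(rng.random(500) < 0.5, "stem", "leaf")
        logits = rng.normal(0, 1, (500, 2))
        cloud = _cloud(pts, delta=0.02)
        inst = sp.group_instances(cloud, classes, logits, gamma=2.5, min_points=1)
        # brute-force all-pairs connected components, per class
        import networkx as nx
        r = 2.5 * 0.02
        expected = []
        for cname in ("stem", "leaf"):
            members = np.nonzero(classes == cname)[0]
            g = nx.Graph()
            g.add_nodes_from(members)
            for ii, i in enumerate(members):
                for j in members[ii + 1:]:
                    if np.linalg.norm(pts[i] - pts[j]) <= r:
                        g.add_edge(i, j)
            expected.extend(frozenset(c) for c in nx.connected_components(g))
        got = {frozenset(map(int, o.member_ids)) for o in inst}
        assert got == set(expected)

    def test_permutation_invariance(self, rng):
        pts = rng.uniform(0, 1, (200, 3))
        classes = np.array(["leaf"] * 200)
        logits = rng.normal(0, 1, (200, 2))
        cloud = _cloud(pts)
        inst1 = sp.group_instances(cloud, classes, logits, min_points=1)
        perm = rng.permutation(200)
        inst2 = sp.group_instances(_cloud(pts[perm]), classes[perm], logits[perm],
                                   min_points=1)
        sets1 = {frozenset(map(int, o.member_ids)) for o in inst1}
        sets2 = {frozenset(int(perm[i]) for i in o.member_ids) for o in inst2}
        assert sets1 == sets2

    def test_large_gamma_single_instance_per_class(self, rng):
        pts = rng.uniform(0, 1, (100, 3))
        classes = np.where(np.arange(100) < 50, "stem", "leaf")
        logits = np.ones((100, 2))
        inst = sp.group_instances(_cloud(pts), classes, logits, gamma=1e4, min_points=1)
        assert sorted(o.semantic_class for o in inst) == ["leaf", "stem"]

    def test_unknown_class_rejected(self, rng):
        cloud = _cloud(rng.uniform(0, 1, (10, 3)))
        with pytest.raises(ValueError, match="unknown class"):
            sp.group_instances(cloud, np.array(["fruit"] * 10), np.ones((10, 2)))

    def test_confidence_is_mean_winning_logit(self, rng):
        pts = rng.normal(0, 0.001, (40, 3))
        logits = np.tile([0.2, 0.7], (40, 1))
        inst = sp.group_instances(_cloud(pts), np.array(["leaf"] * 40), logits,
                                  min_points=1)
        assert inst[0].confidence == pytest.approx(0.7)


class TestRemap:
    def _plant(self, seed=4):
        bundle = sp.make_scene(sp.SceneRecipe(n_neighbors=0, cameras_per_pass=5,
                                              position_jitter_m=0.0, color_bleed=0.0),
                               seed=seed)
        tgt = bundle.target_index
        return bundle, bundle.scene.subset(tgt), tgt

    def test_noiseless_full_assignment_matches_gt(self):
        bundle, plant, tgt = self._plant()
        pts, _, src = sp.export_point_cloud(plant, np.arange(len(plant)), rng_seed=0)
        cloud = sp.normalize_cloud(pts)
        # semantics for cloud points from generator organ labels of source splats
        organ = bundle.gt_organ_class[tgt]
        leaf = bundle.gt_leaf_id[tgt]
        pos_of_id = {pid: i for i, pid in enumerate(plant.ids)}
        rows = np.array([pos_of_id[s] for s in src])
        classes = organ[rows]
        logits = np.where(classes[:, None] == "stem", [5.0, 0.0], [0.0, 5.0])
        instances = []
        iid = 0
        for cname in ("stem", "leaf"):
            if cname == "stem":
                members = np.nonzero(classes == "stem")[0]
                instances.append(sp.OrganInstance("stem", members, 5.0, iid))
                iid += 1
            else:
                for lid in np.unique(leaf[rows][classes == "leaf"]):
                    members = np.nonzero((classes == "leaf") & (leaf[rows] == lid))[0]
                    instances.append(sp.OrganInstance("leaf", members, 5.0, iid))
                    iid += 1
        result = remap_to_splats(instances, cloud, plant, alpha_r=3.0)
        visible = result.visible
        assert len(result.unassigned) == 0
        assert np.all(result.splat_class[visible] == organ[visible])

    def test_alpha_r_zero_all_unassigned(self):
        bundle, plant, tgt = self._plant()
        pts, _, _ = sp.export_point_cloud(plant, np.arange(len(plant)), rng_seed=0)
        cloud = sp.normalize_cloud(pts)
        inst = [sp.OrganInstance("stem", np.arange(len(pts)), 1.0, 0)]
        result = remap_to_splats(inst, cloud, plant, alpha_r=1e-12)
        assert len(result.unassigned) == len(result.visible)

    def test_opacity_threshold_strict(self):
        splats = sp.SplatSet(positions=np.random.default_rng(0).normal(0, 1, (20, 3)),
                             log_scales=np.full((20, 3), -3.0),
                             rotations=np.tile([1.0, 0, 0, 0], (20, 1)),
                             opacity_logits=np.zeros(20), dc_color=np.zeros((20, 3)))
        tau = 0.5  # sigmoid(0) == 0.5 exactly -> excluded
        with pytest.raises(ValueError, match="no visible"):
            remap_to_splats([], sp.normalize_cloud(splats.positions), splats, tau_op=tau)

    def test_assigned_union_unassigned_is_visible(self):
        bundle, plant, tgt = self._plant(seed=5)
        pts, _, _ = sp.export_point_cloud(plant, np.arange(len(plant)), rng_seed=0)
        cloud = sp.normalize_cloud(pts)
        inst = [sp.OrganInstance("leaf", np.arange(100), 1.0, 0)]
        result = remap_to_splats(inst, cloud, plant, alpha_r=1.0)
        assigned = result.visible[result.splat_instance[result.visible] >= 0]
        assert set(assigned) | set(result.unassigned) == set(result.visible)
        assert set(assigned) & set(result.unassigned) == set()


def test_toy_classifier_separates_stem_and_leaf(small_scene):
    bundle = small_scene
    tgt = bundle.target_index
    plant = bundle.scene.subset(tgt)
    pts, _, src = sp.export_point_cloud(plant, np.arange(len(plant)), rng_seed=0)
    classes, logits = toy_geometric_classifier(pts)
    gt = bundle.gt_organ_class[tgt]
    pos_of_id = {pid: i for i, pid in enumerate(plant.ids)}
    rows = np.array([pos_of_id[s] for s in src])
    acc = np.mean(classes == gt[rows])
    assert acc > 0.6  # geometric heuristic, far above chance
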
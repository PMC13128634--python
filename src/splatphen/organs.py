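"""Organ instance grouping and splat remapping.

The per-plant point cloud exported from the Gaussian subset is first
density-normalized so that grouping radii transfer across scenes:

    x' = c + (x - c) * Delta / s,

with c the per-axis median centroid and s the median mean-k-NN spacing.
Given externally provided per-point semantics (stem/leaf class + logits --
a trained point network upstream, or the toy geometric classifier below for
demos), each class is partitioned into connected components under a fixed
linking radius r = gamma * Delta (breadth-first search over the radius
graph).  Instance confidence is the mean winning-class logit over members.

Labels are remapped back to the Gaussian subset: each visible splat
(sigmoid(omega) > tau_op) inherits the labels of its nearest labeled point
within r_assign = alpha_r * d_med (d_med = median nearest-neighbor spacing
among visible splats, world frame), after which the strict chromatic filter
(zeta = 0.80) is reapplied per labeled set to drop chromatic outliers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .refine import DEFAULT_ZETA, chroma_filter, fit_color_gmm, rgb_to_lab
from .splats import SplatSet, derived_params, sigmoid

log = logging.getLogger(__name__)

SEMANTIC_CLASSES = ("stem", "leaf")

DEFAULT_DELTA = 0.02
DEFAULT_K = 8
DEFAULT_GAMMA = 2.5
DEFAULT_MIN_POINTS = 30
DEFAULT_TAU_OP = 0.05
DEFAULT_ALPHA_R = 3.0


@dataclass
class NormalizedCloud:
    points: np.ndarray        # (N, 3) normalized coordinates
    centroid_c: np.ndarray    # (3,) median centroid of the raw cloud
    spacing_s: float          # median mean-kNN spacing of the raw cloud
    delta: float              # target spacing

    def to_world(self, pts: np.ndarray | None = None) -> np.ndarray:
        """Invert the normalization (defaults to the stored points)."""
        pts = self.points if pts is None else np.asarray(pts)
        return self.centroid_c + (pts - self.centroid_c) * (self.spacing_s / self.delta)


@dataclass
class OrganInstance:
    semantic_class: str
    member_ids: np.ndarray    # point indices into the cloud
    confidence: float         # mean winning-class logit
    instance_id: int

    def __len__(self):
        return len(self.member_ids)


@dataclass
class RemapResult:
    splat_class: np.ndarray       # (N,) class string or "" for unassigned
    splat_instance: np.ndarray    # (N,) instance id or -1
    splat_confidence: np.ndarray  # (N,)
    visible: np.ndarray           # positional indices of visible splats
    unassigned: np.ndarray        # visible splats with no label in range
    chroma_dropped: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))


def mean_knn_spacing(points: np.ndarray, k: int = DEFAULT_K) -> float:
    """Median over points of the mean distance to their k nearest neighbors."""
    tree = cKDTree(points)
    d, _ = tree.query(points, k=k + 1)
    return float(np.median(d[:, 1:].mean(axis=1)))


def normalize_cloud(points: np.ndarray, k: int = DEFAULT_K,
                    delta: float = DEFAULT_DELTA) -> NormalizedCloud:
    """Rescale a cloud about its median centroid to target spacing ``delta``."""
    points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    if len(points) < k + 1:
        raise ValueError(f"need at least {k + 1} points")
    s = mean_knn_spacing(points, k)
    if s == 0:
        raise ValueError("degenerate cloud: zero median spacing (duplicated points)")
    c = np.median(points, axis=0)
    return NormalizedCloud(points=c + (points - c) * (delta / s),
                           centroid_c=c, spacing_s=s, delta=delta)


def group_instances(cloud: NormalizedCloud, classes: np.ndarray, logits: np.ndarray,
                    gamma: float = DEFAULT_GAMMA,
                    min_points: int = DEFAULT_MIN_POINTS) -> list[OrganInstance]:
    """Radius-BFS instance grouping per semantic class.

    ``classes`` holds one of the known semantic class names per point;
    ``logits`` is (N, n_classes) in SEMANTIC_CLASSES order.  Points of class
    k are linked when closer than r = gamma * Delta; connected components
    with at least ``min_points`` members become instances.
    """
    classes = np.asarray(classes)
    logits = np.asarray(logits, dtype=np.float64)
    if len(classes) != len(cloud.points):
        raise ValueError("semantics length must match the cloud")
    unknown = set(np.unique(classes)) - set(SEMANTIC_CLASSES)
    if unknown:
        raise ValueError(f"unknown class labels: {sorted(unknown)}")
    r = gamma * cloud.delta
    instances: list[OrganInstance] = []
    next_id = 0
    for ci, cname in enumerate(SEMANTIC_CLASSES):
        members = np.nonzero(classes == cname)[0]
        if len(members) == 0:
            continue
        pts = cloud.points[members]
        tree = cKDTree(pts)
        pairs = tree.query_pairs(r, output_type="ndarray")
        n = len(members)
        if len(pairs):
            data = np.ones(len(pairs))
            adj = csr_matrix((data, (pairs[:, 0], pairs[:, 1])), shape=(n, n))
            _, comp = connected_components(adj, directed=False)
        else:
            comp = np.arange(n)
        for label in np.unique(comp):
            ids = members[comp == label]
            if len(ids) < min_points:
                log.debug("dropping %s component of %d points (< %d)", cname, len(ids), min_points)
                continue
            instances.append(OrganInstance(
                semantic_class=cname, member_ids=ids,
                confidence=float(logits[ids, ci].mean()), instance_id=next_id))
            next_id += 1
    return instances


def toy_geometric_classifier(points: np.ndarray, k: int = 12):
    """Geometric stem/leaf pseudo-semantics for end-to-end demos.

    Scores local neighborhoods by verticality (stem) vs planarity (leaf)
    from the eigenstructure of the k-NN covariance.  Not a substitute for a
    trained network -- a convenience for exercising the grouping stage.
    """
    points = np.asarray(points, dtype=np.float64)
    tree = cKDTree(points)
    _, nbr = tree.query(points, k=min(k + 1, len(points)))
    classes = np.empty(len(points), dtype=object)
    logits = np.zeros((len(points), 2))
    for i in range(len(points)):
        local = points[nbr[i]] - points[nbr[i]].mean(axis=0)
        cov = local.T @ local / len(local)
        w, v = np.linalg.eigh(cov)
        linearity = (w[2] - w[1]) / max(w[2], 1e-12)
        verticality = abs(v[2, 2])
        planarity = (w[1] - w[0]) / max(w[2], 1e-12)
        stem_score = linearity * verticality
        leaf_score = planarity
        logits[i] = [stem_score, leaf_score]
        classes[i] = "stem" if stem_score > leaf_score else "leaf"
    return classes.astype(str), logits


def remap_to_splats(instances: list[OrganInstance], cloud: NormalizedCloud,
                    splats: SplatSet, tau_op: float = DEFAULT_TAU_OP,
                    alpha_r: float = DEFAULT_ALPHA_R,
                    zeta_strict: float = DEFAULT_ZETA, rng_seed: int = 0) -> RemapResult:
    """Transfer organ labels from the normalized cloud back to the splats."""
    alpha = sigmoid(splats.opacity_logits)
    visible = np.nonzero(alpha > tau_op)[0]
    if len(visible) == 0:
        raise ValueError("no visible splats above the opacity threshold")
    vis_pos = splats.positions[visible]
    tree_vis = cKDTree(vis_pos)
    d, _ = tree_vis.query(vis_pos, k=min(2, len(vis_pos)))
    d_med = float(np.median(d[:, 1])) if len(vis_pos) > 1 else 0.0
    r_assign = alpha_r * d_med

    n = len(splats)
    cls = np.full(n, "", dtype=object)
    inst = np.full(n, -1, dtype=np.int64)
    conf = np.zeros(n)
    labeled_pts = []
    labeled_cls = []
    labeled_inst = []
    labeled_conf = []
    world = cloud.to_world()
    for organ in instances:
        labeled_pts.append(world[organ.member_ids])
        labeled_cls.extend([organ.semantic_class] * len(organ))
        labeled_inst.extend([organ.instance_id] * len(organ))
        labeled_conf.extend([organ.confidence] * len(organ))
    if labeled_pts:
        lp = np.concatenate(labeled_pts)
        tree_lab = cKDTree(lp)
        dist, nearest = tree_lab.query(vis_pos, k=1)
        in_range = dist <= r_assign
        labeled_cls = np.asarray(labeled_cls, dtype=object)
        labeled_inst = np.asarray(labeled_inst, dtype=np.int64)
        labeled_conf = np.asarray(labeled_conf)
        cls[visible[in_range]] = labeled_cls[nearest[in_range]]
        inst[visible[in_range]] = labeled_inst[nearest[in_range]]
        conf[visible[in_range]] = labeled_conf[nearest[in_range]]
    unassigned = visible[inst[visible] < 0]

    # strict chromatic re-filter over the labeled splats
    assigned = visible[inst[visible] >= 0]
    dropped = np.empty(0, dtype=np.int64)
    if len(assigned) >= 10:
        _, _, rgb = derived_params(splats)
        lab = rgb_to_lab(rgb[assigned])
        try:
            model = fit_color_gmm(lab, rng_seed=rng_seed)
            refined = chroma_filter(assigned, lab, model, zeta=zeta_strict)
            dropped = np.setdiff1d(assigned, refined)
            cls[dropped] = ""
            inst[dropped] = -1
            conf[dropped] = 0.0
            unassigned = np.sort(np.concatenate([unassigned, dropped]))
        except ValueError:
            log.warning("strict chromatic re-filter skipped (model fit failed)")
    return RemapResult(splat_class=cls, splat_instance=inst, splat_confidence=conf,
                       visible=visible, unassigned=unassigned, chroma_dropped=dropped)


def export_organ_plys(directory, plant_name: str, splats: SplatSet,
                      remap: RemapResult) -> list[str]:
    """One 3DGS PLY per organ instance: ``{plant}_{class}{instance_id}.ply``."""
    from pathlib import Path

    from .splats import write_splat_ply

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for iid in np.unique(remap.splat_instance[remap.splat_instance >= 0]):
        members = np.nonzero(remap.splat_instance == iid)[0]
        cname = remap.splat_class[members[0]]
        path = directory / f"{plant_name}_{cname}{iid}.ply"
        write_splat_ply(path, splats.subset(members))
        written.append(str(path))
    return written
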
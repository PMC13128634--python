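"""Metric scaling, frame alignment and phenotypic trait computation.

Traits are computed in a metric, gravity-aligned frame with the ground at
z = 0.  The scene-to-meters scale comes from a calibration reference of
known physical length visible in the reconstruction (e.g. a greenhouse
rack of 42 cm width); the alignment is a similarity transform
x' = s R x + t whose rotation is estimated by robustly fitting a ground
plane to the lowest points and rotating its normal to +z.

Six traits are extracted per plant:

* height H: maximum of a morphologically filtered top-down height map;
* per-leaf area and LSA: alpha-shape area of each leaf's member ellipsoids
  orthogonally projected on the leaf's PCA plane, summed over leaves;
* LAI = LSA / A_plot with a fixed reference plot area (0.036 m^2 by
  default, the circular footprint of a 0.214 m mean canopy spread);
* leaf count after merging near-coincident fragments and dropping
  components below 1 cm^2;
* node count and internode lengths from a Laplacian-contracted stem
  centerline: an orientation-aware MST links the centerline nodes, the
  main axis is the tree path of maximal vertical span, junctions define
  nodes, and internodes are geodesic path lengths between consecutive
  junctions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import cKDTree
from skimage.morphology import disk

from .geometry import (alpha_shape_area, farthest_point_sample, median_nn_spacing,
                       robust_plane_fit, rotation_to_z, weighted_pca_plane)
from .splats import SplatSet, derived_params, quat_to_rotmat

log = logging.getLogger(__name__)

DEFAULT_A_PLOT_M2 = 0.036
DEFAULT_REF_LENGTH_M = 0.42
DEFAULT_LEAF_K_SIGMA = 2.0
MIN_LEAF_AREA_M2 = 1e-4  # 1 cm^2


def plot_area_from_diameter(diameter_m: float) -> float:
    """Circular-footprint reference area from a canopy spread diameter."""
    return float(np.pi * (diameter_m / 2.0) ** 2)


@dataclass
class MetricFrame:
    """Similarity transform x' = s R x + t to the metric, aligned frame."""

    scale_s: float
    rotation_R: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation_R = np.asarray(self.rotation_R, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if self.scale_s <= 0:
            raise ValueError("scale must be positive")
        if not np.allclose(self.rotation_R @ self.rotation_R.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation must be orthonormal")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return self.scale_s * (np.asarray(points) @ self.rotation_R.T) + self.translation

    def apply_splats(self, splats: SplatSet) -> SplatSet:
        """Transform a splat set: positions, orientations and scales."""
        R = self.rotation_R
        Rq = quat_to_rotmat(splats.rotations)
        Rnew = np.einsum("ij,njk->nik", R, Rq)
        return SplatSet(
            positions=self.apply(splats.positions),
            log_scales=splats.log_scales + np.log(self.scale_s),
            rotations=_rotmat_to_quat(Rnew),
            opacity_logits=splats.opacity_logits.copy(),
            dc_color=splats.dc_color.copy(),
            ids=splats.ids.copy(),
        )


def _rotmat_to_quat(R: np.ndarray) -> np.ndarray:
    """Batch rotation matrices -> unit quaternions (w, x, y, z)."""
    from scipy.spatial.transform import Rotation

    q = Rotation.from_matrix(R).as_quat()  # xyzw
    return np.concatenate([q[:, 3:4], q[:, :3]], axis=1)


@dataclass
class TraitRecord:
    height_cm: float
    lsa_cm2: float
    lai: float
    leaf_count: int
    node_count: int
    internode_lengths_cm: list[float] = field(default_factory=list)
    per_leaf_areas_cm2: list[float] = field(default_factory=list)

    @property
    def mean_internode_cm(self) -> float:
        return float(np.mean(self.internode_lengths_cm)) if self.internode_lengths_cm else 0.0


def metric_scale_align(points: np.ndarray, ref_points: np.ndarray, ref_length_m: float,
                       alignment: "MetricFrame | str" = "estimate") -> tuple[np.ndarray, MetricFrame]:
    """Build and apply the metric frame.

    ``ref_points`` is a pair of scene points whose true separation is
    ``ref_length_m``.  With ``alignment="estimate"`` the ground plane is
    fitted robustly to the lowest 10% of points, its normal rotated to +z
    and the plane shifted to z = 0; passing a MetricFrame reuses a known
    alignment.
    """
    points = np.asarray(points, dtype=np.float64)
    ref_points = np.asarray(ref_points, dtype=np.float64).reshape(2, 3)
    if ref_length_m <= 0:
        raise ValueError("ref_length_m must be positive")
    gap = np.linalg.norm(ref_points[0] - ref_points[1])
    if gap == 0:
        raise ValueError("reference points are coincident")
    s = ref_length_m / gap
    if isinstance(alignment, MetricFrame):
        frame = alignment
    else:
        z_cut = np.quantile(points[:, 2], 0.10)
        low = points[points[:, 2] <= z_cut]
        if len(low) < 50:
            log.warning("ground-plane fit has %d < 50 candidate points; using identity alignment", len(low))
            R = np.eye(3)
            t = np.zeros(3)
        else:
            centroid, normal, inliers = robust_plane_fit(low)
            if inliers.sum() < 50:
                log.warning("ground-plane fit kept %d < 50 inliers; using identity alignment", inliers.sum())
                R = np.eye(3)
                t = np.zeros(3)
            else:
                R = rotation_to_z(normal)
                t = np.array([0.0, 0.0, -s * float((R @ centroid)[2])])
        frame = MetricFrame(scale_s=s, rotation_R=R, translation=t)
    return frame.apply(points), frame


def plant_height(points: np.ndarray, cell: float | None = None,
                 filter_radius_cells: int = 2, operator: str = "closing") -> float:
    """Height from a morphologically filtered top-down height map (meters).

    The map holds the per-cell maximum z over an xy raster (cell size
    defaults to the median nearest-neighbor spacing); a grayscale closing
    (or opening, for suppression of isolated spurious peaks) with a disc of
    ``filter_radius_cells`` is applied and the maximum taken.
    """
    points = np.asarray(points, dtype=np.float64)
    if len(points) == 0:
        raise ValueError("empty point set")
    if (points[:, 2] <= 0).all():
        log.warning("all points at or below ground; height is 0")
        return 0.0
    if cell is None:
        cell = median_nn_spacing(points) or 1e-3
    xy = points[:, :2]
    ij = np.floor((xy - xy.min(axis=0)) / cell).astype(int)
    shape = ij.max(axis=0) + 1
    hmap = np.zeros(shape[::-1])
    np.maximum.at(hmap, (ij[:, 1], ij[:, 0]), points[:, 2])
    if min(hmap.shape) > 1:
        footprint = disk(filter_radius_cells)
        op = ndimage.grey_closing if operator == "closing" else ndimage.grey_opening
        hmap = op(hmap, footprint=footprint)
    return float(hmap.max())


def leaf_area(splats: SplatSet, member_index: np.ndarray,
              k_sigma: float = DEFAULT_LEAF_K_SIGMA,
              alpha_len: float | None = None) -> float:
    """One-sided area of a leaf instance (squared scene/metric units).

    Fits a PCA plane through the opacity-weighted member centers, projects
    each member ellipsoid orthogonally onto it (2D covariance B^T Sigma B),
    discretizes each k_sigma ellipse as 16 boundary points plus its center,
    and takes the alpha-shape area of the pooled points.
    """
    member_index = np.asarray(member_index, dtype=np.int64)
    if len(member_index) < 3:
        raise ValueError("leaf instance needs at least 3 member splats")
    sub = splats.subset(member_index)
    cov, alpha, _ = derived_params(sub)
    centroid, basis, _ = weighted_pca_plane(sub.positions, alpha)
    centered = sub.positions - centroid
    uv = centered @ basis  # (n, 2) in-plane center coordinates
    if np.linalg.matrix_rank(np.cov(uv.T)) < 2 and len(uv) >= 3:
        spread = uv.std(axis=0)
        if min(spread) < 1e-12:
            log.warning("degenerate (collinear) leaf instance; area 0")
            return 0.0
    cov2 = np.einsum("ji,njk,kl->nil", basis, cov, basis)
    evals, evecs = np.linalg.eigh(cov2)
    evals = np.clip(evals, 0.0, None)
    theta = np.linspace(0, 2 * np.pi, 16, endpoint=False)
    circle = np.stack([np.cos(theta), np.sin(theta)], axis=1)  # (16, 2)
    radii = k_sigma * np.sqrt(evals)  # (n, 2)
    boundary = np.einsum("tj,nj,nkj->ntk", circle, radii, evecs) + uv[:, None, :]
    pooled = np.concatenate([boundary.reshape(-1, 2), uv], axis=0)
    if alpha_len is None:
        alpha_len = 4.0 * (median_nn_spacing(sub.positions) or 1.0)
    return alpha_shape_area(pooled, alpha_len)


def leaf_area_lai(splats: SplatSet, leaf_instances: list[np.ndarray],
                  k_sigma: float = DEFAULT_LEAF_K_SIGMA, alpha_len: float | None = None,
                  a_plot_m2: float = DEFAULT_A_PLOT_M2):
    """Per-leaf areas, total LSA and LAI (splats already in metric units)."""
    areas = [leaf_area(splats, idx, k_sigma=k_sigma, alpha_len=alpha_len)
             for idx in leaf_instances]
    lsa = float(sum(areas))
    return areas, lsa, lsa / a_plot_m2


def leaf_count(areas: list[float], centroids: np.ndarray, d_med: float,
               min_area_m2: float = MIN_LEAF_AREA_M2):
    """Merge fragments with centroids within d_med; drop areas < 1 cm^2.

    Returns (count, groups) where groups lists the merged instance index
    sets surviving the area floor.
    """
    centroids = np.asarray(centroids, dtype=np.float64).reshape(-1, 3)
    n = len(areas)
    if n == 0:
        return 0, []
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(centroids[i] - centroids[j]) <= d_med:
                parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    survivors = [g for g in groups.values() if sum(areas[i] for i in g) >= min_area_m2]
    return len(survivors), survivors


def stem_skeleton(stem_points: np.ndarray, lam: float = 0.5, iterations: int = 8,
                  k: int = 12, node_spacing: float | None = None) -> np.ndarray:
    """Centerline nodes via Laplacian contraction + farthest-point sampling.

    Each iteration moves every point toward the mean of its k nearest
    neighbors: x <- (1 - lam) x + lam mean(kNN(x)); the contracted cloud is
    then thinned to nodes at least ``node_spacing`` apart (default twice
    the median nearest-neighbor spacing of the input).
    """
    pts = np.asarray(stem_points, dtype=np.float64).copy()
    if len(pts) < 20:
        raise ValueError("stem skeleton needs at least 20 points")
    if node_spacing is None:
        node_spacing = 2.0 * median_nn_spacing(pts)
    kk = min(k + 1, len(pts))
    for _ in range(iterations):
        tree = cKDTree(pts)
        _, nbr = tree.query(pts, k=kk)
        pts = (1 - lam) * pts + lam * pts[nbr].mean(axis=1)
    nodes = pts[farthest_point_sample(pts, node_spacing)]
    return nodes


def _local_directions(nodes: np.ndarray, k: int = 6) -> np.ndarray:
    """Principal direction of each node's k-neighborhood (unit vectors)."""
    n = len(nodes)
    kk = min(k + 1, n)
    tree = cKDTree(nodes)
    _, nbr = tree.query(nodes, k=kk)
    dirs = np.zeros((n, 3))
    for i in range(n):
        local = nodes[nbr[i]] - nodes[nbr[i]].mean(axis=0)
        _, v = np.linalg.eigh(local.T @ local)
        dirs[i] = v[:, 2]
    return dirs


def internode_stats(nodes: np.ndarray, attachment_hints: np.ndarray | None = None,
                    scale_s: float = 1.0, min_branch_len: float | None = None,
                    merge_len: float | None = None) -> tuple[int, list[float]]:
    """Node count and internode lengths from the centerline node set.

    An MST over the complete node graph uses orientation-aware weights
    w(e) = |e| * (2 - |cos(e, d_local)|) (mean over the edge's two
    endpoints) so edges along the local growth direction are favored.  The
    main axis is the tree path of maximal vertical span; junctions are its
    vertices of tree degree >= 3 whose side branch is at least
    ``min_branch_len`` long (default 4x the median MST edge length --
    shorter twigs are artifacts of residual centerline thickness), plus any
    attachment hints snapped to the nearest axis vertex.  Junctions closer
    than ``merge_len`` along the axis (same default) are merged, since a
    hint and a degree junction of the same physical node rarely snap to the
    identical vertex.  Internode j is the geodesic (along-path) length
    between consecutive junctions, scaled by ``scale_s``.
    """
    nodes = np.asarray(nodes, dtype=np.float64).reshape(-1, 3)
    n = len(nodes)
    if n < 2:
        raise ValueError("need at least 2 centerline nodes")
    dirs = _local_directions(nodes)
    diff = nodes[:, None, :] - nodes[None, :, :]
    length = np.linalg.norm(diff, axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = diff / np.where(length[..., None] > 0, length[..., None], 1.0)
    cos_u = np.abs(np.einsum("ijk,ik->ij", unit, dirs))
    cos_v = np.abs(np.einsum("ijk,jk->ij", unit, dirs))
    weight = length * (2.0 - 0.5 * (cos_u + cos_v))
    mst = minimum_spanning_tree(weight).toarray()
    tree = nx.Graph()
    for i, j in zip(*np.nonzero(mst)):
        tree.add_edge(int(i), int(j), length=length[i, j])
    if tree.number_of_nodes() < n:
        tree.add_nodes_from(range(n))
    if not nx.is_connected(tree):
        raise RuntimeError("MST disconnected on complete graph")
    lo, hi = int(np.argmin(nodes[:, 2])), int(np.argmax(nodes[:, 2]))
    axis = nx.shortest_path(tree, lo, hi, weight="length")
    axis_set = set(axis)
    edge_lengths = [d["length"] for _, _, d in tree.edges(data=True)]
    med_edge = float(np.median(edge_lengths)) if edge_lengths else 0.0
    if min_branch_len is None:
        min_branch_len = 3.0 * med_edge
    if merge_len is None:
        merge_len = med_edge

    def branch_depth(start, blocked):
        # total path length of the deepest side branch rooted at `start`
        best = 0.0
        stack = [(start, 0.0)]
        seen = {blocked, start}
        while stack:
            v, d = stack.pop()
            best = max(best, d)
            for u in tree.neighbors(v):
                if u not in seen and u not in axis_set:
                    seen.add(u)
                    stack.append((u, d + tree.edges[v, u]["length"]))
        return best

    junctions = set()
    for v in axis:
        if tree.degree[v] < 3:
            continue
        side = [u for u in tree.neighbors(v) if u not in axis_set]
        if any(tree.edges[v, u]["length"] + branch_depth(u, v) >= min_branch_len
               for u in side):
            junctions.add(v)
    if attachment_hints is not None and len(attachment_hints):
        # snap each hint to its nearest skeleton node, then walk the tree to
        # the main axis: the entry vertex is the attachment junction
        hints = np.asarray(attachment_hints, dtype=np.float64).reshape(-1, 3)
        nearest = np.argmin(np.linalg.norm(nodes[None, :, :] - hints[:, None, :], axis=2), axis=1)
        for v in nearest:
            v = int(v)
            if v in axis_set:
                junctions.add(v)
                continue
            for u in nx.shortest_path(tree, v, lo, weight="length"):
                if u in axis_set:
                    junctions.add(u)
                    break

    # along-path arc positions; merge junctions closer than merge_len
    seg = [np.linalg.norm(nodes[axis[i + 1]] - nodes[axis[i]]) for i in range(len(axis) - 1)]
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    pos = {v: i for i, v in enumerate(axis)}
    ordered = sorted(junctions, key=lambda v: pos[v])
    merged: list[int] = []
    for v in ordered:
        if merged and arc[pos[v]] - arc[pos[merged[-1]]] < merge_len:
            continue
        merged.append(v)
    if len(merged) < 2:
        return len(merged), []
    lengths = [scale_s * float(arc[pos[b]] - arc[pos[a]])
               for a, b in zip(merged[:-1], merged[1:])]
    return len(merged), lengths


def compute_traits(splats_metric: SplatSet, stem_index: np.ndarray,
                   leaf_instances: list[np.ndarray],
                   a_plot_m2: float = DEFAULT_A_PLOT_M2,
                   k_sigma: float = DEFAULT_LEAF_K_SIGMA,
                   height_operator: str = "closing") -> TraitRecord:
    """Assemble the six traits for one metric-aligned plant."""
    plant_index = np.concatenate([np.asarray(stem_index, dtype=np.int64)]
                                 + [np.asarray(i, dtype=np.int64) for i in leaf_instances])
    pts = splats_metric.positions[plant_index]
    h = plant_height(pts, operator=height_operator)
    areas, lsa, lai = leaf_area_lai(splats_metric, leaf_instances,
                                    k_sigma=k_sigma, a_plot_m2=a_plot_m2)
    centroids = np.array([splats_metric.positions[np.asarray(i)].mean(axis=0)
                          for i in leaf_instances]).reshape(-1, 3)
    d_med = median_nn_spacing(pts)
    count, groups = leaf_count(areas, centroids, d_med)
    # skeletonize the dense sampled stem cloud, not the sparse splat centers:
    # Laplacian contraction needs local neighborhoods well inside the stem
    from .refine import export_point_cloud

    try:
        stem_pts, _, _ = export_point_cloud(splats_metric, np.asarray(stem_index, dtype=np.int64),
                                            density=20.0, rng_seed=0)
        nodes = stem_skeleton(stem_pts)
        node_count, internodes = internode_stats(nodes, attachment_hints=centroids)
    except (ValueError, RuntimeError) as exc:
        log.warning("skeleton failed (%s); node traits empty", exc)
        node_count, internodes = 0, []
    merged_areas = [sum(areas[i] for i in g) for g in groups]
    return TraitRecord(
        height_cm=100.0 * h,
        lsa_cm2=1e4 * lsa,
        lai=lai,
        leaf_count=count,
        node_count=node_count,
        internode_lengths_cm=[100.0 * x for x in internodes],
        per_leaf_areas_cm2=[1e4 * a for a in merged_areas],
    )
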
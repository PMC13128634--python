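"""Stage 2: geometric clustering and retention filtering.

The lifted foreground may still contain background fragments and overlap
with neighboring plants.  Each foreground Gaussian is described by a 4-D
feature: its three world coordinates plus a view-agnostic depth cue (the
mean distance to the cameras that see it), all robustly standardized as

    Z(s | S) = (s - median(S)) / MAD(S),

so Euclidean distances balance local shape with depth regardless of scene
scale.  OPTICS orders the features by reachability and the steepness-based
xi-method (xi = 0.1) extracts clusters as reachability valleys.  The plant
cluster is the one with maximal summed lift score; adjacent clusters are
merged back when their centroid lies within the 90th percentile of the
selected cluster's point-to-centroid distances and their median depth
differs by less than 15%.  Finally a nearest-neighbor retain step restores
any rejected scene splat whose nearest kept neighbor lies within
r_nr = beta * median 1-NN spacing of the kept set (beta = 2), recovering
thin foliage lost at earlier thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from sklearn.cluster import OPTICS

from .cameras import CameraView
from .splats import SplatSet

log = logging.getLogger(__name__)

DEFAULT_XI = 0.1
DEFAULT_BETA = 2.0
MERGE_CENTROID_PERCENTILE = 90.0
MERGE_DEPTH_TOLERANCE = 0.15


@dataclass
class ClusterFeatures:
    descriptor: np.ndarray        # (M, 4) standardized [x', y', z', d']
    mean_cam_dist: np.ndarray     # (M,) raw r_bar
    visible_cams: list[np.ndarray]  # per-splat view-index sets
    foreground: np.ndarray        # (M,) positional indices into the scene


@dataclass
class ClusterOutcome:
    labels: np.ndarray            # cluster id per foreground splat, -1 = noise
    selected: int                 # chosen plant cluster id
    kept: np.ndarray              # positional scene indices after merge (+retain)
    merge_log: list[tuple[int, str]] = field(default_factory=list)


def robust_z(values: np.ndarray) -> tuple[np.ndarray, bool]:
    """Median/MAD standardization; returns (standardized, degenerate_flag).

    Degenerate (MAD = 0) inputs map to all zeros with the flag set.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("robust_z needs at least 1 value")
    if not np.isfinite(values).all():
        raise ValueError("non-finite values in robust_z input")
    med = np.median(values)
    mad = np.median(np.abs(values - med))
    if mad == 0:
        return np.zeros_like(values), True
    return (values - med) / mad, False


def build_descriptors(foreground: np.ndarray, splats: SplatSet,
                      views: list[CameraView]) -> ClusterFeatures:
    """4-D standardized descriptors [x', y', z', d'] over the foreground set."""
    foreground = np.asarray(foreground, dtype=np.int64)
    if foreground.size == 0:
        raise ValueError("foreground is empty")
    pos = splats.positions[foreground]
    vis = np.stack([v.in_frustum(pos) for v in views], axis=1)  # (M, V)
    centers = np.stack([v.center for v in views], axis=0)
    dists = np.linalg.norm(pos[:, None, :] - centers[None, :, :], axis=2)
    none = ~vis.any(axis=1)
    if none.any():
        log.info("%d foreground splats visible in no view; using all views as fallback", none.sum())
        vis[none] = True
    r_bar = (dists * vis).sum(axis=1) / vis.sum(axis=1)
    cols = [robust_z(pos[:, i])[0] for i in range(3)] + [robust_z(r_bar)[0]]
    phi = np.stack(cols, axis=1)
    view_idx = np.asarray([v.view_index for v in views])
    visible = [view_idx[row] for row in vis]
    return ClusterFeatures(descriptor=phi, mean_cam_dist=r_bar,
                           visible_cams=visible, foreground=foreground)


def default_min_samples(n_foreground: int) -> int:
    """Density floor for OPTICS: 0.5% of the foreground, at least 15.

    The floor keeps the xi-extraction from shattering organ-scale structure
    (a single leaf patch easily exceeds 5 mutually-reachable splats) into
    micro-clusters on small scenes.
    """
    return max(15, int(round(0.005 * n_foreground)))


def _top_level_labels(opt: OPTICS, m: int) -> np.ndarray:
    """Coarsest xi-clusters from the OPTICS cluster hierarchy.

    The xi-method yields a hierarchy of reachability valleys; the plant is
    a broad valley whose leaf sub-valleys (individual organs) would
    over-segment it, so the maximal non-nested spans are used as clusters.
    The span covering the entire ordering is ignored unless it is the only
    one.  Points outside every span are noise (-1).
    """
    spans = [tuple(se) for se in np.atleast_2d(np.asarray(opt.cluster_hierarchy_)).tolist()
             if len(se) == 2]
    proper = [s for s in spans if not (s[0] == 0 and s[1] >= m - 1)]
    # the root span covering the whole ordering is a real valley unless its
    # children already partition the ordering (then it only bridges them)
    if proper:
        top_proper = []
        for s, e in sorted(proper, key=lambda se: se[0] - se[1]):
            if not any(ts <= s and e <= te for ts, te in top_proper):
                top_proper.append((s, e))
        covered = sum(e - s + 1 for s, e in top_proper)
        if covered >= 0.5 * m:
            spans = proper
    # keep spans not nested inside another kept span; widest first
    spans.sort(key=lambda se: se[0] - se[1])
    top: list[tuple[int, int]] = []
    for s, e in spans:
        if not any(ts <= s and e <= te for ts, te in top):
            top.append((s, e))
    labels = np.full(m, -1, dtype=np.int64)
    ordering = np.asarray(opt.ordering_)
    for cid, (s, e) in enumerate(sorted(top)):
        labels[ordering[s:e + 1]] = cid
    return labels


def optics_cluster_merge(features: ClusterFeatures, support: np.ndarray,
                         xi: float = DEFAULT_XI, min_samples: int | None = None) -> ClusterOutcome:
    """OPTICS xi-extraction, cue-linked cluster selection, and merging.

    ``support`` is the per-scene lift score; only its foreground entries are
    used.  The selected cluster maximizes summed lift score (ties: larger
    cluster, then lowest id).
    """
    phi = features.descriptor
    m = len(phi)
    if min_samples is None:
        min_samples = default_min_samples(m)
    if m < min_samples:
        raise ValueError(f"only {m} foreground splats < min_samples={min_samples}")
    opt = OPTICS(min_samples=min_samples, xi=xi, cluster_method="xi")
    opt.fit(phi)
    labels = _top_level_labels(opt, m)
    if labels.max() < 0:
        # no xi-cluster: fall back to the densest reachability valley
        log.warning("OPTICS xi-extraction found no cluster; falling back to reachability minimum")
        reach = opt.reachability_[opt.ordering_]
        finite = np.isfinite(reach)
        med = np.median(reach[finite]) if finite.any() else np.inf
        center = int(np.nanargmin(np.where(finite, reach, np.inf)))
        in_valley = np.zeros(m, dtype=bool)
        i = center
        while i >= 0 and reach[i] <= med:
            in_valley[i] = True
            i -= 1
        i = center + 1
        while i < m and reach[i] <= med:
            in_valley[i] = True
            i += 1
        labels[:] = -1
        labels[np.asarray(opt.ordering_)[in_valley]] = 0

    selected = select_cluster(labels, np.asarray(support)[features.foreground])
    keep_mask, merge_log = merge_clusters(features, labels, selected)
    kept = features.foreground[keep_mask]
    return ClusterOutcome(labels=labels, selected=selected, kept=kept, merge_log=merge_log)


def select_cluster(labels: np.ndarray, support_fg: np.ndarray) -> int:
    """Cue-linked cluster choice: maximal summed lift score.

    Ties go to the larger cluster, then the lowest cluster id.
    """
    cluster_ids = np.unique(labels[labels >= 0])
    mass = np.array([support_fg[labels == c].sum() for c in cluster_ids])
    size = np.array([(labels == c).sum() for c in cluster_ids])
    order = np.lexsort((cluster_ids, -size, -mass))
    return int(cluster_ids[order[0]])


def merge_clusters(features: ClusterFeatures, labels: np.ndarray,
                   selected: int) -> tuple[np.ndarray, list[tuple[int, str]]]:
    """Merge clusters near the selected one; noise (-1) is never merged.

    A cluster joins the kept set iff its centroid lies within the 90th
    percentile of the selected cluster's point-to-centroid distances and
    its median depth differs from the selected median depth by < 15%.
    """
    phi = features.descriptor
    sel_mask = labels == selected
    sel_pts = phi[sel_mask]
    sel_centroid = sel_pts.mean(axis=0)
    p90 = np.percentile(np.linalg.norm(sel_pts - sel_centroid, axis=1),
                        MERGE_CENTROID_PERCENTILE)
    sel_depth = np.median(features.mean_cam_dist[sel_mask])

    keep_mask = sel_mask.copy()
    merge_log: list[tuple[int, str]] = []
    for c in np.unique(labels[labels >= 0]):
        if c == selected:
            continue
        c_mask = labels == c
        centroid = phi[c_mask].mean(axis=0)
        cdist = np.linalg.norm(centroid - sel_centroid)
        depth = np.median(features.mean_cam_dist[c_mask])
        depth_ratio = abs(depth - sel_depth) / sel_depth
        if cdist <= p90 and depth_ratio < MERGE_DEPTH_TOLERANCE:
            keep_mask |= c_mask
            merge_log.append((int(c), f"merged: centroid {cdist:.3f} <= P90 {p90:.3f}, "
                                      f"depth ratio {depth_ratio:.3f} < {MERGE_DEPTH_TOLERANCE}"))
        else:
            merge_log.append((int(c), f"dropped: centroid {cdist:.3f} vs P90 {p90:.3f}, "
                                      f"depth ratio {depth_ratio:.3f}"))
    return keep_mask, merge_log


def nn_retain(kept: np.ndarray, scene: SplatSet, beta: float = DEFAULT_BETA) -> np.ndarray:
    """Restore rejected splats within r_nr = beta * median 1-NN kept spacing.

    Distances are in raw world coordinates.  Single pass: newly restored
    splats do not extend the radius search.  Candidates are all scene splats
    not currently kept, including those that failed the lift threshold.
    """
    kept = np.asarray(kept, dtype=np.int64)
    if len(kept) < 2:
        log.warning("nn_retain skipped: kept set has < 2 splats (d_1NN undefined)")
        return kept
    kept_pos = scene.positions[kept]
    tree = cKDTree(kept_pos)
    d1nn, _ = tree.query(kept_pos, k=2)
    d_med = float(np.median(d1nn[:, 1]))
    r_nr = beta * d_med
    mask = np.zeros(len(scene), dtype=bool)
    mask[kept] = True
    rejected = np.nonzero(~mask)[0]
    if len(rejected) == 0:
        return kept
    d, _ = tree.query(scene.positions[rejected], k=1)
    restored = rejected[d <= r_nr]
    return np.sort(np.concatenate([kept, restored]))
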
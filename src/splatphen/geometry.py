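"""Small computational-geometry helpers used by the trait stage."""

from __future__ import annotations

import numpy as np
from scipy.spatial import Delaunay, cKDTree


def alpha_shape_area(points: np.ndarray, alpha: float) -> float:
    """Area of the 2-D alpha-shape with characteristic length ``alpha``.

    Delaunay triangles whose circumradius is at most ``alpha`` are kept and
    their areas summed; as alpha grows the result approaches the convex
    hull area, while small alpha carves out voids between sparse points.
    """
    points = np.asarray(points, dtype=np.float64).reshape(-1, 2)
    if len(points) < 3:
        return 0.0
    try:
        tri = Delaunay(points)
    except Exception:  # collinear/degenerate input
        return 0.0
    p = points[tri.simplices]  # (T, 3, 2)
    a = np.linalg.norm(p[:, 0] - p[:, 1], axis=1)
    b = np.linalg.norm(p[:, 1] - p[:, 2], axis=1)
    c = np.linalg.norm(p[:, 2] - p[:, 0], axis=1)
    cross = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) \
        - (p[:, 1, 1] - p[:, 0, 1]) * (p[:, 2, 0] - p[:, 0, 0])
    area = 0.5 * np.abs(cross)
    with np.errstate(divide="ignore", invalid="ignore"):
        circum = np.where(area > 1e-15, a * b * c / (4 * area), np.inf)
    return float(area[circum <= alpha].sum())


def weighted_pca_plane(points: np.ndarray, weights: np.ndarray | None = None):
    """Least-squares plane through weighted points.

    Returns (centroid, basis (3, 2), normal).  The basis spans the plane;
    the normal is the smallest-variance direction.
    """
    points = np.asarray(points, dtype=np.float64)
    if weights is None:
        weights = np.ones(len(points))
    w = np.asarray(weights, dtype=np.float64)
    w = w / w.sum()
    centroid = w @ points
    centered = points - centroid
    cov = (centered * w[:, None]).T @ centered
    evals, evecs = np.linalg.eigh(cov)
    normal = evecs[:, 0]
    basis = evecs[:, 1:][:, ::-1]  # columns: major then minor in-plane axis
    return centroid, basis, normal


def robust_plane_fit(points: np.ndarray, n_iter: int = 3, sigma_clip: float = 2.5):
    """Plane fit with iterative sigma-clipping of residual outliers.

    Returns (centroid, normal, inlier_mask).
    """
    points = np.asarray(points, dtype=np.float64)
    mask = np.ones(len(points), dtype=bool)
    centroid = normal = None
    for _ in range(n_iter):
        centroid, _, normal = weighted_pca_plane(points[mask])
        resid = np.abs((points - centroid) @ normal)
        scale = np.median(resid[mask]) * 1.4826 + 1e-12
        new_mask = resid <= sigma_clip * scale
        if new_mask.sum() < 3 or np.array_equal(new_mask, mask):
            mask = new_mask if new_mask.sum() >= 3 else mask
            break
        mask = new_mask
    return centroid, normal, mask


def rotation_to_z(normal: np.ndarray) -> np.ndarray:
    """Minimal rotation taking ``normal`` (unit) to +z."""
    normal = np.asarray(normal, dtype=np.float64)
    normal = normal / np.linalg.norm(normal)
    if normal[2] < 0:
        normal = -normal
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(normal, z)
    s = np.linalg.norm(v)
    c = float(normal @ z)
    if s < 1e-12:
        return np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * ((1 - c) / s**2)


def farthest_point_sample(points: np.ndarray, min_spacing: float,
                          start: int | None = None) -> np.ndarray:
    """Greedy farthest-point subset until the farthest remaining point is
    closer than ``min_spacing`` to the selected set.  Returns indices."""
    points = np.asarray(points, dtype=np.float64)
    n = len(points)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    if start is None:
        start = int(np.argmin(points[:, 2]))  # lowest point: stable for stems
    chosen = [start]
    dist = np.linalg.norm(points - points[start], axis=1)
    while True:
        i = int(np.argmax(dist))
        if dist[i] < min_spacing:
            break
        chosen.append(i)
        dist = np.minimum(dist, np.linalg.norm(points - points[i], axis=1))
    return np.asarray(chosen, dtype=np.int64)


def median_nn_spacing(points: np.ndarray) -> float:
    """Median nearest-neighbor distance."""
    points = np.asarray(points, dtype=np.float64)
    if len(points) < 2:
        return 0.0
    tree = cKDTree(points)
    d, _ = tree.query(points, k=2)
    return float(np.median(d[:, 1]))
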
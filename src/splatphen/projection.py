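"""Perspective projection of 3D Gaussians to image-space ellipses.

A Gaussian (mu, Sigma) projects to an ellipse with center at the pinhole
image of mu and 2D covariance J W Sigma W^T J^T, where W is the
world-to-camera rotation and J the perspective Jacobian at mu (the standard
EWA splatting linearization).  The footprint is the set of pixel centers
inside the k_sigma Mahalanobis ellipse, clipped to the image; the kernel is
the 2D Gaussian density at pixel centers renormalized to sum to one over
the footprint.

Pixel convention: 0-based, origin top-left, pixel centers at integer
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cameras import CameraView
from .splats import SplatSet, derived_params

# Diagonal regularizer (px^2) applied when the projected covariance is
# numerically singular; matches the dilation used by 3DGS rasterizers.
COV2D_DILATION = 0.3


class BehindCameraError(ValueError):
    """The Gaussian center has non-positive camera-frame depth."""


@dataclass
class Ellipse2D:
    center: np.ndarray      # (2,) pixel coordinates (u, v)
    cov2d: np.ndarray       # 2x2 symmetric PSD, px^2
    footprint: np.ndarray   # (M, 2) integer pixel coords (u, v) inside image
    kernel: np.ndarray      # (M,) nonnegative weights summing to 1
    clipped: bool = False   # True when part of the k_sigma ellipse left the image

    @property
    def empty(self) -> bool:
        return len(self.footprint) == 0


def perspective_jacobian(pc: np.ndarray, K: np.ndarray) -> np.ndarray:
    """Jacobian (..., 2, 3) of the pinhole map at camera-frame points pc."""
    x, y, z = pc[..., 0], pc[..., 1], pc[..., 2]
    fx, fy = K[0, 0], K[1, 1]
    J = np.zeros(pc.shape[:-1] + (2, 3))
    J[..., 0, 0] = fx / z
    J[..., 0, 2] = -fx * x / z**2
    J[..., 1, 1] = fy / z
    J[..., 1, 2] = -fy * y / z**2
    return J


def project_covariances(cov: np.ndarray, view: CameraView, positions: np.ndarray):
    """Batch-project world covariances; returns (centers (N,2), depth (N,), cov2d (N,2,2))."""
    pc = view.to_camera(positions)
    z = pc[..., 2]
    px, _ = view.project(positions)
    J = perspective_jacobian(pc, view.intrinsics)
    W = view.rotation
    covc = np.einsum("ij,njk,lk->nil", W, cov, W)
    cov2d = np.einsum("nij,njk,nlk->nil", J, covc, J)
    # symmetrize against roundoff
    cov2d = 0.5 * (cov2d + np.transpose(cov2d, (0, 2, 1)))
    det = cov2d[:, 0, 0] * cov2d[:, 1, 1] - cov2d[:, 0, 1] ** 2
    singular = det <= 1e-12
    if singular.any():
        cov2d[singular, 0, 0] += COV2D_DILATION
        cov2d[singular, 1, 1] += COV2D_DILATION
    return px, z, cov2d


def _footprint(center, cov2d, image_size, k_sigma):
    """Pixel centers inside the k_sigma ellipse, and their Gaussian weights."""
    w, h = image_size
    a, b, c = cov2d[0, 0], cov2d[0, 1], cov2d[1, 1]
    det = a * c - b * b
    inv = np.array([[c, -b], [-b, a]]) / det
    # axis-aligned half extents of the k_sigma ellipse
    ru = k_sigma * np.sqrt(max(a, 0.0))
    rv = k_sigma * np.sqrt(max(c, 0.0))
    u0 = int(np.ceil(center[0] - ru))
    u1 = int(np.floor(center[0] + ru))
    v0 = int(np.ceil(center[1] - rv))
    v1 = int(np.floor(center[1] + rv))
    clipped = u0 < 0 or v0 < 0 or u1 > w - 1 or v1 > h - 1
    u0c, u1c = max(u0, 0), min(u1, w - 1)
    v0c, v1c = max(v0, 0), min(v1, h - 1)
    if u0c > u1c or v0c > v1c:
        return np.empty((0, 2), dtype=np.int64), np.empty(0), True
    uu, vv = np.meshgrid(np.arange(u0c, u1c + 1), np.arange(v0c, v1c + 1), indexing="xy")
    du = uu.ravel() - center[0]
    dv = vv.ravel() - center[1]
    m = inv[0, 0] * du * du + 2 * inv[0, 1] * du * dv + inv[1, 1] * dv * dv
    inside = m <= k_sigma**2
    if not inside.any():
        return np.empty((0, 2), dtype=np.int64), np.empty(0), clipped
    pts = np.stack([uu.ravel()[inside], vv.ravel()[inside]], axis=1).astype(np.int64)
    wgt = np.exp(-0.5 * m[inside])
    wgt = wgt / wgt.sum()
    return pts, wgt, clipped


def project_gaussian(splats: SplatSet, splat_index: int, view: CameraView,
                     k_sigma: float = 3.0) -> Ellipse2D:
    """Project one Gaussian into a view; raises BehindCameraError if depth <= 0."""
    cov, _, _ = derived_params(splats.subset(np.array([splat_index])))
    px, z, cov2d = project_covariances(cov, view, splats.positions[[splat_index]])
    if z[0] <= 0:
        raise BehindCameraError(f"splat {splat_index} is behind view {view.view_index}")
    pts, wgt, clipped = _footprint(px[0], cov2d[0], view.image_size, k_sigma)
    return Ellipse2D(center=px[0], cov2d=cov2d[0], footprint=pts, kernel=wgt, clipped=clipped)
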
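"""Calibrated pinhole cameras and their JSON serialization.

Each view carries a 3x3 intrinsic matrix K, a world-to-camera pose (R, t)
with x_cam = R @ x_world + t, the raster size in pixels, and a raw
variance-of-Laplacian sharpness score used to weight views during lifting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np


@dataclass
class CameraView:
    intrinsics: np.ndarray          # 3x3 upper-triangular pinhole matrix
    rotation: np.ndarray            # 3x3 world-to-camera rotation
    translation: np.ndarray         # length-3 world-to-camera translation
    image_size: tuple[int, int]     # (width, height) pixels
    sharpness: float = 1.0          # raw Laplacian-variance score, >= 0
    view_index: int = 0
    image_id: str = ""

    def __post_init__(self):
        self.intrinsics = np.asarray(self.intrinsics, dtype=np.float64).reshape(3, 3)
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        K = self.intrinsics
        if K[0, 0] <= 0 or K[1, 1] <= 0 or abs(K[1, 0]) > 1e-9 or abs(K[2, 0]) > 1e-9 or abs(K[2, 1]) > 1e-9:
            raise ValueError("intrinsics must be upper-triangular with positive focal lengths")
        RtR = self.rotation @ self.rotation.T
        if not np.allclose(RtR, np.eye(3), atol=1e-6) or np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be orthonormal with det +1")
        if self.sharpness < 0:
            raise ValueError("sharpness must be >= 0")

    @property
    def center(self) -> np.ndarray:
        """Camera center in world coordinates: -R^T t."""
        return -self.rotation.T @ self.translation

    def to_camera(self, points: np.ndarray) -> np.ndarray:
        """World points (..., 3) -> camera-frame coordinates."""
        return np.asarray(points) @ self.rotation.T + self.translation

    def project(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Pinhole projection; returns (pixels (..., 2), camera depth (...,))."""
        pc = self.to_camera(points)
        z = pc[..., 2]
        K = self.intrinsics
        u = K[0, 0] * pc[..., 0] / z + K[0, 1] * pc[..., 1] / z + K[0, 2]
        v = K[1, 1] * pc[..., 1] / z + K[1, 2]
        return np.stack([u, v], axis=-1), z

    def in_frustum(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask: point in front of camera and inside image bounds."""
        px, z = self.project(points)
        w, h = self.image_size
        return (z > 0) & (px[..., 0] >= 0) & (px[..., 0] <= w - 1) & (px[..., 1] >= 0) & (px[..., 1] <= h - 1)


def write_cameras_json(path, views: list[CameraView]) -> None:
    payload = []
    for v in views:
        K = v.intrinsics
        payload.append({
            "view_index": int(v.view_index),
            "image_id": v.image_id,
            "width": int(v.image_size[0]),
            "height": int(v.image_size[1]),
            "fx": K[0, 0], "fy": K[1, 1], "cx": K[0, 2], "cy": K[1, 2],
            "rotation": v.rotation.reshape(-1).tolist(),
            "translation": v.translation.tolist(),
            "sharpness": float(v.sharpness),
        })
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_cameras_json(path) -> list[CameraView]:
    with open(path) as fh:
        payload = json.load(fh)
    views = []
    for d in payload:
        K = np.array([[d["fx"], 0.0, d["cx"]], [0.0, d["fy"], d["cy"]], [0.0, 0.0, 1.0]])
        views.append(CameraView(
            intrinsics=K,
            rotation=np.asarray(d["rotation"], dtype=np.float64).reshape(3, 3),
            translation=np.asarray(d["translation"], dtype=np.float64),
            image_size=(int(d["width"]), int(d["height"])),
            sharpness=float(d.get("sharpness", 1.0)),
            view_index=int(d["view_index"]),
            image_id=d.get("image_id", ""),
        ))
    return views


def look_at_camera(center: np.ndarray, target: np.ndarray, *, fx: float, fy: float | None = None,
                   image_size: tuple[int, int], up=(0.0, 0.0, 1.0), sharpness: float = 1.0,
                   view_index: int = 0, image_id: str = "") -> CameraView:
    """Build a pinhole view at ``center`` looking toward ``target``.

    Camera convention: +z forward, +x right, +y down (image v axis).
    """
    center = np.asarray(center, dtype=np.float64)
    fwd = np.asarray(target, dtype=np.float64) - center
    fwd = fwd / np.linalg.norm(fwd)
    up = np.asarray(up, dtype=np.float64)
    right = np.cross(fwd, up)
    nr = np.linalg.norm(right)
    if nr < 1e-12:  # looking straight along up: pick an arbitrary right axis
        right = np.cross(fwd, np.array([1.0, 0.0, 0.0]))
        nr = np.linalg.norm(right)
    right /= nr
    down = np.cross(fwd, right)
    R = np.stack([right, down, fwd], axis=0)  # world->camera rows
    t = -R @ center
    w, h = image_size
    fy = fx if fy is None else fy
    K = np.array([[fx, 0.0, (w - 1) / 2.0], [0.0, fy, (h - 1) / 2.0], [0.0, 0.0, 1.0]])
    return CameraView(K, R, t, (w, h), sharpness=sharpness, view_index=view_index, image_id=image_id)
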
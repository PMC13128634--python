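"""Video-frame subsampling before structure-from-motion.

Dense capture yields far more frames than SfM needs; the policies here thin
the sequence while preserving pose quality.  Frame quality is scored by the
variance of the 3x3 discrete Laplacian (a standard focus measure); the
coverage+sharpness policy keeps the sharpest frame per temporal window,
subject to a minimum inter-frame motion (parallax proxy).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)

_LAPLACIAN = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])


@dataclass
class FrameScoreTable:
    """Per-frame quality scores; indices strictly increasing."""

    frame_index: np.ndarray
    sharpness: np.ndarray
    motion: np.ndarray | None = None  # inter-frame displacement proxy (px)

    def __post_init__(self):
        self.frame_index = np.asarray(self.frame_index, dtype=np.int64)
        self.sharpness = np.asarray(self.sharpness, dtype=np.float64)
        if np.any(np.diff(self.frame_index) <= 0):
            raise ValueError("frame indices must be strictly increasing")
        if np.any(self.sharpness < 0):
            raise ValueError("sharpness must be >= 0")
        if self.motion is None:
            self.motion = np.zeros_like(self.sharpness)
        else:
            self.motion = np.asarray(self.motion, dtype=np.float64)

    def __len__(self):
        return len(self.frame_index)


def laplacian_variance(image: np.ndarray) -> float:
    """Variance of the 3x3 Laplacian response over all valid (interior) pixels."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or min(image.shape) < 3:
        raise ValueError("image must be 2-D with at least 3x3 pixels")
    resp = ndimage.convolve(image, _LAPLACIAN, mode="constant")[1:-1, 1:-1]
    return float(np.var(resp))


def normalize_sharpness(scores: np.ndarray) -> np.ndarray:
    """Clip to the [P5, P95] range and rescale so P5 -> 0, P95 -> 1."""
    scores = np.asarray(scores, dtype=np.float64)
    if scores.size < 2:
        raise ValueError("need at least 2 frames to normalize sharpness")
    p5, p95 = np.percentile(scores, [5, 95])
    if p95 == p5:
        log.warning("degenerate sharpness spread (P5 == P95); all rho set to 1")
        return np.ones_like(scores)
    return np.clip((np.clip(scores, p5, p95) - p5) / (p95 - p5), 0.0, 1.0)


def patch_grid_motion(frame_a: np.ndarray, frame_b: np.ndarray, grid: int = 4,
                      patch: int = 16) -> float:
    """Cheap translation estimate between consecutive frames (pixels).

    Estimates a shift per patch on a coarse grid via FFT cross-correlation
    and returns the median displacement magnitude.
    """
    a = np.asarray(frame_a, dtype=np.float64)
    b = np.asarray(frame_b, dtype=np.float64)
    h, w = a.shape
    mags = []
    for gy in range(grid):
        for gx in range(grid):
            y0 = min(int(gy * h / grid), h - patch)
            x0 = min(int(gx * w / grid), w - patch)
            pa = a[y0:y0 + patch, x0:x0 + patch]
            pb = b[y0:y0 + patch, x0:x0 + patch]
            pa = pa - pa.mean()
            pb = pb - pb.mean()
            if pa.std() < 1e-9 or pb.std() < 1e-9:
                continue
            corr = np.fft.ifft2(np.fft.fft2(pa) * np.conj(np.fft.fft2(pb))).real
            dy, dx = np.unravel_index(np.argmax(corr), corr.shape)
            dy = dy - patch if dy > patch // 2 else dy
            dx = dx - patch if dx > patch // 2 else dx
            mags.append(np.hypot(dy, dx))
    return float(np.median(mags)) if mags else 0.0


def select_frames(table: FrameScoreTable, keep_fraction: float,
                  policy: str = "coverage_sharpness", min_motion: float = 2.0) -> np.ndarray:
    """Retained frame indices under a subsampling policy.

    Policies: ``uniform`` (even temporal spacing, start-anchored),
    ``sharpness`` (global top-k by Laplacian variance, re-sorted
    temporally), ``coverage_sharpness`` (sequence split into k contiguous
    windows; the sharpest frame per window is retained, skipping candidates
    whose cumulative motion since the previously retained frame is below
    ``min_motion``, falling back to the window's sharpest frame).
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    n = len(table)
    k = int(round(keep_fraction * n))
    if k < 2:
        raise ValueError(f"keep_fraction * N = {keep_fraction * n:.2f} < 2: too few frames")
    if policy == "uniform":
        pos = np.round(np.arange(k) * n / k).astype(int)
        return table.frame_index[np.minimum(pos, n - 1)]
    if policy == "sharpness":
        top = np.argsort(table.sharpness, kind="stable")[::-1][:k]
        return table.frame_index[np.sort(top)]
    if policy == "coverage_sharpness":
        bounds = np.round(np.arange(k + 1) * n / k).astype(int)
        cum_motion = np.concatenate([[0.0], np.cumsum(table.motion[1:])])
        retained: list[int] = []
        last = None
        for wi in range(k):
            lo, hi = bounds[wi], bounds[wi + 1]
            if hi <= lo:
                continue
            order = lo + np.argsort(table.sharpness[lo:hi], kind="stable")[::-1]
            chosen = None
            for cand in order:
                if last is None or cum_motion[cand] - cum_motion[last] >= min_motion:
                    chosen = cand
                    break
            if chosen is None:
                chosen = order[0]
                log.info("window %d: no candidate met min_motion=%.2f px; kept sharpest", wi, min_motion)
            retained.append(chosen)
            last = chosen
        return table.frame_index[np.asarray(retained, dtype=np.int64)]
    raise ValueError(f"unknown policy {policy!r}")
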
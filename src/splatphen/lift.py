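"""Stage 1: lift sparse 2D mask cues into per-Gaussian support scores.

Each Gaussian is projected into every seeded view.  The masked footprint
fraction

    s_tilde(g,v) = sum_{u in Omega} kappa(u) M_v(u),   s(g,v) = alpha_g * s_tilde

is combined across views with geometry- and quality-dependent weights

    w_v = alpha_bar(g,v) * max(cos theta(g,v), 0) * rho_v,

where alpha_bar is a visibility proxy (by default the splat's own opacity;
optionally the mean of a per-view accumulated-opacity map over the
footprint), theta is the angle between the viewing ray and the Gaussian's
shortest principal axis (the surface normal of flattened foliage splats,
sign-resolved via |cos|), and rho_v the percentile-normalized sharpness.
The multi-view support is the weighted mean

    S(g) = sum_v w_v s(g,v) / sum_v w_v,

and the foreground is the scene-adaptive top quantile F = {g : S(g) >= tau},
tau = quantile(S, q) with q = 0.88 by default (top 12% of lift score).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .cameras import CameraView
from .cues import CueSet
from .frames import normalize_sharpness
from .projection import _footprint, project_covariances
from .splats import SplatSet, derived_params, quat_to_rotmat

log = logging.getLogger(__name__)

DEFAULT_Q = 0.88


@dataclass
class LiftResult:
    support: np.ndarray                 # (N,) S(g) over the whole scene
    quantile_q: float | None = None
    threshold: float | None = None      # tau = quantile(S, q)
    foreground: np.ndarray | None = None  # positional indices with S >= tau
    per_view: list[dict] = field(default_factory=list)

    def save_npz(self, path) -> None:
        np.savez(path, support=self.support,
                 quantile_q=-1.0 if self.quantile_q is None else self.quantile_q,
                 threshold=np.nan if self.threshold is None else self.threshold,
                 foreground=np.empty(0, np.int64) if self.foreground is None else self.foreground)

    @classmethod
    def load_npz(cls, path) -> "LiftResult":
        d = np.load(path)
        q = float(d["quantile_q"])
        return cls(support=d["support"], quantile_q=None if q < 0 else q,
                   threshold=None if np.isnan(d["threshold"]) else float(d["threshold"]),
                   foreground=d["foreground"] if len(d["foreground"]) else None)


def masked_fraction(ellipse, mask: np.ndarray, alpha: float = 1.0):
    """Masked footprint fraction s_tilde and opacity-weighted score s."""
    if ellipse.empty:
        return 0.0, 0.0
    m = mask[ellipse.footprint[:, 1], ellipse.footprint[:, 0]]
    s_tilde = float(np.dot(ellipse.kernel, m.astype(np.float64)))
    return s_tilde, alpha * s_tilde


def splat_normals(splats: SplatSet) -> tuple[np.ndarray, np.ndarray]:
    """Shortest principal axis of each Gaussian (unit vectors) + degeneracy mask.

    For flattened foliage splats the smallest-scale axis is the surface
    normal.  When the two smallest scales coincide (within 1e-9 of the
    log-scale), orientation is uninformative and the mask flags it.
    """
    order = np.argsort(splats.log_scales, axis=1)
    smallest = order[:, 0]
    second = order[:, 1]
    rows = np.arange(len(splats))
    degenerate = np.abs(splats.log_scales[rows, smallest] - splats.log_scales[rows, second]) < 1e-9
    R = quat_to_rotmat(splats.rotations)
    normals = R[rows, :, smallest]
    return normals, degenerate


def view_weight(splats: SplatSet, view: CameraView, rho: float,
                alpha_bar: np.ndarray | None = None) -> np.ndarray:
    """Per-splat view weight w_v = alpha_bar * max(|cos theta|, 0) * rho."""
    _, alpha, _ = derived_params(splats)
    if alpha_bar is None:
        alpha_bar = alpha
    normals, degenerate = splat_normals(splats)
    rays = splats.positions - view.center
    rays = rays / np.maximum(np.linalg.norm(rays, axis=1, keepdims=True), 1e-12)
    cos = np.abs(np.einsum("ni,ni->n", rays, normals))
    cos[degenerate] = 1.0
    if degenerate.any():
        log.debug("%d splats with degenerate minimal axis; cos set to 1", degenerate.sum())
    return alpha_bar * np.maximum(cos, 0.0) * rho


def accumulated_opacity_map(splats: SplatSet, view: CameraView, scale: float = 0.25,
                            k_sigma: float = 3.0) -> np.ndarray:
    """Front-to-back composited opacity map at reduced resolution.

    Optional visibility proxy: alpha_bar(g,v) is then the mean of this map
    over the splat's footprint instead of the splat's own opacity.
    """
    w, h = view.image_size
    sw, sh = max(1, int(round(w * scale))), max(1, int(round(h * scale)))
    K = view.intrinsics.copy()
    K[:2] *= scale
    small = CameraView(K, view.rotation, view.translation, (sw, sh),
                       sharpness=view.sharpness, view_index=view.view_index)
    cov, alpha, _ = derived_params(splats)
    px, z, cov2d = project_covariances(cov, small, splats.positions)
    acc = np.zeros((sh, sw))
    transmit = np.ones((sh, sw))
    for i in np.argsort(z):
        if z[i] <= 0:
            continue
        pts, wgt, _ = _footprint(px[i], cov2d[i], (sw, sh), k_sigma)
        if len(pts) == 0:
            continue
        gauss = wgt / wgt.max()
        a = alpha[i] * gauss
        acc[pts[:, 1], pts[:, 0]] += transmit[pts[:, 1], pts[:, 0]] * a
        transmit[pts[:, 1], pts[:, 0]] *= 1.0 - a
    return np.clip(acc, 0.0, 1.0)


def support_scores(splats: SplatSet, views: list[CameraView], cues: CueSet,
                   k_sigma: float = 3.0, all_sharpness: np.ndarray | None = None,
                   visibility: str = "opacity", record_per_view: bool = False) -> LiftResult:
    """Aggregate cue masks over seeded views into per-Gaussian support S(g).

    ``views`` must contain every view referenced by the cues.  Sharpness is
    normalized over ``all_sharpness`` when the full scene's frame scores are
    available, otherwise over the seeded views themselves.  Views where a
    splat is behind the camera or fully clipped contribute to neither sum.
    """
    if not cues.entries:
        raise ValueError("no seeded views")
    cues.validate_against(views)
    by_index = {v.view_index: v for v in views}
    seeded = [by_index[vi] for vi in cues.view_indices]
    sharp = np.asarray([v.sharpness for v in seeded], dtype=np.float64)
    if all_sharpness is not None:
        pool = np.asarray(all_sharpness, dtype=np.float64)
        p5, p95 = np.percentile(pool, [5, 95])
        rho = np.ones_like(sharp) if p95 == p5 else np.clip((np.clip(sharp, p5, p95) - p5) / (p95 - p5), 0, 1)
    else:
        rho = normalize_sharpness(sharp) if len(seeded) > 1 else np.ones(1)

    n = len(splats)
    cov, alpha, _ = derived_params(splats)
    num = np.zeros(n)
    den = np.zeros(n)
    per_view: list[dict] = []
    for view, rho_v in zip(seeded, rho):
        mask = cues.combined_mask(view.view_index)
        alpha_bar = None
        if visibility == "accumulated":
            vmap = accumulated_opacity_map(splats, view, k_sigma=k_sigma)
        px, z, cov2d = project_covariances(cov, view, splats.positions)
        w_all = view_weight(splats, view, rho_v)
        s_tilde = np.zeros(n)
        valid = z > 0
        for i in np.nonzero(valid)[0]:
            pts, wgt, _ = _footprint(px[i], cov2d[i], view.image_size, k_sigma)
            if len(pts) == 0:
                valid[i] = False
                continue
            s_tilde[i] = np.dot(wgt, mask[pts[:, 1], pts[:, 0]])
            if visibility == "accumulated":
                sy = np.minimum((pts[:, 1] * vmap.shape[0]) // view.image_size[1], vmap.shape[0] - 1)
                sx = np.minimum((pts[:, 0] * vmap.shape[1]) // view.image_size[0], vmap.shape[1] - 1)
                w_all[i] = np.mean(vmap[sy, sx]) * (w_all[i] / max(alpha[i], 1e-12))
        s = alpha * s_tilde
        num[valid] += w_all[valid] * s[valid]
        den[valid] += w_all[valid]
        if record_per_view:
            per_view.append({"view_index": view.view_index, "rho": float(rho_v),
                             "s_tilde": s_tilde, "s": s, "w": np.where(valid, w_all, 0.0)})
    support = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return LiftResult(support=support, per_view=per_view)


def foreground_select(result: LiftResult, q: float = DEFAULT_Q) -> np.ndarray:
    """Scene-adaptive foreground: F = {g : S(g) >= quantile(S, q)} (ties kept)."""
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    s = result.support
    # tau = floor(q*N)-th order statistic: |F| = N - floor(q*N) plus ties,
    # and any q below 1/N keeps the whole scene
    rank = min(int(np.floor(q * len(s))), len(s) - 1)
    tau = float(np.partition(s, rank)[rank])
    if s.max() == s.min():
        log.warning("all lift scores identical; foreground = all splats")
    fg = np.nonzero(s >= tau)[0]
    result.quantile_q = q
    result.threshold = tau
    result.foreground = fg
    return fg
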
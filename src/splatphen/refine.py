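"""Stage 3: chromatic refinement in CIELAB and dual export.

Residual background splats that survived geometric clustering are removed
by color.  DC colors of the kept set are converted to CIELAB; a
full-covariance Gaussian mixture with up to four components (chosen by BIC)
models the color distribution, the dominant component is the one with
maximal weight, and every kept splat whose squared Mahalanobis distance to
the dominant component exceeds the zeta-quantile of the in-component
distance distribution is dropped (zeta = 0.80 by default; 0.90 in relaxed
mode for recall-sensitive downstream training data).

The refined subset is exported both as the Gaussian subset itself (all
original per-splat properties preserved) and as a dense colored point
cloud, sampling each Gaussian ellipsoid with a count proportional to its
opacity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import truncnorm
from skimage import color as _skcolor
from sklearn.mixture import GaussianMixture

from .splats import SplatSet, derived_params, quat_to_rotmat

log = logging.getLogger(__name__)

DEFAULT_ZETA = 0.80
RELAXED_ZETA = 0.90
GMM_MAX_COMPONENTS = 4
SUBSAMPLE_CAP = 50_000
QUANTILE_BINS = 8


@dataclass
class ColorModel:
    weights: np.ndarray       # (k,)
    means: np.ndarray         # (k, 3) Lab
    covariances: np.ndarray   # (k, 3, 3) full
    bic_trace: dict[int, float]

    @property
    def n_components(self) -> int:
        return len(self.weights)

    @property
    def dominant(self) -> int:
        return int(np.argmax(self.weights))

    def mahalanobis_sq(self, lab: np.ndarray, component: int | None = None) -> np.ndarray:
        c = self.dominant if component is None else component
        diff = np.atleast_2d(lab) - self.means[c]
        prec = np.linalg.inv(self.covariances[c])
        return np.einsum("ni,ij,nj->n", diff, prec, diff)

    def assign(self, lab: np.ndarray) -> np.ndarray:
        """Most-probable component per point."""
        lab = np.atleast_2d(lab)
        logp = np.empty((len(lab), self.n_components))
        for c in range(self.n_components):
            d2 = self.mahalanobis_sq(lab, c)
            _, logdet = np.linalg.slogdet(self.covariances[c])
            logp[:, c] = np.log(self.weights[c]) - 0.5 * (d2 + logdet)
        return np.argmax(logp, axis=1)


def rgb_to_lab(rgb: np.ndarray) -> np.ndarray:
    """sRGB in [0,1] -> CIELAB (D65); out-of-range inputs are clipped."""
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.min() < 0 or rgb.max() > 1:
        log.warning("rgb values outside [0,1] clipped before Lab conversion")
        rgb = np.clip(rgb, 0.0, 1.0)
    return _skcolor.rgb2lab(rgb.reshape(1, -1, 3)).reshape(rgb.shape)


def lab_to_rgb(lab: np.ndarray) -> np.ndarray:
    lab = np.asarray(lab, dtype=np.float64)
    return np.clip(_skcolor.lab2rgb(lab.reshape(1, -1, 3)).reshape(lab.shape), 0.0, 1.0)


def stratified_subsample(lab: np.ndarray, cap: int, rng: np.random.Generator) -> np.ndarray:
    """Quantile-cell subsample preserving the Lab distribution.

    Each channel is split at its 8-quantiles; cells are the resulting boxes
    and each occupied cell contributes proportionally to its occupancy.
    Returns row indices into ``lab``.
    """
    n = len(lab)
    if n <= cap:
        return np.arange(n)
    codes = np.zeros(n, dtype=np.int64)
    for ch in range(3):
        edges = np.quantile(lab[:, ch], np.linspace(0, 1, QUANTILE_BINS + 1)[1:-1])
        codes = codes * QUANTILE_BINS + np.searchsorted(edges, lab[:, ch])
    chosen: list[np.ndarray] = []
    cells, counts = np.unique(codes, return_counts=True)
    # proportional allocation with largest-remainder rounding to hit the cap
    exact = counts * (cap / n)
    base = np.floor(exact).astype(int)
    rem = cap - base.sum()
    order = np.argsort(exact - base)[::-1]
    base[order[:rem]] += 1
    for cell, take in zip(cells, base):
        if take == 0:
            continue
        members = np.nonzero(codes == cell)[0]
        chosen.append(rng.choice(members, size=min(take, len(members)), replace=False))
    return np.sort(np.concatenate(chosen))


def fit_color_gmm(lab: np.ndarray, max_components: int = GMM_MAX_COMPONENTS,
                  cap: int = SUBSAMPLE_CAP, rng_seed: int = 0) -> ColorModel:
    """BIC-selected full-covariance mixture over Lab colors (k = 1..4)."""
    lab = np.asarray(lab, dtype=np.float64).reshape(-1, 3)
    if len(lab) < 10:
        raise ValueError("need at least 10 points to fit the color model")
    rng = np.random.default_rng(rng_seed)
    idx = stratified_subsample(lab, cap, rng)
    data = lab[idx]
    best = None
    trace: dict[int, float] = {}
    for k in range(1, max_components + 1):
        if k > len(data):
            break
        gm = GaussianMixture(n_components=k, covariance_type="full",
                             reg_covar=1e-6, random_state=rng_seed, n_init=1)
        gm.fit(data)
        trace[k] = float(gm.bic(data))
        if best is None or trace[k] < trace[best[0]]:
            best = (k, gm)
    k, gm = best
    return ColorModel(weights=gm.weights_.copy(), means=gm.means_.copy(),
                      covariances=gm.covariances_.copy(), bic_trace=trace)


def chroma_filter(kept: np.ndarray, lab: np.ndarray, model: ColorModel,
                  zeta: float = DEFAULT_ZETA, tau: float | None = None) -> np.ndarray:
    """Keep splats inside the dominant component's zeta-coverage window.

    tau(zeta) is the zeta-quantile of the squared Mahalanobis distance of
    the dominant-assigned ("in-component") points; the D^2 <= tau test is
    then applied to *all* kept points, so points assigned elsewhere but
    chromatically compatible survive.  Passing ``tau`` reuses a previously
    estimated window (making the filter idempotent on its own output).
    """
    if not 0 < zeta < 1:
        raise ValueError("zeta must be in (0, 1)")
    kept = np.asarray(kept, dtype=np.int64)
    lab = np.asarray(lab, dtype=np.float64).reshape(-1, 3)
    if len(lab) != len(kept):
        raise ValueError("lab rows must correspond to kept entries")
    d2 = model.mahalanobis_sq(lab)
    if tau is None:
        in_comp = model.assign(lab) == model.dominant
        if in_comp.sum() < 5:
            log.warning("dominant component has < 5 members; chromatic filter skipped")
            return kept
        tau = float(np.quantile(d2[in_comp], zeta))
    return kept[d2 <= tau]


def coverage_threshold(lab: np.ndarray, model: ColorModel,
                       zeta: float = DEFAULT_ZETA) -> float:
    """The zeta-quantile of in-component squared Mahalanobis distances."""
    lab = np.asarray(lab, dtype=np.float64).reshape(-1, 3)
    in_comp = model.assign(lab) == model.dominant
    d2 = model.mahalanobis_sq(lab)
    return float(np.quantile(d2[in_comp], zeta))


def refine(scene: SplatSet, kept: np.ndarray, zeta: float = DEFAULT_ZETA,
           rng_seed: int = 0) -> tuple[np.ndarray, ColorModel]:
    """Fit the color model on the kept set and apply the chromatic window."""
    kept = np.asarray(kept, dtype=np.int64)
    _, _, rgb = derived_params(scene)
    lab = rgb_to_lab(rgb[kept])
    model = fit_color_gmm(lab, rng_seed=rng_seed)
    return chroma_filter(kept, lab, model, zeta=zeta), model


def export_point_cloud(splats: SplatSet, subset: np.ndarray, density: float = 20.0,
                       trunc: float = 2.0, rng_seed: int = 0):
    """Sample each Gaussian ellipsoid into a colored point cloud.

    Per splat, n_i = max(1, round(density * alpha_i)) points are drawn from
    N(mu_i, Sigma_i) truncated at ``trunc`` standard deviations along each
    principal axis; each point inherits the splat's DC RGB color.

    Returns (points (M, 3), colors (M, 3), source (M,) positional splat index).
    """
    subset = np.asarray(subset, dtype=np.int64)
    if len(subset) == 0:
        raise ValueError("subset is empty")
    if density < 1:
        raise ValueError("density must be >= 1")
    sub = splats.subset(subset)
    _, alpha, rgb = derived_params(sub)
    R = quat_to_rotmat(sub.rotations)
    scales = np.exp(sub.log_scales)
    rng = np.random.default_rng(rng_seed)
    counts = np.maximum(1, np.round(density * alpha).astype(int))
    total = int(counts.sum())
    z = truncnorm.rvs(-trunc, trunc, size=(total, 3), random_state=rng)
    rep = np.repeat(np.arange(len(sub)), counts)
    local = z * scales[rep]
    pts = sub.positions[rep] + np.einsum("nij,nj->ni", R[rep], local)
    return pts, rgb[rep], subset[rep]


def write_point_cloud_ply(path, points: np.ndarray, colors: np.ndarray) -> None:
    """Write x,y,z + 8-bit RGB as binary-little-endian PLY."""
    n = len(points)
    rec = np.empty(n, dtype=[("x", "<f4"), ("y", "<f4"), ("z", "<f4"),
                             ("red", "u1"), ("green", "u1"), ("blue", "u1")])
    rec["x"], rec["y"], rec["z"] = points.astype(np.float32).T
    rgb8 = np.clip(np.round(colors * 255), 0, 255).astype(np.uint8)
    rec["red"], rec["green"], rec["blue"] = rgb8.T
    header = ("ply\nformat binary_little_endian 1.0\n"
              f"element vertex {n}\n"
              "property float x\nproperty float y\nproperty float z\n"
              "property uchar red\nproperty uchar green\nproperty uchar blue\n"
              "end_header\n")
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(rec.tobytes())
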
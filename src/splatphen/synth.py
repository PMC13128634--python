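"""Synthetic multi-plant greenhouse splat scenes with full ground truth.

The generator emulates the structure of a trellised greenhouse row
reconstructed with 3D Gaussian Splatting, at the scale and with the
population statistics of early-vegetative muskmelon:

* a target plant at the origin and neighbor plants at the 0.72 m
  within-row spacing, each built as a mildly curved vertical stem of
  elongated Gaussians with ``round(N(6.9, 2.1))`` leaf junctions at
  internode spacings ``N(3.7, 0.9)`` cm, and one flattened-disc leaf of
  area ``N(74.9, 22.8)`` cm^2 per junction (short Gaussian axis = leaf
  normal);
* background structure: a ground plane, one pot per plant, vertical
  trellis posts and horizontal bars, all in gray/brown colors that are
  separable from the plant green in CIELAB;
* two horizontal camera passes at ~0.5 m and ~1.5 m height with pinhole
  intrinsics, mimicking an outbound/return video acquisition;
* a metric calibration reference: two bracket splats 0.42 m apart on the
  trellis (a rack-width stand-in), with the whole scene multiplied by a
  configurable fake reconstruction scale so metric alignment is exercised.

Colors are sampled in CIELAB and converted to DC coefficients, so the
chromatic separation is controlled in the space where filtering operates.
Each material carries one exact per-scene color; a small ``color_bleed``
fraction of splats receives continuous Lab jitter, emulating the mixed
colors 3DGS optimization produces at material boundaries while keeping
each material's color essentially uniform, as converged DC colors of a
homogeneous surface are.

Every splat carries exactly one ground-truth plant label (target /
neighbor / background) and, on the target plant, an organ label (stem or
leaf index); ground-truth traits are recorded from the constructed
geometry (internodes are exact arc lengths along the stem path, leaf areas
the nominal disc areas, height the realized apex height).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation
from scipy.spatial.transform import Rotation

from .cameras import CameraView, look_at_camera
from .cues import CueEntry, CueSet, bbox_of_mask
from .projection import _footprint, project_covariances
from .refine import lab_to_rgb
from .splats import SH_C0, SplatSet, derived_params
from .traits import TraitRecord

LABEL_BACKGROUND, LABEL_TARGET, LABEL_NEIGHBOR = 0, 1, 2


@dataclass
class SceneRecipe:
    """Study conditions of the synthetic greenhouse row."""

    n_neighbors: int = 2
    row_spacing_m: float = 0.72
    mean_nodes: float = 6.9
    sd_nodes: float = 2.1
    mean_internode_m: float = 0.037
    sd_internode_m: float = 0.009
    mean_leaf_area_m2: float = 74.9e-4
    sd_leaf_area_m2: float = 22.8e-4
    pot_top_m: float = 0.12
    stem_step_m: float = 0.008
    gaussians_per_leaf: int = 30
    plant_opacity_logit: float = 3.0
    background_opacity_logit: float = 0.5
    plant_lab: tuple[float, float, float] = (40.0, -35.0, 30.0)
    ground_lab: tuple[float, float, float] = (45.0, 6.0, 14.0)
    pot_lab: tuple[float, float, float] = (35.0, 10.0, 16.0)
    trellis_lab: tuple[float, float, float] = (60.0, 2.0, 4.0)
    color_bleed: float = 0.03         # fraction of splats with Lab jitter
    position_jitter_m: float = 0.002  # reconstruction noise on plant splats
    recon_scale: float = 1.19         # fake SfM scale factor
    ref_length_m: float = 0.42        # rack-width calibration reference
    cameras_per_pass: int = 10
    pass_heights_m: tuple[float, float] = (0.5, 1.5)
    image_size: tuple[int, int] = (200, 150)
    focal_px: float = 150.0
    max_splats: int = 6000            # scene budget

    def __post_init__(self):
        if self.n_neighbors < 0 or self.gaussians_per_leaf <= 0 or self.stem_step_m <= 0:
            raise ValueError("infeasible recipe: negative or zero sizes")
        if self.mean_internode_m <= 0 or self.mean_leaf_area_m2 <= 0:
            raise ValueError("infeasible recipe: non-positive trait means")


@dataclass
class SceneBundle:
    scene: SplatSet
    cameras: list[CameraView]
    gt_plant_labels: np.ndarray   # 0 background / 1 target / 2 neighbor
    gt_organ_class: np.ndarray    # "stem"/"leaf" on the target plant, "" elsewhere
    gt_leaf_id: np.ndarray        # leaf index on leaf splats, -1 elsewhere
    gt_traits: TraitRecord        # target-plant ground truth (metric units)
    ref_pair_index: np.ndarray    # two splat ids forming the calibration pair
    recipe: SceneRecipe
    seed: int
    cues: CueSet | None = None
    background_kind: np.ndarray = field(default=None)  # type: ignore[assignment]

    @property
    def target_index(self) -> np.ndarray:
        return np.nonzero(self.gt_plant_labels == LABEL_TARGET)[0]

    @property
    def background_index(self) -> np.ndarray:
        return np.nonzero(self.gt_plant_labels == LABEL_BACKGROUND)[0]


def _lab_to_dc(lab: np.ndarray) -> np.ndarray:
    rgb = lab_to_rgb(np.asarray(lab, dtype=np.float64))
    return (rgb - 0.5) / SH_C0


def _quat_with_axes(long_axis: np.ndarray, normal_hint: np.ndarray | None = None) -> np.ndarray:
    """Quaternion whose rotation puts ``long_axis`` first and the shortest
    scale axis last (the splat normal convention used across the package)."""
    a = long_axis / np.linalg.norm(long_axis)
    h = np.array([0.0, 0.0, 1.0]) if normal_hint is None else normal_hint
    b = np.cross(h, a)
    if np.linalg.norm(b) < 1e-9:
        b = np.cross(np.array([1.0, 0.0, 0.0]), a)
    b /= np.linalg.norm(b)
    c = np.cross(a, b)
    R = np.stack([a, b, c], axis=1)
    if np.linalg.det(R) < 0:
        R[:, 1] = -R[:, 1]
    q = Rotation.from_matrix(R).as_quat()
    return np.array([q[3], q[0], q[1], q[2]])


def _disc_quat(normal: np.ndarray) -> np.ndarray:
    n = normal / np.linalg.norm(normal)
    t = np.cross(n, np.array([0.0, 0.0, 1.0]))
    if np.linalg.norm(t) < 1e-9:
        t = np.array([1.0, 0.0, 0.0])
    t /= np.linalg.norm(t)
    u = np.cross(n, t)
    R = np.stack([t, u, n], axis=1)  # normal last = shortest axis
    if np.linalg.det(R) < 0:
        R[:, 0] = -R[:, 0]
    q = Rotation.from_matrix(R).as_quat()
    return np.array([q[3], q[0], q[1], q[2]])


def _make_plant(recipe: SceneRecipe, rng: np.random.Generator, base: np.ndarray):
    """One plant; returns (positions, log_scales, quats, organ_class, leaf_id, gt)."""
    # population statistics truncated to the observed cohort ranges
    n_nodes = int(np.clip(round(rng.normal(recipe.mean_nodes, recipe.sd_nodes)), 3, 16))
    spacings = np.clip(rng.normal(recipe.mean_internode_m, recipe.sd_internode_m, n_nodes),
                       0.019, 0.061)
    areas = np.clip(rng.normal(recipe.mean_leaf_area_m2, recipe.sd_leaf_area_m2, n_nodes),
                    39e-4, 122e-4)
    total_len = float(spacings.sum()) + 0.02  # short tip above the last node

    # stem path parameterized by arc length: gentle wobble around vertical
    ds = 0.002
    n_steps = int(np.ceil(total_len / ds))
    phase = rng.uniform(0, 2 * np.pi, 2)
    bend = rng.uniform(0.05, 0.12, 2)
    t = np.linspace(0, 1, n_steps)
    dirs = np.stack([bend[0] * np.sin(2 * np.pi * t + phase[0]),
                     bend[1] * np.sin(2 * np.pi * t + phase[1]),
                     np.ones(n_steps)], axis=1)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    path = base + np.concatenate([np.zeros((1, 3)), np.cumsum(dirs * ds, axis=0)])
    arc = np.arange(n_steps + 1) * ds
    junction_arc = np.cumsum(spacings)
    junction_idx = np.searchsorted(arc, junction_arc)
    junction_idx = np.minimum(junction_idx, n_steps)

    positions, log_scales, quats, organ, leaf_id = [], [], [], [], []

    # stem Gaussians along the path
    step = max(1, int(round(recipe.stem_step_m / ds)))
    sigma_long, sigma_short = 0.010, 0.0020
    for i in range(0, n_steps + 1, step):
        tangent = dirs[min(i, n_steps - 1)]
        positions.append(path[i])
        log_scales.append([np.log(sigma_long), np.log(sigma_short), np.log(sigma_short)])
        quats.append(_quat_with_axes(tangent))
        organ.append("stem")
        leaf_id.append(-1)

    # one petiole + disc leaf per junction
    gt_internodes = []
    prev = 0.0
    for j, (jarc, area) in enumerate(zip(junction_arc, areas)):
        if j > 0:  # internodes run between consecutive nodes; the segment
            gt_internodes.append(float(jarc - prev))  # below node 1 is not one
        prev = float(jarc)
        jpos = path[junction_idx[j]]
        azim = rng.uniform(0, 2 * np.pi)
        out = np.array([np.cos(azim), np.sin(azim), 0.25])
        out /= np.linalg.norm(out)
        pet_len = rng.uniform(0.04, 0.06)
        for frac in np.linspace(0.25, 1.0, 4):
            positions.append(jpos + out * pet_len * frac)
            log_scales.append([np.log(0.008), np.log(0.0018), np.log(0.0018)])
            quats.append(_quat_with_axes(out))
            organ.append("stem")
            leaf_id.append(-1)
        # flattened-disc leaf at the petiole end
        r = float(np.sqrt(area / np.pi))
        center = jpos + out * (pet_len + 0.55 * r)
        tilt = rng.uniform(0.25, 0.6)
        normal = np.array([np.sin(tilt) * np.cos(azim), np.sin(tilt) * np.sin(azim), np.cos(tilt)])
        tang = np.cross(normal, np.array([0.0, 0.0, 1.0]))
        if np.linalg.norm(tang) < 1e-9:
            tang = np.array([1.0, 0.0, 0.0])
        tang /= np.linalg.norm(tang)
        bitang = np.cross(normal, tang)
        sigma_p = 0.11 * r
        n_g = recipe.gaussians_per_leaf
        n_ring = min(n_g, max(6, n_g // 3))
        ring = np.linspace(0, 2 * np.pi, n_ring, endpoint=False) + rng.uniform(0, 2 * np.pi)
        rad_ring = np.full(n_ring, 0.78 * r)
        n_in = n_g - n_ring
        rad_in = 0.78 * r * np.sqrt(rng.uniform(0, 1, n_in))
        ang_in = rng.uniform(0, 2 * np.pi, n_in)
        rr = np.concatenate([rad_ring, rad_in])
        aa = np.concatenate([ring, ang_in])
        for rho, ang in zip(rr, aa):
            p = center + rho * (np.cos(ang) * tang + np.sin(ang) * bitang)
            positions.append(p)
            log_scales.append([np.log(sigma_p), np.log(sigma_p), np.log(sigma_p / 8)])
            quats.append(_disc_quat(normal))
            organ.append("leaf")
            leaf_id.append(j)

    gt = {"n_nodes": n_nodes, "internodes_m": gt_internodes,
          "leaf_areas_m2": areas.tolist(), "total_len": total_len}
    return (np.asarray(positions), np.asarray(log_scales), np.asarray(quats),
            np.asarray(organ, dtype=object), np.asarray(leaf_id, dtype=np.int64), gt)


def _background(recipe: SceneRecipe, rng: np.random.Generator, plant_xs: list[float]):
    """Ground plane, pots, trellis; returns (pos, ls, quat, kind, ref_pair_local)."""
    positions, log_scales, quats, kind = [], [], [], []
    up = np.array([0.0, 0.0, 1.0])

    # ground plane: flattened discs on a jittered grid
    xs = np.arange(-1.2, 1.21, 0.06)
    ys = np.arange(-0.8, 0.81, 0.06)
    for x in xs:
        for y in ys:
            p = np.array([x, y, 0.0]) + rng.normal(0, 0.004, 3) * np.array([1, 1, 0.3])
            positions.append(p)
            log_scales.append([np.log(0.035), np.log(0.035), np.log(0.004)])
            quats.append(_disc_quat(up))
            kind.append("ground")

    # pots: cylinder shells under each plant
    for px in plant_xs:
        for z in np.linspace(0.02, recipe.pot_top_m, 5):
            for ang in np.linspace(0, 2 * np.pi, 16, endpoint=False):
                p = np.array([px + 0.07 * np.cos(ang), 0.07 * np.sin(ang), z])
                positions.append(p + rng.normal(0, 0.002, 3))
                log_scales.append([np.log(0.015), np.log(0.015), np.log(0.003)])
                quats.append(_disc_quat(np.array([np.cos(ang), np.sin(ang), 0.0])))
                kind.append("pot")

    # trellis: vertical posts between/behind plants + two horizontal bars
    post_xs = [-1.08, -0.36, 0.36, 1.08]
    for px in post_xs:
        for z in np.arange(0.0, 1.61, 0.04):
            positions.append(np.array([px, 0.25, z]) + rng.normal(0, 0.0015, 3))
            log_scales.append([np.log(0.02), np.log(0.006), np.log(0.006)])
            quats.append(_quat_with_axes(up))
            kind.append("trellis")
    for zbar in (0.8, 1.6):
        for x in np.arange(-1.2, 1.21, 0.04):
            positions.append(np.array([x, 0.25, zbar]) + rng.normal(0, 0.0015, 3))
            log_scales.append([np.log(0.02), np.log(0.006), np.log(0.006)])
            quats.append(_quat_with_axes(np.array([1.0, 0.0, 0.0])))
            kind.append("trellis")

    # rack-width calibration brackets: an exact ref_length_m apart
    ref_local = []
    for sgn in (-1.0, 1.0):
        ref_local.append(len(positions))
        positions.append(np.array([sgn * recipe.ref_length_m / 2, 0.25, 1.2]))
        log_scales.append([np.log(0.012), np.log(0.012), np.log(0.012)])
        quats.append(np.array([1.0, 0.0, 0.0, 0.0]))
        kind.append("bracket")

    return (np.asarray(positions), np.asarray(log_scales), np.asarray(quats),
            np.asarray(kind, dtype=object), np.asarray(ref_local, dtype=np.int64))


def make_scene(recipe: SceneRecipe | None = None, seed: int = 0) -> SceneBundle:
    """Deterministic synthetic greenhouse scene with full ground truth."""
    recipe = recipe or SceneRecipe()
    rng = np.random.default_rng(seed)

    plant_xs = [0.0]
    for i in range(recipe.n_neighbors):
        plant_xs.append(recipe.row_spacing_m * (1 if i % 2 == 0 else -1) * (i // 2 + 1))

    pos_all, ls_all, quat_all = [], [], []
    labels, organ_all, leaf_all, kind_all = [], [], [], []
    gt_target = None
    for pi, px in enumerate(plant_xs):
        base = np.array([px, 0.0, recipe.pot_top_m])
        p, ls, q, organ, lid, gt = _make_plant(recipe, rng, base)
        if recipe.position_jitter_m > 0:
            p = p + rng.normal(0, recipe.position_jitter_m, p.shape)
        pos_all.append(p)
        ls_all.append(ls)
        quat_all.append(q)
        if pi == 0:
            gt_target = (gt, p, organ)
            labels.append(np.full(len(p), LABEL_TARGET))
            organ_all.append(organ)
            leaf_all.append(lid)
        else:
            labels.append(np.full(len(p), LABEL_NEIGHBOR))
            organ_all.append(np.full(len(p), "", dtype=object))
            leaf_all.append(np.full(len(p), -1, dtype=np.int64))
        kind_all.append(np.full(len(p), "plant", dtype=object))

    bpos, bls, bquat, bkind, ref_local = _background(recipe, rng, plant_xs)
    ref_index = sum(len(p) for p in pos_all) + ref_local
    pos_all.append(bpos)
    ls_all.append(bls)
    quat_all.append(bquat)
    labels.append(np.full(len(bpos), LABEL_BACKGROUND))
    organ_all.append(np.full(len(bpos), "", dtype=object))
    leaf_all.append(np.full(len(bpos), -1, dtype=np.int64))
    kind_all.append(bkind)

    positions = np.concatenate(pos_all)
    log_scales = np.concatenate(ls_all)
    quats = np.concatenate(quat_all)
    labels = np.concatenate(labels)
    organ_class = np.concatenate(organ_all)
    leaf_id = np.concatenate(leaf_all)
    kind = np.concatenate(kind_all)
    n = len(positions)
    if n > recipe.max_splats:
        raise ValueError(f"recipe produced {n} splats > budget {recipe.max_splats}")

    # material colors: one exact Lab color per material + a bleed fraction
    lab = np.empty((n, 3))
    lab[labels != LABEL_BACKGROUND] = recipe.plant_lab
    lab[kind == "ground"] = recipe.ground_lab
    lab[kind == "pot"] = recipe.pot_lab
    lab[(kind == "trellis") | (kind == "bracket")] = recipe.trellis_lab
    bleed = rng.random(n) < recipe.color_bleed
    lab[bleed] += rng.normal(0, 5.0, (int(bleed.sum()), 3))
    dc = _lab_to_dc(lab)

    opacity = np.where(labels == LABEL_BACKGROUND,
                       recipe.background_opacity_logit, recipe.plant_opacity_logit)
    opacity = opacity + rng.normal(0, 0.2, n)

    # fake reconstruction scale on the whole geometry
    s = recipe.recon_scale
    scene = SplatSet(positions=positions * s, log_scales=log_scales + np.log(s),
                     rotations=quats, opacity_logits=opacity, dc_color=dc)

    # cameras: two passes along the row (scaled world)
    cameras = []
    vi = 0
    for hpass, height in enumerate(recipe.pass_heights_m):
        xs = np.linspace(-0.9, 0.9, recipe.cameras_per_pass)
        if hpass == 1:
            xs = xs[::-1]  # return pass
        for x in xs:
            cam = look_at_camera(np.array([x, -1.1, height]) * s,
                                 np.array([0.0, 0.0, 0.30]) * s,
                                 fx=recipe.focal_px, image_size=recipe.image_size,
                                 sharpness=float(rng.lognormal(5.0, 0.5)),
                                 view_index=vi, image_id=f"frame_{vi:04d}")
            cameras.append(cam)
            vi += 1

    gt, tpos, torgan = gt_target
    tmask = labels == LABEL_TARGET
    apex_z = float(positions[tmask, 2].max())
    gt_traits = TraitRecord(
        height_cm=100.0 * apex_z,
        lsa_cm2=1e4 * float(np.sum(gt["leaf_areas_m2"])),
        lai=float(np.sum(gt["leaf_areas_m2"])) / 0.036,
        leaf_count=gt["n_nodes"],
        node_count=gt["n_nodes"],
        internode_lengths_cm=[100.0 * x for x in gt["internodes_m"]],
        per_leaf_areas_cm2=[1e4 * a for a in gt["leaf_areas_m2"]],
    )
    return SceneBundle(scene=scene, cameras=cameras, gt_plant_labels=labels,
                       gt_organ_class=organ_class, gt_leaf_id=leaf_id,
                       gt_traits=gt_traits, ref_pair_index=ref_index,
                       recipe=recipe, seed=seed, background_kind=kind)


def render_cue_masks(bundle: SceneBundle, view_indices: list[int],
                     dilate_px: int = 0, clutter_boxes: int = 0,
                     dropout: float = 0.0, seed: int = 0) -> CueSet:
    """Binary cue masks of the target plant, with controllable looseness.

    The clean mask is the union of the filled 2-sigma projected ellipses of
    the target-plant splats; noise emulates loose zero-shot masks (binary
    dilation), background clutter (random rectangles set to 1) and missed
    thin parts (random dropout of per-splat ellipses).
    """
    rng = np.random.default_rng(seed)
    target = bundle.target_index
    sub = bundle.scene.subset(target)
    cov, _, _ = derived_params(sub)
    entries = []
    for vi in view_indices:
        view = bundle.cameras[vi]
        w, h = view.image_size
        mask = np.zeros((h, w), dtype=bool)
        px, z, cov2d = project_covariances(cov, view, sub.positions)
        keep = rng.random(len(sub)) >= dropout
        any_visible = False
        for i in np.nonzero(keep & (z > 0))[0]:
            pts, _, _ = _footprint(px[i], cov2d[i], view.image_size, 2.0)
            if len(pts):
                mask[pts[:, 1], pts[:, 0]] = True
                any_visible = True
            # thin sub-pixel projections still mark their center pixel
            u, v = int(round(px[i, 0])), int(round(px[i, 1]))
            if 0 <= u < w and 0 <= v < h:
                mask[v, u] = True
                any_visible = True
        if not any_visible:
            continue
        if dilate_px > 0:
            yy, xx = np.ogrid[-dilate_px:dilate_px + 1, -dilate_px:dilate_px + 1]
            mask = binary_dilation(mask, structure=xx**2 + yy**2 <= dilate_px**2)
        for _ in range(clutter_boxes):
            bw, bh = rng.integers(10, 30, 2)
            x0 = int(rng.integers(0, max(1, w - bw)))
            y0 = int(rng.integers(0, max(1, h - bh)))
            mask[y0:y0 + bh, x0:x0 + bw] = True
        entries.append(CueEntry(image_id=view.image_id, view_index=vi, mask_id=0,
                                bbox=bbox_of_mask(mask), mask=mask))
    if not entries:
        raise ValueError("target plant not visible in any requested view")
    return CueSet(entries)


DEFAULT_SEEDED_VIEWS = (2, 7, 14)
DEFAULT_MASK_NOISE = {"dilate_px": 3, "clutter_boxes": 2, "dropout": 0.0}


def default_suite_scene(seed: int) -> tuple[SceneBundle, CueSet]:
    """One scene of the default synthetic evaluation suite with noisy cues."""
    bundle = make_scene(SceneRecipe(), seed=seed)
    cues = render_cue_masks(bundle, list(DEFAULT_SEEDED_VIEWS),
                            seed=seed + 10_000, **DEFAULT_MASK_NOISE)
    bundle.cues = cues
    return bundle, cues
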
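"""3D Gaussian Splatting scene container and PLY I/O.

A 3DGS scene is a set of anisotropic Gaussian primitives, each with a world
position mu, a covariance factored into per-axis log-scales and a rotation
quaternion, an opacity logit omega (alpha = sigmoid(omega)), and spherical
harmonic color coefficients of which only the DC band is used here.

The on-disk format is the binary-little-endian PLY dialect emitted by
reference 3DGS implementations: vertex properties x,y,z, optional normals,
``f_dc_0..2``, optional ``f_rest_*`` (stored but otherwise ignored),
``opacity``, ``scale_0..2`` (log-scales) and ``rot_0..3`` (w,x,y,z).
Unknown properties are preserved verbatim on write.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Degree-0 real spherical harmonic constant: Y_0^0 = 1/(2*sqrt(pi)).
SH_C0 = 0.28209479177387814

_REQUIRED_PROPS = (
    "x", "y", "z",
    "f_dc_0", "f_dc_1", "f_dc_2",
    "opacity",
    "scale_0", "scale_1", "scale_2",
    "rot_0", "rot_1", "rot_2", "rot_3",
)

_PLY_TYPES = {
    "char": "i1", "uchar": "u1", "short": "i2", "ushort": "u2",
    "int": "i4", "uint": "u4", "float": "f4", "double": "f8",
    "int8": "i1", "uint8": "u1", "int16": "i2", "uint16": "u2",
    "int32": "i4", "uint32": "u4", "float32": "f4", "float64": "f8",
}
_PLY_NAMES = {"i1": "char", "u1": "uchar", "i2": "short", "u2": "ushort",
              "i4": "int", "u4": "uint", "f4": "float", "f8": "double"}


class SplatFormatError(ValueError):
    """Raised when a PLY file does not follow the 3DGS vertex layout."""


class EmptySceneError(ValueError):
    """Raised when a scene file contains zero Gaussians."""


@dataclass
class SplatSet:
    """A 3DGS scene of N Gaussian primitives.

    Attributes
    ----------
    positions : (N, 3) float array of world coordinates (scene units).
    log_scales : (N, 3) log of the per-axis standard deviations.
    rotations : (N, 4) unit quaternions in (w, x, y, z) order.
    opacity_logits : (N,) opacity logits omega; alpha = sigmoid(omega).
    dc_color : (N, 3) spherical-harmonic DC coefficients.
    ids : (N,) stable integer indices (load order).
    extra : structured array of extra PLY properties, preserved on write.
    """

    positions: np.ndarray
    log_scales: np.ndarray
    rotations: np.ndarray
    opacity_logits: np.ndarray
    dc_color: np.ndarray
    ids: np.ndarray = field(default=None)  # type: ignore[assignment]
    extra: np.ndarray | None = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.float64).reshape(-1, 3)
        n = len(self.positions)
        self.log_scales = np.asarray(self.log_scales, dtype=np.float64).reshape(n, 3)
        self.rotations = np.asarray(self.rotations, dtype=np.float64).reshape(n, 4)
        self.opacity_logits = np.asarray(self.opacity_logits, dtype=np.float64).reshape(n)
        self.dc_color = np.asarray(self.dc_color, dtype=np.float64).reshape(n, 3)
        if self.ids is None:
            self.ids = np.arange(n, dtype=np.int64)
        else:
            self.ids = np.asarray(self.ids, dtype=np.int64).reshape(n)
        if len(np.unique(self.ids)) != n:
            raise ValueError("splat ids must be unique")
        norms = np.linalg.norm(self.rotations, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero-norm quaternion")
        # renormalize only when needed so float32 round trips stay bit-stable
        off = np.abs(norms - 1.0) > 1e-6
        if off.any():
            self.rotations = self.rotations.copy()
            self.rotations[off] /= norms[off, None]

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def n(self) -> int:
        return len(self)

    def subset(self, index: np.ndarray) -> "SplatSet":
        """Return the sub-scene at the given positional indices (ids kept)."""
        index = np.asarray(index, dtype=np.int64)
        return SplatSet(
            positions=self.positions[index],
            log_scales=self.log_scales[index],
            rotations=self.rotations[index],
            opacity_logits=self.opacity_logits[index],
            dc_color=self.dc_color[index],
            ids=self.ids[index],
            extra=None if self.extra is None else self.extra[index],
        )


def quat_to_rotmat(q: np.ndarray) -> np.ndarray:
    """Rotation matrices (..., 3, 3) from unit quaternions (..., 4) wxyz."""
    q = np.asarray(q, dtype=np.float64)
    w, x, y, z = q[..., 0], q[..., 1], q[..., 2], q[..., 3]
    R = np.empty(q.shape[:-1] + (3, 3))
    R[..., 0, 0] = 1 - 2 * (y * y + z * z)
    R[..., 0, 1] = 2 * (x * y - w * z)
    R[..., 0, 2] = 2 * (x * z + w * y)
    R[..., 1, 0] = 2 * (x * y + w * z)
    R[..., 1, 1] = 1 - 2 * (x * x + z * z)
    R[..., 1, 2] = 2 * (y * z - w * x)
    R[..., 2, 0] = 2 * (x * z - w * y)
    R[..., 2, 1] = 2 * (y * z + w * x)
    R[..., 2, 2] = 1 - 2 * (x * x + y * y)
    return R


def sigmoid(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=np.float64)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def derived_params(splats: SplatSet):
    """Per-Gaussian covariance, opacity and RGB color.

    Returns
    -------
    cov : (N, 3, 3) covariance Sigma = R diag(exp(log_scales)^2) R^T.
    alpha : (N,) opacity sigmoid(omega) in (0, 1).
    rgb : (N, 3) clip(0.5 + C0 * dc_color, 0, 1).
    """
    bad = ~(
        np.isfinite(splats.positions).all(axis=1)
        & np.isfinite(splats.log_scales).all(axis=1)
        & np.isfinite(splats.rotations).all(axis=1)
        & np.isfinite(splats.opacity_logits)
        & np.isfinite(splats.dc_color).all(axis=1)
    )
    if bad.any():
        raise ValueError(f"non-finite splat parameters at ids {splats.ids[bad][:5].tolist()}")
    R = quat_to_rotmat(splats.rotations)
    s2 = np.exp(splats.log_scales) ** 2
    cov = np.einsum("nij,nj,nkj->nik", R, s2, R)
    alpha = sigmoid(splats.opacity_logits)
    rgb = np.clip(0.5 + SH_C0 * splats.dc_color, 0.0, 1.0)
    return cov, alpha, rgb


# ---------------------------------------------------------------------------
# PLY codec (binary little endian, 3DGS vertex element)
# ---------------------------------------------------------------------------

def _parse_header(fh):
    line = fh.readline().strip()
    if line != b"ply":
        raise SplatFormatError("not a PLY file")
    fmt = None
    n_vertex = None
    props: list[tuple[str, str]] = []
    in_vertex = False
    while True:
        line = fh.readline()
        if not line:
            raise SplatFormatError("truncated PLY header")
        tokens = line.strip().decode("ascii").split()
        if not tokens:
            continue
        if tokens[0] == "format":
            fmt = tokens[1]
        elif tokens[0] == "element":
            in_vertex = tokens[1] == "vertex"
            if in_vertex:
                n_vertex = int(tokens[2])
        elif tokens[0] == "property" and in_vertex:
            if tokens[1] == "list":
                raise SplatFormatError("list properties are not supported in 3DGS PLY")
            if tokens[1] not in _PLY_TYPES:
                raise SplatFormatError(f"unknown PLY type {tokens[1]!r}")
            props.append((tokens[2], _PLY_TYPES[tokens[1]]))
        elif tokens[0] == "end_header":
            break
    if fmt != "binary_little_endian":
        raise SplatFormatError(f"unsupported PLY format {fmt!r} (need binary_little_endian)")
    if n_vertex is None:
        raise SplatFormatError("PLY has no vertex element")
    return n_vertex, props


def read_splat_ply(path) -> SplatSet:
    """Read a 3DGS scene from a binary-little-endian PLY file.

    Quaternions are renormalized on load; record order defines ids 0..N-1.
    Properties beyond the 3DGS set are kept in ``extra`` and round-trip
    verbatim through :func:`write_splat_ply`.
    """
    with open(path, "rb") as fh:
        n_vertex, props = _parse_header(fh)
        names = [p[0] for p in props]
        for req in _REQUIRED_PROPS:
            if req not in names:
                raise SplatFormatError(f"missing required 3DGS property {req!r}")
        if n_vertex == 0:
            raise EmptySceneError(f"{path}: zero Gaussians in scene")
        dtype = np.dtype([(name, "<" + code) for name, code in props])
        raw = np.frombuffer(fh.read(dtype.itemsize * n_vertex), dtype=dtype, count=n_vertex)
    col = lambda *ns: np.stack([raw[n].astype(np.float64) for n in ns], axis=1)
    extra_names = [n for n in names if n not in _REQUIRED_PROPS]
    extra = raw[extra_names].copy() if extra_names else None
    return SplatSet(
        positions=col("x", "y", "z"),
        log_scales=col("scale_0", "scale_1", "scale_2"),
        rotations=col("rot_0", "rot_1", "rot_2", "rot_3"),
        opacity_logits=raw["opacity"].astype(np.float64),
        dc_color=col("f_dc_0", "f_dc_1", "f_dc_2"),
        extra=extra,
    )


def write_splat_ply(path, splats: SplatSet) -> None:
    """Write a scene in the binary-little-endian 3DGS PLY dialect.

    Float properties are stored as float32 (the ecosystem convention); a
    write/read round trip is bit-stable at that precision.
    """
    n = len(splats)
    fields = [(name, "<f4") for name in _REQUIRED_PROPS]
    extra_names: list[str] = []
    if splats.extra is not None:
        for name in splats.extra.dtype.names:
            fields.append((name, splats.extra.dtype[name].str))
            extra_names.append(name)
    dtype = np.dtype(fields)
    rec = np.empty(n, dtype=dtype)
    rec["x"], rec["y"], rec["z"] = splats.positions.astype(np.float32).T
    rec["scale_0"], rec["scale_1"], rec["scale_2"] = splats.log_scales.astype(np.float32).T
    for i in range(4):
        rec[f"rot_{i}"] = splats.rotations[:, i].astype(np.float32)
    rec["opacity"] = splats.opacity_logits.astype(np.float32)
    for i in range(3):
        rec[f"f_dc_{i}"] = splats.dc_color[:, i].astype(np.float32)
    for name in extra_names:
        rec[name] = splats.extra[name]
    header = ["ply", "format binary_little_endian 1.0", f"element vertex {n}"]
    for name, code in fields:
        header.append(f"property {_PLY_NAMES[code.lstrip('<')]} {name}")
    header.append("end_header\n")
    with open(path, "wb") as fh:
        fh.write("\n".join(header).encode("ascii"))
        fh.write(rec.tobytes())
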
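"""Parametric synthetic torso/spine anatomy.

Generates a labeled voxel model of a human trunk for trans-spinal
direct-current stimulation (tsDCS) simulations: elliptical skin/fat/muscle
shells, a thoracolumbar vertebral column (low-conductivity vertebral bodies,
laminae and spinous processes separated by disks), a spinal canal with dura,
CSF and cord (white + gray matter), lateral spinal roots with dorsal root
ganglia (DRG) in the intervertebral foramina, and convex organ blobs
(lungs, heart, abdominal viscera).

The geometry is a deliberate stand-in for a licensed whole-body model:
primitive shapes with literature-typical dimensions, preserving the
topological features that shape the current flow — the high-conductivity
CSF channel, the bone barrier around it, and the root/foramen openings.

Coordinate convention (fixed throughout the package):

* ``+x`` — subject left, ``+y`` — dorsal, ``+z`` — rostral;
* voxel ``(i, j, k)`` is the cell centered at ``origin + (index + 0.5)·h``;
* the default anatomy is mirror-symmetric about the mid-sagittal plane
  ``x = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy import ndimage

from . import labels as L
from .errors import AnatomyError, ResolutionError, SegmentRangeError

__all__ = [
    "AnatomyParams",
    "LabelGrid",
    "CordFrame",
    "Landmarks",
    "ValidationCheck",
    "ValidationReport",
    "build_anatomy",
    "segment_for_z",
    "validate_anatomy",
    "DEFAULT_CORD_SEGMENTS",
    "DEFAULT_SEGMENT_WEIGHTS",
]

_CANONICAL_LEVELS = (
    [f"C{i}" for i in range(1, 8)]
    + [f"T{i}" for i in range(1, 13)]
    + [f"L{i}" for i in range(1, 6)]
    + ["sacrum"]
)

#: Cord segments represented in the model, rostral → caudal.
DEFAULT_CORD_SEGMENTS = (
    [f"T{i}" for i in range(6, 13)]
    + [f"L{i}" for i in range(1, 6)]
    + [f"S{i}" for i in range(1, 6)]
    + ["Co"]
)

#: Relative rostro-caudal lengths of cord segments.  Thoracic segments are
#: the longest, sacral ones the shortest; the ratios place the lumbar cord
#: adjacent to the T11–L1 vertebral bodies with the conus at the L1/L2 disk.
DEFAULT_SEGMENT_WEIGHTS = {"T": 1.5, "L": 1.0, "S": 0.35, "Co": 0.3}


class AnatomyParams(BaseModel):
    """Geometric parameters of the synthetic trunk, all lengths in mm."""

    grid_resolution: float = 2.0
    torso_height: float = 460.0
    torso_semi_axes: tuple[float, float] = (130.0, 95.0)  # (x: left-right, y: AP)
    skin_thickness: float = 4.0
    fat_thickness: float = 8.0

    vertebral_body_radius: float = 16.0
    vertebral_body_height: float = 22.0
    disk_height: float = 6.0
    spinous_process_depth: float = 30.0
    spinous_process_width: float = 8.0
    lamina_thickness: float = 5.0

    canal_radius: float = 10.0
    canal_center_y: float = 35.0
    dura_thickness: float = 2.0
    cord_semi_axes: tuple[float, float] = (5.5, 4.0)  # (rl, vd)
    gm_semi_axes: tuple[float, float] = (2.5, 1.8)
    cauda_radius: float = 3.0

    root_radius: float = 2.5
    root_lateral_extent: float = 24.0
    drg_semi_axes: tuple[float, float, float] = (3.5, 2.5, 2.5)
    drg_lateral_offset: float = 15.0

    sacrum_height: float = 45.0
    sacrum_radius_scale: float = 1.25
    bottom_margin: float = 25.0

    levels: list[str] = Field(
        default_factory=lambda: [f"T{i}" for i in range(5, 13)]
        + [f"L{i}" for i in range(1, 6)]
    )
    drg_levels: list[str] = Field(
        default_factory=lambda: ["T12", "L1", "L2", "L3", "L4", "L5"]
    )
    cord_segments: list[str] = Field(
        default_factory=lambda: list(DEFAULT_CORD_SEGMENTS)
    )
    segment_weights: dict[str, float] = Field(
        default_factory=lambda: dict(DEFAULT_SEGMENT_WEIGHTS)
    )
    conus_level_pair: tuple[str, str] = ("L1", "L2")

    rng_seed: int = 0
    jitter_mm: float = 0.0

    @model_validator(mode="after")
    def _check(self) -> "AnatomyParams":
        positive = {
            "grid_resolution": self.grid_resolution,
            "torso_height": self.torso_height,
            "skin_thickness": self.skin_thickness,
            "fat_thickness": self.fat_thickness,
            "vertebral_body_radius": self.vertebral_body_radius,
            "vertebral_body_height": self.vertebral_body_height,
            "disk_height": self.disk_height,
            "canal_radius": self.canal_radius,
            "dura_thickness": self.dura_thickness,
            "root_radius": self.root_radius,
        }
        for name, value in positive.items():
            if value <= 0:
                raise AnatomyError(f"{name} must be > 0, got {value}")
        if not all(v > 0 for v in self.torso_semi_axes + self.cord_semi_axes
                   + self.gm_semi_axes + self.drg_semi_axes):
            raise AnatomyError("all semi-axes must be > 0")

        inner = self.canal_radius - self.dura_thickness
        if not (max(self.gm_semi_axes) < max(self.cord_semi_axes) < inner
                and self.gm_semi_axes[0] < self.cord_semi_axes[0]
                and self.gm_semi_axes[1] < self.cord_semi_axes[1]):
            raise AnatomyError(
                "nesting constraint violated: need gm_semi_axes < "
                "cord_semi_axes < canal_radius - dura_thickness "
                f"({self.gm_semi_axes} / {self.cord_semi_axes} / {inner})"
            )

        thin = min(self.dura_thickness, self.root_radius)
        if self.grid_resolution > thin:
            raise ResolutionError(
                f"grid_resolution={self.grid_resolution} mm cannot resolve "
                f"the thinnest structure (min(dura_thickness, root_radius)="
                f"{thin} mm); refine the grid or thicken the structure"
            )

        order = [_CANONICAL_LEVELS.index(lv) for lv in self.levels
                 if lv in _CANONICAL_LEVELS]
        if len(order) != len(self.levels) or order != sorted(order):
            raise AnatomyError(
                f"levels must be known vertebral labels ordered rostral to "
                f"caudal, got {self.levels}"
            )
        for lv in self.drg_levels:
            if lv not in self.levels:
                raise AnatomyError(f"drg level {lv!r} not in levels")
        return self


# ---------------------------------------------------------------------------
# containers


@dataclass
class LabelGrid:
    """3-D voxel array of tissue labels with physical coordinates."""

    labels: np.ndarray  # (nx, ny, nz) uint8
    voxel_size: float  # mm, isotropic
    origin: np.ndarray  # (3,) mm, corner of voxel (0,0,0)
    label_dictionary: dict[int, str] = field(
        default_factory=lambda: dict(L.LABEL_NAMES)
    )

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def axis_centers(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centers along one axis."""
        n = self.labels.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.voxel_size

    def center_coords(self):
        """Sparse broadcastable (X, Y, Z) center-coordinate arrays."""
        x = self.axis_centers(0)[:, None, None]
        y = self.axis_centers(1)[None, :, None]
        z = self.axis_centers(2)[None, None, :]
        return x, y, z

    def world_to_index(self, point) -> tuple[int, int, int]:
        idx = np.floor((np.asarray(point, float) - self.origin)
                       / self.voxel_size).astype(int)
        return tuple(idx)

    def copy(self) -> "LabelGrid":
        return LabelGrid(self.labels.copy(), self.voxel_size,
                         self.origin.copy(), dict(self.label_dictionary))

    def mask(self, *label_ids: int) -> np.ndarray:
        return np.isin(self.labels, label_ids)

    def voxel_volume(self) -> float:
        return float(self.voxel_size ** 3)


@dataclass
class CordFrame:
    """Cord centerline with a per-point orthonormal triad.

    ``tangents`` point rostral; ``ventral`` is the dorsal→ventral axis and
    ``left`` the right→left axis, so (tangent, ventral, left) is a
    right-handed orthonormal triad at every centerline point.  Triads are
    interpolated linearly in z and re-orthonormalized.
    """

    points: np.ndarray  # (n, 3) mm, ordered caudal → rostral
    tangents: np.ndarray  # (n, 3) unit, pointing rostral
    ventral: np.ndarray  # (n, 3) unit, dorsal → ventral
    left: np.ndarray  # (n, 3) unit, right → left

    def __post_init__(self) -> None:
        for name in ("tangents", "ventral", "left"):
            v = getattr(self, name)
            norms = np.linalg.norm(v, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-9):
                raise AnatomyError(f"CordFrame.{name} must be unit vectors")

    @property
    def z_range(self) -> tuple[float, float]:
        return float(self.points[0, 2]), float(self.points[-1, 2])

    def triad_at(self, z: np.ndarray):
        """Interpolated orthonormal triads at the given z coordinates.

        Returns arrays of shape ``(len(z), 3)`` for (tangent, ventral, left),
        re-orthonormalized after linear interpolation so the triad is
        orthonormal to round-off at every query point.
        """
        z = np.atleast_1d(np.asarray(z, float))
        zs = self.points[:, 2]
        t = _interp_rows(z, zs, self.tangents)
        v = _interp_rows(z, zs, self.ventral)
        t /= np.linalg.norm(t, axis=1, keepdims=True)
        v -= (v * t).sum(axis=1, keepdims=True) * t
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        r = np.cross(t, v)
        return t, v, r


def _interp_rows(z, zs, rows):
    out = np.empty((len(z), rows.shape[1]))
    for c in range(rows.shape[1]):
        out[:, c] = np.interp(z, zs, rows[:, c])
    return out


@dataclass
class Landmarks:
    """Anatomical landmarks derived during construction."""

    interspinous_z: dict[str, float]  # "L1-L2" -> z mm
    spinous_process_z: dict[str, float]  # "T8" -> z mm
    drg_centers: dict[tuple[str, str], np.ndarray]  # ("L2","left") -> point
    root_axes: dict[tuple[str, str], np.ndarray]  # cord → periphery unit vec
    segment_z_ranges: dict[str, tuple[float, float]]  # "L1" -> (zmin, zmax)
    cord_z_range: tuple[float, float] = (0.0, 0.0)


# ---------------------------------------------------------------------------
# geometric stamping primitives (unit-tested against analytic volumes)


def ellipse_cylinder_mask(X, Y, Z, center_xy, semi_axes, z_range):
    """Voxels whose centers lie in an elliptic cylinder along z."""
    cx, cy = center_xy
    a, b = semi_axes
    r2 = ((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2
    return (r2 <= 1.0) & (Z >= z_range[0]) & (Z < z_range[1])


def annulus_mask(X, Y, Z, center_xy, r_inner, r_outer, z_range):
    cx, cy = center_xy
    d2 = (X - cx) ** 2 + (Y - cy) ** 2
    return ((d2 >= r_inner ** 2) & (d2 < r_outer ** 2)
            & (Z >= z_range[0]) & (Z < z_range[1]))


def ellipsoid_mask(X, Y, Z, center, semi_axes):
    cx, cy, cz = center
    a, b, c = semi_axes
    return (((X - cx) / a) ** 2 + ((Y - cy) / b) ** 2
            + ((Z - cz) / c) ** 2) <= 1.0


def box_mask(X, Y, Z, x_range, y_range, z_range):
    return ((X >= x_range[0]) & (X < x_range[1])
            & (Y >= y_range[0]) & (Y < y_range[1])
            & (Z >= z_range[0]) & (Z < z_range[1]))


def cylinder_x_mask(X, Y, Z, center_yz, radius, x_range):
    """Circular cylinder with its axis along x (a lateral root channel)."""
    cy, cz = center_yz
    d2 = (Y - cy) ** 2 + (Z - cz) ** 2
    return (d2 <= radius ** 2) & (X >= x_range[0]) & (X <= x_range[1])


# ---------------------------------------------------------------------------
# anatomy builder


def build_anatomy(params: AnatomyParams) -> tuple[LabelGrid, CordFrame, Landmarks]:
    """Stamp the synthetic trunk onto a voxel grid.

    Deterministic for fixed parameters and seed.  Returns the label grid,
    the cord reference frame and the landmark tables (vertebral z positions,
    DRG centers, spinal-segment map).
    """
    p = params
    h = p.grid_resolution
    a, b = p.torso_semi_axes

    # grid extents: torso plus a 2-voxel background pad; even voxel counts in
    # x keep the lattice mirror-symmetric about x = 0
    pad = 2 * h
    nx = int(np.ceil(2 * (a + pad) / h / 2) * 2)
    ny = int(np.ceil(2 * (b + pad) / h / 2) * 2)
    nz = int(np.ceil((p.torso_height + 2 * pad) / h))
    origin = np.array([-nx * h / 2.0, -ny * h / 2.0, -pad])

    grid = LabelGrid(np.zeros((nx, ny, nz), dtype=np.uint8), h, origin)
    X, Y, Z = grid.center_coords()
    lab = grid.labels

    rng = np.random.default_rng(p.rng_seed)

    def stamp(mask, value, only=None):
        if only is not None:
            mask = mask & np.isin(lab, only)
        lab[mask] = value

    # --- outer shells (skin lids cap the truncation planes so the outer
    # surface is one closed, insulated shell)
    z0, z1 = 0.0, p.torso_height
    ts, tf = p.skin_thickness, p.fat_thickness
    stamp(ellipse_cylinder_mask(X, Y, Z, (0, 0), (a, b), (z0, z1)), L.SKIN)
    stamp(ellipse_cylinder_mask(X, Y, Z, (0, 0), (a - ts, b - ts),
                                (z0 + ts, z1 - ts)), L.FAT)
    stamp(ellipse_cylinder_mask(X, Y, Z, (0, 0), (a - ts - tf, b - ts - tf),
                                (z0 + ts + tf, z1 - ts - tf)), L.MUSCLE)

    # --- vertebral column z layout (built caudal → rostral)
    zb = p.bottom_margin
    sac_z = (zb, zb + p.sacrum_height)
    body_z: dict[str, tuple[float, float]] = {}
    disk_z: dict[tuple[str, str], tuple[float, float]] = {}  # (upper, lower)
    z_cursor = sac_z[1]
    below = "sacrum"
    for lv in reversed(p.levels):
        disk_z[(lv, below)] = (z_cursor, z_cursor + p.disk_height)
        z_cursor += p.disk_height
        body_z[lv] = (z_cursor, z_cursor + p.vertebral_body_height)
        z_cursor += p.vertebral_body_height
        below = lv
    column_top = z_cursor
    if column_top > z1 - ts:
        raise AnatomyError(
            f"vertebral column (top {column_top:.0f} mm) does not fit in the "
            f"torso height {p.torso_height:.0f} mm"
        )

    y_canal = p.canal_center_y
    y_body = y_canal - (p.canal_radius + p.vertebral_body_radius + 2.0)
    lam_outer = p.canal_radius + p.lamina_thickness
    sp_tip = y_canal + lam_outer + p.spinous_process_depth
    if sp_tip > b - ts - tf:
        raise AnatomyError("spinous processes would pierce the fat/skin shell")

    # --- organ blobs (anterior, midline-symmetric); the column overwrites
    z_top_c = column_top
    stamp(ellipsoid_mask(X, Y, Z, (48, -20, z_top_c - 80), (36, 42, 70)),
          L.LUNGS, only=[L.MUSCLE])
    stamp(ellipsoid_mask(X, Y, Z, (-48, -20, z_top_c - 80), (36, 42, 70)),
          L.LUNGS, only=[L.MUSCLE])
    stamp(ellipsoid_mask(X, Y, Z, (0, -35, z_top_c - 150), (28, 28, 45)),
          L.HEART, only=[L.MUSCLE, L.LUNGS])
    stamp(ellipsoid_mask(X, Y, Z, (0, -25, sac_z[1] + 95), (68, 45, 88)),
          L.VISCERA, only=[L.MUSCLE])

    # --- bony column
    spin_x: dict[str, float] = {}
    for lv, (zb0, zb1) in body_z.items():
        stamp(ellipse_cylinder_mask(
            X, Y, Z, (0, y_body),
            (p.vertebral_body_radius, p.vertebral_body_radius), (zb0, zb1)),
            L.BONE)
        stamp(annulus_mask(X, Y, Z, (0, y_canal), p.canal_radius, lam_outer,
                           (zb0, zb1)), L.BONE)
        jx = float(rng.normal(0.0, p.jitter_mm)) if p.jitter_mm > 0 else 0.0
        spin_x[lv] = jx
        w = p.spinous_process_width / 2
        stamp(box_mask(X, Y, Z, (jx - w, jx + w),
                       (y_canal + p.canal_radius, sp_tip), (zb0, zb1)),
              L.BONE)
    for (up, lo), (zd0, zd1) in disk_z.items():
        stamp(ellipse_cylinder_mask(
            X, Y, Z, (0, y_body),
            (p.vertebral_body_radius, p.vertebral_body_radius), (zd0, zd1)),
            L.DISK)
    sac_r = p.sacrum_radius_scale * p.vertebral_body_radius
    stamp(ellipse_cylinder_mask(X, Y, Z, (0, y_body), (sac_r, sac_r), sac_z),
          L.BONE)
    # posterior sacral wing toward the canal
    stamp(box_mask(X, Y, Z, (-sac_r / 2, sac_r / 2),
                   (y_body, y_canal + lam_outer), sac_z), L.BONE)

    # --- spinal canal contents; the canal overshoots the column top so the
    # (truncated) cord ends bathed in CSF, and dural discs cap both ends
    canal_z = (sac_z[0] + p.sacrum_height / 2.0, column_top + 10.0)
    r_in = p.canal_radius - p.dura_thickness
    stamp(annulus_mask(X, Y, Z, (0, y_canal), r_in, p.canal_radius, canal_z),
          L.DURA)
    rc = p.canal_radius
    stamp(ellipse_cylinder_mask(X, Y, Z, (0, y_canal), (rc, rc),
                                (canal_z[0] - p.dura_thickness, canal_z[0])),
          L.DURA)
    stamp(ellipse_cylinder_mask(X, Y, Z, (0, y_canal), (rc, rc),
                                (canal_z[1], canal_z[1] + p.dura_thickness)),
          L.DURA)
    stamp(ellipse_cylinder_mask(X, Y, Z, (0, y_canal), (r_in, r_in), canal_z),
          L.CSF)

    conus_z = float(np.mean(disk_z[p.conus_level_pair]))
    cord_z = (conus_z, column_top)
    stamp(ellipse_cylinder_mask(X, Y, Z, (0, y_canal), p.cord_semi_axes,
                                cord_z), L.SPINAL_WM)
    # GM column recessed from the cord end faces so it stays strictly
    # inside WM even at the truncated ends
    gm_z = (cord_z[0] + 2 * h, cord_z[1] - 2 * h)
    stamp(ellipse_cylinder_mask(X, Y, Z, (0, y_canal), p.gm_semi_axes,
                                gm_z), L.SPINAL_GM)
    # cauda equina below the conus
    stamp(ellipse_cylinder_mask(X, Y, Z, (0, y_canal),
                                (p.cauda_radius, p.cauda_radius),
                                (canal_z[0], conus_z)), L.ROOTS,
          only=[L.CSF])

    # --- roots + DRG through the intervertebral foramina
    drg_centers: dict[tuple[str, str], np.ndarray] = {}
    root_axes: dict[tuple[str, str], np.ndarray] = {}
    soft = [L.MUSCLE, L.FAT, L.DURA, L.CSF, L.DISK, L.VISCERA, L.LUNGS,
            L.HEART]
    for lv in p.drg_levels:
        below = _level_below(p.levels, lv)
        z_f = float(np.mean(disk_z[(lv, below)]))
        for side, sgn in (("left", 1.0), ("right", -1.0)):
            x_end = sgn * p.root_lateral_extent
            xr = (min(0.0, x_end), max(0.0, x_end))
            stamp(cylinder_x_mask(X, Y, Z, (y_canal, z_f), p.root_radius, xr),
                  L.ROOTS, only=soft)
            center = np.array([sgn * p.drg_lateral_offset, y_canal, z_f])
            stamp(ellipsoid_mask(X, Y, Z, center, p.drg_semi_axes),
                  L.ROOTS, only=soft + [L.ROOTS])
            drg_centers[(lv, side)] = center
            root_axes[(lv, side)] = np.array([sgn, 0.0, 0.0])

    # --- landmarks
    spinous_z = {lv: float(np.mean(body_z[lv])) for lv in p.levels}
    interspinous = {f"{up}-{lo}": float(np.mean(zr))
                    for (up, lo), zr in disk_z.items()}
    segments = _segment_map(p, cord_z)
    landmarks = Landmarks(
        interspinous_z=interspinous,
        spinous_process_z=spinous_z,
        drg_centers=drg_centers,
        root_axes=root_axes,
        segment_z_ranges=segments,
        cord_z_range=cord_z,
    )
    frame = _straight_frame(y_canal, cord_z)
    return grid, frame, landmarks


def _level_below(levels: list[str], lv: str) -> str:
    i = levels.index(lv)
    return levels[i + 1] if i + 1 < len(levels) else "sacrum"


def _straight_frame(y_canal: float, cord_z: tuple[float, float]) -> CordFrame:
    z = np.arange(cord_z[0], cord_z[1] + 1e-9, 5.0)
    if z[-1] < cord_z[1]:
        z = np.append(z, cord_z[1])
    n = len(z)
    pts = np.column_stack([np.zeros(n), np.full(n, y_canal), z])
    t = np.tile([0.0, 0.0, 1.0], (n, 1))  # rostral
    v = np.tile([0.0, -1.0, 0.0], (n, 1))  # dorsal → ventral
    r = np.cross(t, v)  # right → left = +x
    return CordFrame(pts, t, v, r)


def _segment_map(p: AnatomyParams,
                 cord_z: tuple[float, float]) -> dict[str, tuple[float, float]]:
    """Partition the cord extent into segments by relative length weights."""
    weights = []
    for seg in p.cord_segments:
        key = "Co" if seg == "Co" else seg[0]
        weights.append(p.segment_weights[key])
    weights = np.asarray(weights, float)
    frac = weights / weights.sum()
    length = cord_z[1] - cord_z[0]
    # segments listed rostral → caudal; z grows rostral
    edges = cord_z[1] - np.concatenate([[0.0], np.cumsum(frac)]) * length
    return {seg: (float(edges[i + 1]), float(edges[i]))
            for i, seg in enumerate(p.cord_segments)}


# ---------------------------------------------------------------------------
# segment lookup


def segment_for_z(z: float, landmarks: Landmarks) -> str:
    """Spinal segment containing the z coordinate (mm).

    Piecewise-constant in z; a z exactly on a boundary between two segments
    belongs to the more caudal one.  Raises :class:`SegmentRangeError`
    outside the mapped cord extent.
    """
    ranges = landmarks.segment_z_ranges
    segs = sorted(ranges, key=lambda s: ranges[s][0])  # caudal → rostral
    lo = ranges[segs[0]][0]
    hi = ranges[segs[-1]][1]
    if z < lo - 1e-9 or z > hi + 1e-9:
        raise SegmentRangeError(
            f"z={z} mm outside the cord segment map [{lo}, {hi}] mm")
    edges = np.array([ranges[s][1] for s in segs])  # rostral edges
    idx = int(np.searchsorted(edges, z, side="left"))
    return segs[min(idx, len(segs) - 1)]


# ---------------------------------------------------------------------------
# validation


@dataclass
class ValidationCheck:
    name: str
    passed: bool
    offending_count: int = 0
    detail: str = ""


@dataclass
class ValidationReport:
    checks: list[ValidationCheck]

    @property
    def passed(self) -> bool:
        return all(c.passed for c in self.checks)

    def __str__(self) -> str:
        lines = []
        for c in self.checks:
            status = "PASS" if c.passed else "FAIL"
            extra = f" ({c.detail})" if c.detail else ""
            lines.append(f"[{status}] {c.name}: {c.offending_count} offending"
                         f"{extra}")
        return "\n".join(lines)


_NEIGHBOR_SHIFTS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0),
                    (0, 0, 1), (0, 0, -1)]


def _shifted(arr: np.ndarray, shift, fill=0) -> np.ndarray:
    out = np.full_like(arr, fill)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, s in enumerate(shift):
        if s == 1:
            src[ax], dst[ax] = slice(1, None), slice(None, -1)
        elif s == -1:
            src[ax], dst[ax] = slice(None, -1), slice(1, None)
    out[tuple(dst)] = arr[tuple(src)]
    return out


def _containment_check(lab, inner_labels, allowed, name) -> ValidationCheck:
    inner = np.isin(lab, inner_labels)
    bad = np.zeros_like(inner)
    for shift in _NEIGHBOR_SHIFTS:
        nb = _shifted(lab, shift, fill=L.BACKGROUND)
        bad |= inner & ~np.isin(nb, allowed)
    n = int(bad.sum())
    detail = ""
    if n:
        i, j, k = (int(v[0]) for v in np.nonzero(bad))
        detail = f"first offending voxel index ({i}, {j}, {k})"
    return ValidationCheck(name, n == 0, n, detail)


def validate_anatomy(grid: LabelGrid) -> ValidationReport:
    """Run the structural invariant checks on a label grid.

    Checks: every label known; skin forms a closed shell around interior
    tissues (axis-ray test); CSF is a single 26-connected component; GM
    strictly inside WM, WM inside CSF/roots, CSF inside dura/cord/roots.
    Returns a report; it never raises — callers decide whether to refuse
    a failing grid.
    """
    lab = grid.labels
    checks: list[ValidationCheck] = []

    unknown = ~np.isin(lab, list(grid.label_dictionary))
    checks.append(ValidationCheck("known_labels", not unknown.any(),
                                  int(unknown.sum())))

    # closed skin shell: along each axis ray from outside, an interior tissue
    # voxel must be preceded by a skin voxel
    interior = np.isin(lab, [t for t in L.TISSUE_LABELS if t != L.SKIN])
    skin = lab == L.SKIN
    exposed = np.zeros_like(skin)
    for ax in range(3):
        for direction in (1, -1):
            sl = slice(None, None, direction)
            idx = [slice(None)] * 3
            idx[ax] = sl
            covered = np.cumsum(skin[tuple(idx)], axis=ax) > 0
            exposed |= (interior[tuple(idx)] & ~covered)[tuple(idx)]
    n_exp = int(exposed.sum())
    detail = ""
    if n_exp:
        i, j, k = (int(v[0]) for v in np.nonzero(exposed))
        detail = (f"breach reaches voxel ({i}, {j}, {k}), tissue "
                  f"{grid.label_dictionary.get(int(lab[i, j, k]), '?')}")
    checks.append(ValidationCheck("skin_closed_shell", n_exp == 0, n_exp,
                                  detail))

    csf = lab == L.CSF
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    _, n_comp = ndimage.label(csf, structure=structure)
    checks.append(ValidationCheck(
        "csf_single_component", n_comp == 1, max(0, n_comp - 1),
        f"component count {n_comp}"))

    checks.append(_containment_check(
        lab, [L.SPINAL_GM], [L.SPINAL_GM, L.SPINAL_WM], "gm_inside_wm"))
    checks.append(_containment_check(
        lab, [L.SPINAL_WM],
        [L.SPINAL_WM, L.SPINAL_GM, L.CSF, L.ROOTS], "wm_inside_csf"))
    checks.append(_containment_check(
        lab, [L.CSF],
        [L.CSF, L.DURA, L.SPINAL_WM, L.SPINAL_GM, L.ROOTS],
        "csf_inside_dura"))
    return ValidationReport(checks)
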
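"""Tissue conductivities and anisotropic tensor assembly.

Isotropic DC conductivities follow the standard literature compilation for
low-frequency volume-conductor models (skin 0.435 S/m, fat 0.040, muscle
0.355, CSF 1.790, bone 0.006 S/m, ...), plus the electrode materials
(saline gel 4 S/m, conductive rubber 44 S/m).

Muscle and spinal white matter are fibrous and conduct better along the
fiber axis.  Anisotropy is modeled with the volume constraint: given the
isotropic reference ``σ_iso`` and longitudinal:transverse ratio ``r``, the
tensor eigenvalues are

    σ_long = σ_iso · r^(2/3)   (along the fiber axis)
    σ_trans = σ_iso · r^(-1/3) (twice, transverse)

so that ``det(σ) = σ_long · σ_trans² = σ_iso³`` — the geometric mean of the
eigenvalues is preserved.  White-matter fibers follow the local cord
tangent; paravertebral muscle fibers are taken as longitudinal (body axis).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import labels as L
from .errors import AnatomyError, TissueLookupError
from .synthetic_anatomy import CordFrame, LabelGrid

__all__ = [
    "TissueEntry",
    "TissueTable",
    "ConductivityField",
    "default_tissue_table",
    "sigma_for_tissue",
    "build_anisotropic_tensor",
    "assemble_conductivity",
]

FIBER_RULES = ("none", "cord_tangent", "body_axis")


@dataclass(frozen=True)
class TissueEntry:
    name: str
    sigma_iso: float  # S/m
    anisotropic: bool = False
    anisotropy_ratio: float = 1.0  # longitudinal : transverse eigenvalues
    fiber_rule: str = "none"

    def __post_init__(self) -> None:
        if self.sigma_iso <= 0:
            raise AnatomyError(f"{self.name}: sigma_iso must be > 0")
        if self.anisotropy_ratio < 1.0:
            raise AnatomyError(f"{self.name}: anisotropy_ratio must be >= 1")
        if self.fiber_rule not in FIBER_RULES:
            raise AnatomyError(f"{self.name}: unknown fiber_rule "
                               f"{self.fiber_rule!r}")


@dataclass
class TissueTable:
    """Conductivity per tissue name (the names of the label dictionary)."""

    entries: dict[str, TissueEntry] = field(default_factory=dict)

    def __getitem__(self, name: str) -> TissueEntry:
        key = _normalize(name)
        if key not in self.entries:
            raise TissueLookupError(
                f"unknown tissue {name!r}; known: {sorted(self.entries)}")
        return self.entries[key]

    def __contains__(self, name: str) -> bool:
        return _normalize(name) in self.entries


_ALIASES = {
    "vertebrae": "vertebrae_bone",
    "bone": "vertebrae_bone",
    "disks": "intervertebral_disk",
    "disk": "intervertebral_disk",
    "intervertebral_disks": "intervertebral_disk",
    "dura": "dura_mater",
    "roots": "spinal_roots",
    "brainstem_spinal_roots": "spinal_roots",
    "spinal_wm_isotropic": "spinal_wm",
    "muscle_isotropic": "muscle",
}


def _normalize(name: str) -> str:
    key = name.strip().lower()
    for ch in "/- ()":
        key = key.replace(ch, "_")
    while "__" in key:
        key = key.replace("__", "_")
    key = key.strip("_")
    return _ALIASES.get(key, key)


def default_tissue_table(wm_ratio: float = 10.0,
                         muscle_ratio: float = 5.0) -> TissueTable:
    """The shipped conductivity table (S/m).

    ``wm_ratio`` and ``muscle_ratio`` set the longitudinal:transverse
    anisotropy of spinal white matter and muscle; pass 1.0 for a fully
    isotropic model.
    """
    def e(name, sigma, **kw):
        return TissueEntry(name, sigma, **kw)

    entries = [
        e("skin", 0.435),
        e("fat", 0.040),
        e("muscle", 0.355, anisotropic=muscle_ratio > 1,
          anisotropy_ratio=muscle_ratio, fiber_rule="body_axis"),
        e("lungs", 0.046),
        e("heart", 0.535),
        e("viscera", 0.123),
        e("vertebrae_bone", 0.006),
        e("intervertebral_disk", 0.200),
        e("dura_mater", 0.030),
        e("csf", 1.790),
        e("spinal_roots", 0.154),
        e("spinal_wm", 0.143, anisotropic=wm_ratio > 1,
          anisotropy_ratio=wm_ratio, fiber_rule="cord_tangent"),
        e("spinal_gm", 0.333),
        e("gel", 4.0),
        e("rubber", 44.0),
        # the metallic connector is handled as an isopotential boundary;
        # its bulk conductivity only enters the contact face conductance
        e("connector_anode", 1.0e6),
        e("connector_cathode", 1.0e6),
    ]
    return TissueTable({t.name: t for t in entries})


def sigma_for_tissue(name: str, table: TissueTable | None = None) -> float:
    """Isotropic reference conductivity (S/m) for a tissue name."""
    if table is None:
        table = default_tissue_table()
    return table[name].sigma_iso


def build_anisotropic_tensor(sigma_iso: float, direction, r: float) -> np.ndarray:
    """Volume-constrained conductivity tensor for a fiber direction.

    Eigenvalues are ``σ_iso·r^(2/3)`` along ``direction`` and
    ``σ_iso·r^(-1/3)`` (twice) transverse, so ``det = σ_iso³`` exactly.
    """
    d = np.asarray(direction, dtype=float)
    n = np.linalg.norm(d)
    if abs(n - 1.0) > 1e-9:
        raise AnatomyError(f"direction must be a unit vector, |d| = {n}")
    if r < 1.0:
        raise AnatomyError(f"anisotropy ratio must be >= 1, got {r}")
    s_long = sigma_iso * r ** (2.0 / 3.0)
    s_trans = sigma_iso * r ** (-1.0 / 3.0)
    return s_trans * np.eye(3) + (s_long - s_trans) * np.outer(d, d)


# tensor component order in the packed representation
TENSOR_COMPONENTS = ("xx", "yy", "zz", "xy", "xz", "yz")


@dataclass
class ConductivityField:
    """Per-voxel symmetric conductivity tensor, packed as 6 components.

    ``tensors[..., :3]`` are the diagonal (xx, yy, zz) and
    ``tensors[..., 3:]`` the off-diagonal (xy, xz, yz) entries in S/m;
    non-conductive (background) voxels are all-zero.  ``anisotropic`` marks
    voxels whose tensor was built from a fiber direction.
    """

    tensors: np.ndarray  # (nx, ny, nz, 6)
    anisotropic: np.ndarray  # (nx, ny, nz) bool
    voxel_size: float

    @property
    def has_off_diagonal(self) -> bool:
        return bool(np.any(self.tensors[..., 3:]))

    def full_tensor(self, index) -> np.ndarray:
        xx, yy, zz, xy, xz, yz = self.tensors[index]
        return np.array([[xx, xy, xz], [xy, yy, yz], [xz, yz, zz]])

    def determinants(self) -> np.ndarray:
        t = self.tensors
        xx, yy, zz, xy, xz, yz = (t[..., i] for i in range(6))
        return (xx * (yy * zz - yz ** 2) - xy * (xy * zz - yz * xz)
                + xz * (xy * yz - yy * xz))


def _pack(tensor: np.ndarray) -> np.ndarray:
    return np.array([tensor[0, 0], tensor[1, 1], tensor[2, 2],
                     tensor[0, 1], tensor[0, 2], tensor[1, 2]])


def assemble_conductivity(grid: LabelGrid, table: TissueTable | None = None,
                          frame: CordFrame | None = None) -> ConductivityField:
    """Map the label grid to a per-voxel conductivity tensor field.

    Isotropic tissues get ``σ_iso·I``.  Anisotropic tissues get the
    volume-constrained tensor with the fiber direction given by their rule:
    ``cord_tangent`` interpolates the cord frame at the voxel z (an error if
    the cord extends beyond the frame coverage), ``body_axis`` uses the
    global z axis.
    """
    if table is None:
        table = default_tissue_table()
    lab = grid.labels
    out = np.zeros(lab.shape + (6,), dtype=np.float64)
    aniso = np.zeros(lab.shape, dtype=bool)

    for label_id in np.unique(lab):
        if label_id == L.BACKGROUND:
            continue
        name = grid.label_dictionary[int(label_id)]
        entry = table[name]
        mask = lab == label_id
        if not entry.anisotropic:
            for c in range(3):
                out[..., c][mask] = entry.sigma_iso
            continue
        aniso |= mask
        if entry.fiber_rule == "body_axis":
            t = build_anisotropic_tensor(entry.sigma_iso, (0, 0, 1),
                                         entry.anisotropy_ratio)
            out[mask] = _pack(t)
        elif entry.fiber_rule == "cord_tangent":
            if frame is None:
                raise AnatomyError(
                    f"tissue {name!r} needs a cord frame (fiber_rule="
                    f"cord_tangent) but none was given")
            zs = grid.axis_centers(2)
            ks = np.unique(np.nonzero(mask)[2])
            zlo, zhi = frame.z_range
            tol = grid.voxel_size
            bad = (zs[ks] < zlo - tol) | (zs[ks] > zhi + tol)
            if bad.any():
                raise AnatomyError(
                    f"{name} voxels at z={zs[ks][bad][:3]} mm outside the "
                    f"cord frame coverage [{zlo}, {zhi}] mm")
            tangents, _, _ = frame.triad_at(zs[ks])
            for k, d in zip(ks, tangents):
                t = build_anisotropic_tensor(entry.sigma_iso, d,
                                             entry.anisotropy_ratio)
                sl = mask[:, :, k]
                out[:, :, k][sl] = _pack(t)
        else:  # pragma: no cover - rejected earlier by TissueEntry
            raise AnatomyError(f"unsupported fiber rule {entry.fiber_rule!r}")
    return ConductivityField(out, aniso, grid.voxel_size)
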
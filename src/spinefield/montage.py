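"""Electrode montages and session dosimetry.

Each electrode is a stack stamped onto the dorsal skin: a saline-gel layer
(50 × 50 × 2.5 mm) that conforms to the curved skin, a conductive rubber
pad (49 × 49 × 1 mm) on a flat plane above it, and a metallic connector
disc (10 mm diameter, 1 mm thick) embedded in the top face of the pad.
The connector is the isopotential current port of the solver.

Three montages are supported, all with the cathode over the lumbar spine
(cathodal tsDCS convention):

* ``T8-L2`` — both electrodes on the midline: anode over the T8 spinous
  process, cathode between the L1 and L2 spinous processes;
* ``pvT8R-pvL2L`` — paravertebral: anode 25 mm to the right of T8,
  cathode 25 mm to the left of L1–L2;
* ``pvT8L-pvL2R`` — the mirror image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import labels as L
from .errors import PlacementError, SpinefieldError
from .synthetic_anatomy import LabelGrid, Landmarks

__all__ = [
    "ElectrodeSpec",
    "MontageModel",
    "SessionParams",
    "Dosimetry",
    "MONTAGE_PRESETS",
    "place_electrode",
    "preset_montage",
    "place_montage",
    "session_dosimetry",
]

#: Preset lateral offsets (mm, + = subject left) and anchors.
MONTAGE_PRESETS = {
    "T8-L2": {"anode": ("T8", 0.0), "cathode": ("L1-L2", 0.0)},
    "pvT8R-pvL2L": {"anode": ("T8", -25.0), "cathode": ("L1-L2", +25.0)},
    "pvT8L-pvL2R": {"anode": ("T8", +25.0), "cathode": ("L1-L2", -25.0)},
}


@dataclass(frozen=True)
class ElectrodeSpec:
    """One electrode of a montage.

    ``level_anchor`` is either a spinous-process label (``"T8"``) or an
    interspinous pair (``"L1-L2"``); ``lateral_offset`` is signed mm with
    + = subject left.  Sizes are (width x, height z, thickness y) in mm.
    """

    role: str  # "anode" | "cathode"
    level_anchor: str
    lateral_offset: float = 0.0
    gel_size: tuple[float, float, float] = (50.0, 50.0, 2.5)
    pad_size: tuple[float, float, float] = (49.0, 49.0, 1.0)
    connector_diameter: float = 10.0
    connector_thickness: float = 1.0

    def __post_init__(self) -> None:
        if self.role not in ("anode", "cathode"):
            raise SpinefieldError(f"role must be anode|cathode, {self.role!r}")
        if not (self.pad_size[0] <= self.gel_size[0]
                and self.pad_size[1] <= self.gel_size[1]):
            raise SpinefieldError("pad footprint must fit inside the gel")
        if self.connector_diameter >= min(self.pad_size[:2]):
            raise SpinefieldError("connector must fit strictly inside pad")

    @property
    def connector_label(self) -> int:
        return (L.CONNECTOR_ANODE if self.role == "anode"
                else L.CONNECTOR_CATHODE)


@dataclass(frozen=True)
class MontageModel:
    name: str
    electrodes: tuple[ElectrodeSpec, ElectrodeSpec]

    def __post_init__(self) -> None:
        roles = sorted(e.role for e in self.electrodes)
        if roles != ["anode", "cathode"]:
            raise SpinefieldError(
                f"montage needs exactly one anode and one cathode, {roles}")

    @property
    def anode(self) -> ElectrodeSpec:
        return next(e for e in self.electrodes if e.role == "anode")

    @property
    def cathode(self) -> ElectrodeSpec:
        return next(e for e in self.electrodes if e.role == "cathode")


@dataclass(frozen=True)
class SessionParams:
    """Stimulation session: current (mA), duration (s), electrode area (cm²)."""

    current_mA: float = 4.0
    duration_s: float = 900.0
    electrode_area_cm2: float = 25.0
    safety_limit_A_per_m2: float = 250.0

    def __post_init__(self) -> None:
        if self.current_mA < 0:
            raise SpinefieldError("current must be >= 0")
        if self.duration_s <= 0 or self.electrode_area_cm2 <= 0:
            raise SpinefieldError("duration and area must be > 0")


@dataclass(frozen=True)
class Dosimetry:
    current_density_A_per_m2: float
    charge_density_mC_per_cm2: float
    within_safety_limit: bool


def session_dosimetry(params: SessionParams) -> Dosimetry:
    """Mean electrode current density I/A and delivered charge density I·t/A.

    4 mA for 900 s through a 25 cm² electrode gives 144 mC/cm² and a mean
    current density of 1.6 A/m², far below the 250 A/m² tissue-damage bound.
    """
    i_A = params.current_mA * 1e-3
    area_m2 = params.electrode_area_cm2 * 1e-4
    j = i_A / area_m2  # A/m²
    charge = (params.current_mA * params.duration_s
              / params.electrode_area_cm2)  # mC/cm²
    return Dosimetry(j, charge, j <= params.safety_limit_A_per_m2)


def preset_montage(name: str, landmarks: Landmarks) -> MontageModel:
    """Instantiate a named montage on a set of anatomical landmarks."""
    if name not in MONTAGE_PRESETS:
        raise SpinefieldError(
            f"unknown montage {name!r}; valid: {sorted(MONTAGE_PRESETS)}")
    spec = MONTAGE_PRESETS[name]
    electrodes = []
    for role in ("anode", "cathode"):
        anchor, offset = spec[role]
        _anchor_z(anchor, landmarks)  # fail early on a missing landmark
        electrodes.append(ElectrodeSpec(role=role, level_anchor=anchor,
                                        lateral_offset=offset))
    return MontageModel(name, tuple(electrodes))


def _anchor_z(anchor: str, landmarks: Landmarks) -> float:
    if "-" in anchor:
        if anchor not in landmarks.interspinous_z:
            raise PlacementError(f"interspinous anchor {anchor!r} not in "
                                 f"landmarks")
        return landmarks.interspinous_z[anchor]
    if anchor not in landmarks.spinous_process_z:
        raise PlacementError(f"spinous anchor {anchor!r} not in landmarks")
    return landmarks.spinous_process_z[anchor]


def place_electrode(grid: LabelGrid, landmarks: Landmarks,
                    spec: ElectrodeSpec) -> LabelGrid:
    """Stamp one electrode stack onto the dorsal skin; returns a new grid.

    The gel fills the space between the curved skin surface and the flat
    pad base column-by-column (conforming contact, no air gap).  Stamping
    is idempotent; overlap with a *different* electrode is an error.
    """
    h = grid.voxel_size
    out = grid.copy()
    lab = out.labels
    nx, ny, nz = lab.shape
    xs, ys, zs = (grid.axis_centers(a) for a in range(3))

    xc = spec.lateral_offset
    zc = _anchor_z(spec.level_anchor, landmarks)
    half_x = spec.gel_size[0] / 2.0
    half_z = spec.gel_size[1] / 2.0

    ix = np.nonzero(np.abs(xs - xc) <= half_x)[0]
    iz = np.nonzero(np.abs(zs - zc) <= half_z)[0]
    if ix.size == 0 or iz.size == 0:
        raise PlacementError(
            f"electrode footprint at x={xc} mm, z={zc} mm is outside grid")

    anatomy = list(L.TISSUE_LABELS)
    # dorsal skin surface under each footprint column
    tissue_cols = np.isin(lab[np.ix_(ix, range(ny), iz)], anatomy)
    has_body = tissue_cols.any(axis=1)
    if not has_body.all():
        n_off = int((~has_body).sum())
        raise PlacementError(
            f"electrode at x={xc} mm, z={zc} mm: {n_off} footprint columns "
            f"miss the body (footprint off the dorsal skin)")
    j_top = ny - 1 - np.argmax(tissue_cols[:, ::-1, :], axis=1)
    surf_labels = lab[np.ix_(ix, range(ny), iz)][
        np.arange(ix.size)[:, None], j_top, np.arange(iz.size)[None, :]]
    if not np.all(surf_labels == L.SKIN):
        raise PlacementError(
            f"electrode at x={xc} mm, z={zc} mm does not rest on skin "
            f"everywhere (surface tissue ids {np.unique(surf_labels)})")

    gel_vox = max(1, round(spec.gel_size[2] / h))
    pad_vox = max(1, round(spec.pad_size[2] / h))
    conn_vox = max(1, round(spec.connector_thickness / h))
    j_pad = int(j_top.max()) + 1 + gel_vox  # flat pad base plane
    j_pad_end = j_pad + pad_vox
    if j_pad_end > ny:
        raise PlacementError("electrode stack exceeds the grid dorsally")

    stamp = np.zeros_like(lab)
    # gel: fill each column from the local skin surface to the pad base
    jj = np.arange(ny)
    gel_mask = ((jj[None, :, None] > j_top[:, None, :])
                & (jj[None, :, None] < j_pad))
    sub = stamp[np.ix_(ix, range(ny), iz)]
    sub[gel_mask] = L.GEL
    # rubber pad (slightly smaller footprint), then connector disc embedded
    # in the pad's top face
    pad_x = np.abs(xs[ix] - xc) <= spec.pad_size[0] / 2.0
    pad_z = np.abs(zs[iz] - zc) <= spec.pad_size[1] / 2.0
    pad_fp = pad_x[:, None] & pad_z[None, :]
    view = sub[:, j_pad:j_pad_end, :]
    view[...] = np.where(pad_fp[:, None, :], L.RUBBER, view)
    conn_r = spec.connector_diameter / 2.0
    conn_fp = ((xs[ix][:, None] - xc) ** 2
               + (zs[iz][None, :] - zc) ** 2) <= conn_r ** 2
    j_conn = max(j_pad, j_pad_end - conn_vox)
    view = sub[:, j_conn:j_pad_end, :]
    view[...] = np.where(conn_fp[:, None, :], spec.connector_label, view)
    stamp[np.ix_(ix, range(ny), iz)] = sub

    new = stamp > 0
    clash = new & (lab != L.BACKGROUND) & (lab != stamp)
    if clash.any():
        ids = np.unique(lab[clash])
        raise PlacementError(
            f"electrode at x={xc} mm, z={zc} mm overlaps existing labels "
            f"{[grid.label_dictionary[int(i)] for i in ids]}")
    lab[new] = stamp[new]
    return out


def place_montage(grid: LabelGrid, landmarks: Landmarks,
                  montage: MontageModel) -> LabelGrid:
    """Stamp both electrodes of a montage."""
    out = place_electrode(grid, landmarks, montage.anode)
    return place_electrode(out, landmarks, montage.cathode)
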
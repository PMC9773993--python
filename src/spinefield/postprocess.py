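"""Spinal-cord E-field analyses.

Reproduces the standard tsDCS dosimetry read-outs on a solved field:

* decomposition of E into the cord-frame components — longitudinal
  ``E_long`` (positive = rostral→caudal), ventral–dorsal ``E_vd``
  (positive = dorsal→ventral) and right–left ``E_rl`` (positive =
  right→left) — plus the magnitude ``E_norm``;
* per-slice means along the cord (1 mm analysis slices on a fine grid;
  never thinner than a voxel);
* per-spinal-segment maxima of the slice means (the montage comparison
  table), taking the absolute value of the signed component means only at
  the maximum step;
* supra-threshold regions (E_norm ≥ 0.15 V/m by default, inclusive);
* spherical probes at the dorsal-root-ganglion landmarks with the signed
  field projection onto the root axis (positive = cord→periphery);
* ranking of montages over a DRG or segment target.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import labels as L
from .errors import AnatomyError, ComparisonError, SpinefieldError
from .solver import FieldSolution
from .synthetic_anatomy import (CordFrame, LabelGrid, Landmarks,
                                segment_for_z)

__all__ = [
    "AnalysisConfig",
    "ComponentField",
    "decompose_components",
    "slice_profile",
    "segment_summary",
    "threshold_regions",
    "drg_probe",
    "compare_montages",
    "segments_between",
    "anatomy_hash",
    "cord_masks",
]

COMPONENT_COLUMNS = ("mean_e_norm", "mean_e_long", "mean_e_vd", "mean_e_rl")


@dataclass(frozen=True)
class AnalysisConfig:
    """Analysis parameters: threshold (V/m), slice thickness and probe radius (mm)."""

    neuromodulation_threshold: float = 0.15
    slice_thickness: float = 1.0
    drg_probe_radius: float = 2.0

    def __post_init__(self) -> None:
        if self.neuromodulation_threshold <= 0:
            raise SpinefieldError("threshold must be > 0")
        if self.slice_thickness <= 0 or self.drg_probe_radius <= 0:
            raise SpinefieldError("slice thickness and probe radius must be > 0")


@dataclass
class ComponentField:
    """Cord-frame components of E on the cord voxels (signed, V/m)."""

    e_long: np.ndarray  # (nx, ny, nz); NaN outside the cord masks
    e_vd: np.ndarray
    e_rl: np.ndarray
    e_norm: np.ndarray
    masks: dict[str, np.ndarray]  # tissue name -> voxel mask
    voxel_size: float
    z_centers: np.ndarray  # (nz,) voxel-center z coordinates, mm


def cord_masks(grid: LabelGrid) -> dict[str, np.ndarray]:
    """The GM and WM voxel masks used by all cord analyses."""
    return {"GM": grid.labels == L.SPINAL_GM,
            "WM": grid.labels == L.SPINAL_WM}


def decompose_components(sol: FieldSolution, frame: CordFrame,
                         masks: dict[str, np.ndarray]) -> ComponentField:
    """Project E onto the local cord triad at every cord voxel.

    The longitudinal axis is the *caudal* direction (−tangent), so a field
    pointing rostral→caudal has positive ``E_long``; ``E_vd`` is positive
    dorsal→ventral and ``E_rl`` positive right→left.  Raises if a cord
    voxel lies outside the frame's z coverage.
    """
    if sol.grid is None:
        raise SpinefieldError("FieldSolution carries no grid coordinates")
    shape = sol.E.shape[:3]
    union = np.zeros(shape, bool)
    for m in masks.values():
        union |= m
    h = sol.grid.voxel_size
    z_lo, z_hi = frame.z_range
    zs = sol.grid.axis_centers(2)
    ks = np.nonzero(union.any(axis=(0, 1)))[0]
    bad = (zs[ks] < z_lo - h) | (zs[ks] > z_hi + h)
    if bad.any():
        raise AnatomyError(
            f"cord voxels at z={zs[ks][bad][:3]} mm outside cord frame "
            f"coverage [{z_lo}, {z_hi}] mm")

    tang, vent, left = frame.triad_at(zs)
    e_long = np.full(shape, np.nan)
    e_vd = np.full(shape, np.nan)
    e_rl = np.full(shape, np.nan)
    e_norm = np.full(shape, np.nan)
    for k in ks:
        mk = union[:, :, k]
        Ek = sol.E[:, :, k][mk]  # (n, 3)
        e_long[:, :, k][mk] = Ek @ -tang[k]  # caudal = −tangent
        e_vd[:, :, k][mk] = Ek @ vent[k]
        e_rl[:, :, k][mk] = Ek @ left[k]
        e_norm[:, :, k][mk] = np.linalg.norm(Ek, axis=1)
    return ComponentField(e_long=e_long, e_vd=e_vd, e_rl=e_rl, e_norm=e_norm,
                          masks=dict(masks), voxel_size=h, z_centers=zs)


def slice_profile(comp: ComponentField, cfg: AnalysisConfig | None = None
                  ) -> pd.DataFrame:
    """Per-z-bin, per-tissue means of E_norm and the signed components.

    ``E_norm`` is averaged as the mean voxel magnitude; components keep
    their sign so opposing directions cancel.  Bins tile the cord z-extent
    at the configured thickness; bins with no voxels of a tissue appear
    with ``n_voxels = 0`` and NaN means (flagged missing, never zero).
    """
    if cfg is None:
        cfg = AnalysisConfig()
    if cfg.slice_thickness < comp.voxel_size:
        raise SpinefieldError(
            f"slice thickness {cfg.slice_thickness} mm is below the voxel "
            f"size {comp.voxel_size} mm")
    union = np.zeros(comp.e_norm.shape, bool)
    for m in comp.masks.values():
        union |= m
    if not union.any():
        raise SpinefieldError("empty cord masks")
    ks = np.nonzero(union.any(axis=(0, 1)))[0]
    z_min = comp.z_centers[ks[0]] - comp.voxel_size / 2
    z_max = comp.z_centers[ks[-1]] + comp.voxel_size / 2
    n_bins = int(np.ceil((z_max - z_min) / cfg.slice_thickness - 1e-9))
    edges = z_min + np.arange(n_bins + 1) * cfg.slice_thickness

    rows = []
    kbin = np.digitize(comp.z_centers, edges) - 1
    for tissue, mask in comp.masks.items():
        for b in range(n_bins):
            sel = mask & (kbin == b)[None, None, :]
            n = int(sel.sum())
            row = {"tissue": tissue, "bin": b,
                   "z_center": float(0.5 * (edges[b] + edges[b + 1])),
                   "n_voxels": n}
            if n:
                row.update({
                    "mean_e_norm": float(comp.e_norm[sel].mean()),
                    "mean_e_long": float(comp.e_long[sel].mean()),
                    "mean_e_vd": float(comp.e_vd[sel].mean()),
                    "mean_e_rl": float(comp.e_rl[sel].mean()),
                })
            else:
                row.update({c: np.nan for c in COMPONENT_COLUMNS})
            rows.append(row)
    return pd.DataFrame(rows)


def segment_summary(profile: pd.DataFrame, landmarks: Landmarks
                    ) -> pd.DataFrame:
    """Per-segment × tissue maxima of the slice means.

    For each spinal segment and tissue: the maximum over the segment's
    slices of the mean E_norm and of the *absolute* signed component means
    (the signs only enter here), with the arg-max slice z for E_norm.
    """
    prof = profile.dropna(subset=["mean_e_norm"]).copy()
    prof["segment"] = [segment_for_z(z, landmarks)
                       for z in prof["z_center"]]
    rows = []
    for (seg, tissue), g in prof.groupby(["segment", "tissue"]):
        i_max = g["mean_e_norm"].idxmax()
        rows.append({
            "segment": seg, "tissue": tissue,
            "max_e_norm": float(g["mean_e_norm"].max()),
            "max_abs_e_long": float(g["mean_e_long"].abs().max()),
            "max_abs_e_vd": float(g["mean_e_vd"].abs().max()),
            "max_abs_e_rl": float(g["mean_e_rl"].abs().max()),
            "argmax_z": float(g.loc[i_max, "z_center"]),
            "n_slices": int(len(g)),
        })
    out = pd.DataFrame(rows)
    order = sorted(landmarks.segment_z_ranges,
                   key=lambda s: -landmarks.segment_z_ranges[s][0])
    out["segment"] = pd.Categorical(out["segment"], categories=order,
                                    ordered=True)
    return out.sort_values(["tissue", "segment"]).reset_index(drop=True)


def threshold_regions(comp: ComponentField, cfg: AnalysisConfig | None = None,
                      landmarks: Landmarks | None = None):
    """Supra-threshold mask (E_norm ≥ threshold, inclusive) and statistics.

    Returns ``(mask, stats)`` where stats is a per-segment DataFrame with
    voxel counts, volume (mm³) and the covered fraction of each segment's
    cord voxels (requires ``landmarks``; otherwise a single global row).
    """
    if cfg is None:
        cfg = AnalysisConfig()
    union = np.zeros(comp.e_norm.shape, bool)
    for m in comp.masks.values():
        union |= m
    mask = union & (np.nan_to_num(comp.e_norm, nan=-1.0)
                    >= cfg.neuromodulation_threshold)
    vv = comp.voxel_size ** 3
    if landmarks is None:
        stats = pd.DataFrame([{
            "segment": "all", "n_voxels": int(mask.sum()),
            "volume_mm3": float(mask.sum() * vv),
            "coverage": float(mask.sum() / max(union.sum(), 1))}])
        return mask, stats
    rows = []
    for seg, (z0, z1) in sorted(landmarks.segment_z_ranges.items(),
                                key=lambda kv: -kv[1][0]):
        in_seg = (comp.z_centers >= z0) & (comp.z_centers < z1)
        seg_union = union & in_seg[None, None, :]
        seg_mask = mask & in_seg[None, None, :]
        n_all = int(seg_union.sum())
        n = int(seg_mask.sum())
        rows.append({"segment": seg, "n_voxels": n,
                     "volume_mm3": float(n * vv),
                     "coverage": float(n / n_all) if n_all else np.nan})
    return mask, pd.DataFrame(rows)


def drg_probe(sol: FieldSolution, grid: LabelGrid, landmarks: Landmarks,
              cfg: AnalysisConfig | None = None) -> pd.DataFrame:
    """Mean field in spheres at the DRG landmarks, with the root-axis sign.

    One row per (level, side): mean E_norm over conductive voxels within
    the probe radius, and the projection of the mean field onto the root
    axis — positive when the field points from the cord to the periphery.
    Empty probes are flagged (``n_voxels = 0``, NaN values).
    """
    if cfg is None:
        cfg = AnalysisConfig()
    X, Y, Z = grid.center_coords()
    En = sol.E_norm
    conductive = ~np.isnan(sol.phi)
    rows = []
    for (level, side), center in landmarks.drg_centers.items():
        d2 = (X - center[0]) ** 2 + (Y - center[1]) ** 2 + (Z - center[2]) ** 2
        sel = (d2 <= cfg.drg_probe_radius ** 2) & conductive
        n = int(sel.sum())
        row = {"level": level, "side": side, "n_voxels": n}
        if n:
            mean_E = sol.E[sel].mean(axis=0)
            axis = landmarks.root_axes[(level, side)]
            row.update({
                "mean_e_norm": float(En[sel].mean()),
                "projection": float(mean_E @ axis),
            })
        else:
            row.update({"mean_e_norm": np.nan, "projection": np.nan})
        rows.append(row)
    return pd.DataFrame(rows)


def segments_between(landmarks: Landmarks, montage) -> list[str]:
    """Spinal segments lying strictly between the two electrodes.

    The inter-electrode window runs from the inner (facing) edge of the
    caudal electrode's gel footprint to the inner edge of the rostral one;
    a segment qualifies when its whole z-range falls inside the window.
    This is where the induced field is predominantly longitudinal.
    """
    from .montage import _anchor_z

    spans = []
    for e in montage.electrodes:
        zc = _anchor_z(e.level_anchor, landmarks)
        half = e.gel_size[1] / 2.0
        spans.append((zc - half, zc + half))
    spans.sort()
    lo, hi = spans[0][1], spans[1][0]
    if lo >= hi:
        raise SpinefieldError("electrode footprints touch or overlap in z")
    return [seg for seg, (z0, z1) in landmarks.segment_z_ranges.items()
            if z0 >= lo and z1 <= hi]


def anatomy_hash(grid: LabelGrid) -> str:
    """Digest identifying the anatomy + electrode layout of a run."""
    hsh = hashlib.sha256()
    hsh.update(np.ascontiguousarray(grid.labels).tobytes())
    hsh.update(np.asarray([grid.voxel_size], float).tobytes())
    hsh.update(np.asarray(grid.origin, float).tobytes())
    return hsh.hexdigest()[:16]


@dataclass
class MontageRun:
    """One solved montage packaged for comparison."""

    name: str
    summary: pd.DataFrame
    drg_report: pd.DataFrame
    anatomy_digest: str
    current_mA: float = 4.0


def compare_montages(runs: list[MontageRun], target: dict) -> dict:
    """Rank montages by mean E_norm over a stated target.

    ``target`` is ``{"kind": "drg", "items": [(level, side), ...]}`` or
    ``{"kind": "segments", "items": [name, ...], "tissue": "GM"}``.  Runs
    must share the same anatomy digest (electrode layouts differ, so the
    digest is computed on the electrode-free grid) and current.  Ties are
    broken by montage name, ascending.
    """
    if len(runs) < 2:
        raise ComparisonError("need at least two montage runs to compare")
    digests = {r.anatomy_digest for r in runs}
    if len(digests) > 1:
        raise ComparisonError(f"anatomy digests differ across runs: {digests}")
    if len({r.current_mA for r in runs}) > 1:
        raise ComparisonError("runs use different injected currents")

    kind = target.get("kind")
    scores = {}
    for run in runs:
        if kind == "drg":
            rep = run.drg_report.set_index(["level", "side"])
            vals = [rep.loc[item, "mean_e_norm"] for item in target["items"]]
        elif kind == "segments":
            tissue = target.get("tissue", "GM")
            s = run.summary
            sel = s[(s["tissue"] == tissue)
                    & (s["segment"].isin(target["items"]))]
            vals = list(sel["max_e_norm"])
        else:
            raise ComparisonError(f"unknown target kind {kind!r}")
        if not len(vals):
            raise ComparisonError(f"target {target} matched nothing in "
                                  f"run {run.name!r}")
        scores[run.name] = float(np.mean(vals))

    ranking = sorted(scores, key=lambda n: (-scores[n], n))
    return {"target": target, "scores": scores, "ranking": ranking,
            "winner": ranking[0]}
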
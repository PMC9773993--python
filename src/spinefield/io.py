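"""Export and import of grids, fields and analysis tables.

Label grids and scalar/vector volumes go to NIfTI (RAS-like affine built
from the origin and isotropic voxel size), label dictionaries, landmarks
and run logs to JSON, tabular outputs to CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .solver import FieldSolution
from .synthetic_anatomy import CordFrame, LabelGrid, Landmarks

__all__ = [
    "save_label_grid",
    "load_label_grid",
    "save_volume",
    "save_landmarks",
    "save_cord_frame",
    "save_field_solution",
]


def _affine(grid: LabelGrid) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] *= grid.voxel_size
    aff[:3, 3] = grid.origin + grid.voxel_size / 2.0
    return aff


def save_label_grid(grid: LabelGrid, path: str | Path) -> None:
    """Write labels to NIfTI with the label dictionary as a JSON sidecar."""
    path = Path(path)
    img = nib.Nifti1Image(grid.labels.astype(np.int16), _affine(grid))
    nib.save(img, path)
    sidecar = path.with_suffix("").with_suffix(".labels.json")
    sidecar.write_text(json.dumps(
        {str(k): v for k, v in grid.label_dictionary.items()}, indent=1))


def load_label_grid(path: str | Path) -> LabelGrid:
    path = Path(path)
    img = nib.load(path)
    aff = img.affine
    voxel = float(aff[0, 0])
    origin = np.asarray(aff[:3, 3], float) - voxel / 2.0
    sidecar = path.with_suffix("").with_suffix(".labels.json")
    label_dict = None
    if sidecar.exists():
        label_dict = {int(k): v
                      for k, v in json.loads(sidecar.read_text()).items()}
    data = np.asarray(img.dataobj).astype(np.uint8)
    if label_dict is None:
        return LabelGrid(data, voxel, origin)
    return LabelGrid(data, voxel, origin, label_dict)


def save_volume(data: np.ndarray, grid: LabelGrid, path: str | Path) -> None:
    """Write a scalar or vector volume in the grid's coordinate system."""
    nib.save(nib.Nifti1Image(np.nan_to_num(data).astype(np.float32),
                             _affine(grid)), Path(path))


def save_landmarks(landmarks: Landmarks, path: str | Path) -> None:
    payload = {
        "interspinous_z": landmarks.interspinous_z,
        "spinous_process_z": landmarks.spinous_process_z,
        "drg_centers": {f"{lv}:{side}": list(map(float, c))
                        for (lv, side), c in landmarks.drg_centers.items()},
        "root_axes": {f"{lv}:{side}": list(map(float, a))
                      for (lv, side), a in landmarks.root_axes.items()},
        "segment_z_ranges": {k: list(v)
                             for k, v in landmarks.segment_z_ranges.items()},
        "cord_z_range": list(landmarks.cord_z_range),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def save_cord_frame(frame: CordFrame, path: str | Path) -> None:
    payload = {
        "points": frame.points.tolist(),
        "tangents": frame.tangents.tolist(),
        "ventral": frame.ventral.tolist(),
        "left": frame.left.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def save_field_solution(sol: FieldSolution, grid: LabelGrid,
                        out_dir: str | Path) -> None:
    """Export φ, |E|, E components, |J| and the solver run log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_volume(sol.phi, grid, out / "phi.nii.gz")
    save_volume(sol.E_norm, grid, out / "E_norm.nii.gz")
    for i, c in enumerate("xyz"):
        save_volume(sol.E[..., i], grid, out / f"E_{c}.nii.gz")
    save_volume(np.linalg.norm(sol.J, axis=-1), grid, out / "J_norm.nii.gz")
    log = {
        "montage": sol.montage_name,
        "current_mA": sol.current_mA,
        "electrode_currents_mA": sol.electrode_currents_mA,
        "relative_residual": sol.potential.relative_residual,
        "iterations": sol.potential.iterations,
        "voxel_size_mm": grid.voxel_size,
        "scale_factor": sol.scale_factor,
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=1))
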
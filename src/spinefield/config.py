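"""TOML run configuration.

A run file groups the tunables of a simulation::

    [anatomy]
    grid_resolution = 2.0

    [tissues]            # overrides of the shipped table (S/m)
    spinal_wm = { anisotropy_ratio = 10.0 }
    muscle = { sigma_iso = 0.355 }

    [montage]
    preset = "pvT8R-pvL2L"

    [session]
    current_mA = 4.0
    duration_s = 900.0

    [analysis]
    neuromodulation_threshold = 0.15

    [solver]
    tol = 1e-10
"""

from __future__ import annotations

import dataclasses
import tomllib
from pathlib import Path

from .conductivity import TissueTable, default_tissue_table
from .montage import SessionParams
from .postprocess import AnalysisConfig
from .synthetic_anatomy import AnatomyParams

__all__ = ["RunConfig", "load_config"]


@dataclasses.dataclass
class RunConfig:
    anatomy: AnatomyParams
    tissues: TissueTable
    montage_preset: str
    session: SessionParams
    analysis: AnalysisConfig
    solver_tol: float = 1e-10


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a TOML run config; missing sections fall back to defaults."""
    raw: dict = {}
    if path is not None:
        raw = tomllib.loads(Path(path).read_text())

    anatomy = AnatomyParams(**raw.get("anatomy", {}))
    table = default_tissue_table()
    for name, patch in raw.get("tissues", {}).items():
        entry = table[name]
        table.entries[entry.name] = dataclasses.replace(entry, **patch)

    session_kw = dict(raw.get("session", {}))
    montage_preset = raw.get("montage", {}).get("preset", "T8-L2")

    analysis_kw = dict(raw.get("analysis", {}))
    analysis_kw.setdefault("slice_thickness",
                           max(1.0, anatomy.grid_resolution))
    return RunConfig(
        anatomy=anatomy,
        tissues=table,
        montage_preset=montage_preset,
        session=SessionParams(**session_kw),
        analysis=AnalysisConfig(**analysis_kw),
        solver_tol=float(raw.get("solver", {}).get("tol", 1e-10)),
    )
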
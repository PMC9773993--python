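"""Analytic verification cases for the finite-volume solver.

Since the reference fields of a licensed whole-body model cannot be
redistributed, solver correctness is established against closed-form 1-D
current-flow problems instead:

* homogeneous bar — linear potential, uniform E = ΔV/L, Ohm's law current;
* layered slab — piecewise-linear potential; J_z continuous across the
  interface, E jumps by the conductivity ratio;
* anisotropic bar — volume-constrained tensor with the principal axis
  along the current; Ohm's law holds with σ_long = σ_iso·r^(2/3).

All cases put the connector layers at the bar ends, so the analytic
Dirichlet positions are the terminal cell centers; the homogeneous and
on-face layered cases are then reproduced exactly by the harmonic-mean
finite-volume scheme, and off-face interfaces provide genuine
discretization error for the convergence study.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import labels as L
from .conductivity import ConductivityField, build_anisotropic_tensor
from .errors import SpinefieldError
from .solver import (FieldSolution, assemble_system, compute_field,
                     electrode_current, solve_potential)
from .synthetic_anatomy import LabelGrid

__all__ = [
    "OracleCase",
    "OracleReport",
    "homogeneous_bar",
    "layered_slab",
    "anisotropic_bar",
    "run_oracle",
    "conservation_check",
    "convergence_study",
]


@dataclass(frozen=True)
class OracleCase:
    """A 1-D current-flow verification case (current along z).

    ``layers`` is a list of ``(thickness_mm, sigma_S_per_m)`` from the
    anode end; for the anisotropic bar ``anisotropy=(sigma_iso, ratio)``
    replaces the scalar conductivity.  ``delta_v`` is the total applied
    potential difference across the connector layers.
    """

    name: str
    layers: tuple[tuple[float, float], ...]
    cross_section_mm: tuple[float, float] = (12.0, 12.0)
    delta_v: float = 1.0
    anisotropy: tuple[float, float] | None = None  # (sigma_iso, ratio)

    @property
    def length_mm(self) -> float:
        return sum(t for t, _ in self.layers)


def homogeneous_bar(sigma: float = 0.355, length_mm: float = 50.0,
                    delta_v: float = 1.0,
                    cross_section_mm: tuple[float, float] = (10.0, 10.0)
                    ) -> OracleCase:
    return OracleCase("homogeneous_bar", ((length_mm, sigma),),
                      cross_section_mm, delta_v)


def layered_slab(sigma_top: float = 0.435, sigma_bottom: float = 0.006,
                 thickness_top: float = 24.0, thickness_bottom: float = 24.0,
                 delta_v: float = 1.0) -> OracleCase:
    return OracleCase("layered_slab",
                      ((thickness_top, sigma_top),
                       (thickness_bottom, sigma_bottom)),
                      delta_v=delta_v)


def anisotropic_bar(sigma_iso: float = 0.143, ratio: float = 10.0,
                    length_mm: float = 50.0, delta_v: float = 1.0
                    ) -> OracleCase:
    return OracleCase("anisotropic_bar", ((length_mm, sigma_iso),),
                      delta_v=delta_v, anisotropy=(sigma_iso, ratio))


# labels given to successive layers so the field gradient is one-sided at
# the material interface
_LAYER_LABELS = (L.MUSCLE, L.SKIN, L.FAT, L.HEART)


def _build_case(case: OracleCase, resolution: float
                ) -> tuple[LabelGrid, ConductivityField, np.ndarray]:
    """Voxelize an oracle case; returns grid, tensors and per-cell σ_zz."""
    h = resolution
    nxy = (max(2, round(case.cross_section_mm[0] / h)),
           max(2, round(case.cross_section_mm[1] / h)))
    n_layers = [round(t / h) for t, _ in case.layers]
    if min(n_layers) < 1:
        raise SpinefieldError(f"resolution {h} mm too coarse for case "
                              f"{case.name!r}")
    nz = sum(n_layers) + 2  # one connector layer at each end
    labels = np.zeros((nxy[0], nxy[1], nz), dtype=np.uint8)
    sigma_z = np.zeros(nz)

    k = 1
    for i, ((_, sig), n) in enumerate(zip(case.layers, n_layers)):
        labels[:, :, k:k + n] = _LAYER_LABELS[i]
        sigma_z[k:k + n] = sig
        k += n
    labels[:, :, 0] = L.CONNECTOR_ANODE
    labels[:, :, -1] = L.CONNECTOR_CATHODE
    # metal-like connector layers: negligible series resistance, so the
    # analytic Dirichlet planes sit at the material end faces (1e6 S/m keeps
    # the system well-conditioned for CG while adding < 1e-8 relative R)
    sigma_z[0] = sigma_z[-1] = 1e6

    tensors = np.zeros(labels.shape + (6,))
    if case.anisotropy is not None:
        sig_iso, r = case.anisotropy
        t = build_anisotropic_tensor(sig_iso, (0, 0, 1), r)
        packed = np.array([t[0, 0], t[1, 1], t[2, 2],
                           t[0, 1], t[0, 2], t[1, 2]])
        tensors[...] = packed
        sigma_z[1:-1] = t[2, 2]
        for c in range(3):
            tensors[..., c][:, :, 0] = sigma_z[0]
            tensors[..., c][:, :, -1] = sigma_z[-1]
        tensors[..., 3:][:, :, 0] = 0.0
        tensors[..., 3:][:, :, -1] = 0.0
        aniso = np.ones(labels.shape, bool)
        aniso[:, :, 0] = aniso[:, :, -1] = False
    else:
        for c in range(3):
            tensors[..., c] = sigma_z[None, None, :]
        aniso = np.zeros(labels.shape, bool)

    grid = LabelGrid(labels, h, np.zeros(3))
    return grid, ConductivityField(tensors, aniso, h), sigma_z


def _analytic(case: OracleCase, grid: LabelGrid, sigma_z: np.ndarray):
    """Closed-form φ(z), E_z(z) and I of the continuous series problem.

    The continuous solution uses the exact layer thicknesses with the
    Dirichlet planes at the material end faces (the metal connector layers
    contribute no resistance); it is evaluated at the cell centers.
    """
    h = grid.voxel_size
    zc = grid.axis_centers(2)
    z0 = h  # material start face (one connector layer below)
    if case.anisotropy is not None:
        sig_iso, r = case.anisotropy
        layer_sigmas = [sig_iso * r ** (2.0 / 3.0)]
    else:
        layer_sigmas = [s for _, s in case.layers]
    bounds = z0 + np.concatenate([[0.0],
                                  np.cumsum([t for t, _ in case.layers])])

    def r_of(z):
        z = np.clip(z, bounds[0], bounds[-1])
        acc = np.zeros_like(np.asarray(z, float))
        for s, b0, b1 in zip(layer_sigmas, bounds[:-1], bounds[1:]):
            acc = acc + np.clip(z - b0, 0.0, b1 - b0) * 1e-3 / s
        return acc  # Ω·m²

    r_tot = float(r_of(bounds[-1]))
    area = (grid.labels.shape[0] * grid.labels.shape[1]) * (h * 1e-3) ** 2
    current = case.delta_v / r_tot * area  # A
    phi = case.delta_v / 2 - case.delta_v * r_of(zc) / r_tot
    j_z = case.delta_v / r_tot  # A/m², uniform
    e_z = j_z / sigma_z  # E_z = −dφ/dz > 0 (anode at low z)
    return phi, e_z, current


@dataclass
class OracleReport:
    case: str
    resolution_mm: float
    max_abs_phi_error: float  # V
    max_rel_E_error: float  # on E_z, interior material cells
    rel_current_error: float
    solution: FieldSolution = field(repr=False, default=None)


def run_oracle(case: OracleCase, resolution: float = 1.0,
               tol: float = 1e-12) -> OracleReport:
    """Solve one verification case and compare with its closed form."""
    grid, cond, sigma_z = _build_case(case, resolution)
    dv = case.delta_v
    system = assemble_system(cond, grid,
                             dirichlet={L.CONNECTOR_ANODE: +dv / 2,
                                        L.CONNECTOR_CATHODE: -dv / 2})
    pot = solve_potential(system, tol=tol)
    # the oracle measures conservation itself, so disable the hard gate
    fsol = compute_field(pot, cond, grid, montage_name=case.name,
                         check_tol=np.inf)

    phi_exact, e_exact, i_exact = _analytic(case, grid, sigma_z)
    phi_err = np.nanmax(np.abs(pot.phi - phi_exact[None, None, :]))
    # E on interior material cells (outside the connector layers, away from
    # the one-sided stencils touching them)
    interior = np.zeros(grid.labels.shape, bool)
    interior[:, :, 2:-2] = True
    ez = fsol.E[..., 2]
    rel = np.abs(ez[interior] - np.broadcast_to(
        e_exact[None, None, :], grid.labels.shape)[interior]) / np.abs(
            e_exact).max()
    i_num = abs(electrode_current(pot, L.CONNECTOR_ANODE)) * 1e-3  # A
    return OracleReport(case.name, resolution, float(phi_err),
                        float(rel.max()),
                        float(abs(i_num - i_exact) / i_exact), fsol)


def conservation_check(fsol: FieldSolution) -> float:
    """Max interior net-current residual, relative to the injected current.

    For every free control volume the discrete fluxes must sum to zero;
    returns ``max |Σ flux| / I``.  A converged run passes at ≤ 1e-6.
    """
    sysm = fsol.potential.system
    if fsol.current_mA == 0:
        return 0.0
    phi_cond = fsol.phi.ravel()[sysm.cond_flat]
    r = sysm.A_cond @ phi_cond  # A, net flux out of each control volume
    resid = float(np.abs(r[sysm.free_mask]).max())
    return resid / (abs(fsol.current_mA) * 1e-3)


def convergence_study(case: OracleCase, resolutions: list[float]
                      ) -> dict:
    """Richardson estimate of the observed convergence order.

    Needs ≥ 3 resolutions (coarse → fine).  Non-monotone errors or
    round-off-dominated errors leave the order ``not established`` with a
    warning instead of a number.
    """
    if len(resolutions) < 3:
        raise SpinefieldError("convergence study needs >= 3 resolutions")
    res = sorted(resolutions, reverse=True)
    errors = [run_oracle(case, h).max_abs_phi_error for h in res]
    report = {"case": case.name, "resolutions_mm": res, "phi_errors": errors,
              "order": None, "established": False}
    if max(errors) < 1e-7 * case.delta_v:
        warnings.warn(f"{case.name}: errors at round-off level; order not "
                      f"established", stacklevel=2)
        return report
    if any(e2 >= e1 for e1, e2 in zip(errors, errors[1:])):
        warnings.warn(f"{case.name}: errors not monotonically decreasing; "
                      f"order not established", stacklevel=2)
        return report
    orders = [np.log(e1 / e2) / np.log(h1 / h2)
              for (e1, e2), (h1, h2) in zip(zip(errors, errors[1:]),
                                            zip(res, res[1:]))]
    report["order"] = float(np.mean(orders))
    report["established"] = True
    return report
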
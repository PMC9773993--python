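"""Finite-volume solver for the quasi-static current-flow problem.

At DC the potential obeys ``∇·(σ∇φ) = 0`` with insulating outer boundaries
and isopotential metallic connectors.  The discretization is cell-centered
finite volume on the uniform voxel grid:

* diagonal tensor components couple face neighbors through harmonic-mean
  face conductances (7-point stencil), which is exact for 1-D layered
  profiles with interfaces on cell faces;
* off-diagonal tensor components add the symmetric 4-point cross stencil on
  the edge-diagonal neighbors (27-point stencil); the matrix stays
  symmetric by construction because every pairwise coupling uses the
  arithmetic mean of the two cells' tensor entries;
* row sums are zero over all conductive neighbors, so discrete current is
  conserved exactly in every interior control volume.

Connector voxels carry Dirichlet values (+0.5 V anode, −0.5 V cathode);
the solved two-terminal problem is rescaled by linearity to the target
injected current (the isopotential-connector, prescribed-total-current
formulation).  Conductive islands with no path to an electrode are pruned
with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import cg

from . import labels as L
from .conductivity import ConductivityField
from .errors import AssemblyError, ConservationError, ConvergenceError
from .montage import MontageModel
from .synthetic_anatomy import LabelGrid

__all__ = [
    "LinearSystem",
    "PotentialField",
    "FieldSolution",
    "assemble_system",
    "solve_potential",
    "electrode_current",
    "compute_field",
    "scale_to_current",
    "solve_montage_system",
]

#: Default Dirichlet potentials applied to the connector labels (V).
DEFAULT_DIRICHLET = {L.CONNECTOR_ANODE: +0.5, L.CONNECTOR_CATHODE: -0.5}


@dataclass
class LinearSystem:
    """Assembled discrete operator over the conductive voxels.

    ``A_cond`` is the symmetric operator over all conductive voxels (free +
    Dirichlet) in flat-index order; ``A_ff``/``b`` is the reduced SPD system
    over free voxels.  ``cond_flat`` holds the full-grid flat indices of the
    conductive voxels; ``free_mask``/``dirichlet_values`` are in conductive
    ordering (values NaN on free voxels).
    """

    A_cond: sparse.csr_matrix
    A_ff: sparse.csr_matrix
    b: np.ndarray
    cond_flat: np.ndarray
    free_mask: np.ndarray
    dirichlet_values: np.ndarray
    dirichlet_groups: dict[int, np.ndarray]  # label -> indices (cond order)
    shape: tuple[int, int, int]
    voxel_size: float


@dataclass
class PotentialField:
    """Solved potential with solver metadata."""

    phi: np.ndarray  # full grid (nx, ny, nz), NaN outside the conductive set
    system: LinearSystem
    relative_residual: float
    iterations: int

    @property
    def dirichlet_map(self) -> dict[int, float]:
        sysm = self.system
        return {lab: float(sysm.dirichlet_values[idx[0]])
                for lab, idx in sysm.dirichlet_groups.items() if idx.size}


@dataclass
class FieldSolution:
    """E (V/m) and J (A/m²) vector fields at a prescribed injected current."""

    E: np.ndarray  # (nx, ny, nz, 3)
    J: np.ndarray  # (nx, ny, nz, 3)
    phi: np.ndarray  # V, scaled
    current_mA: float
    montage_name: str
    electrode_currents_mA: dict[str, float]
    potential: PotentialField
    grid: LabelGrid | None = None
    scale_factor: float = 1.0

    @property
    def E_norm(self) -> np.ndarray:
        return np.linalg.norm(self.E, axis=-1)


def _face_conductance(s0: np.ndarray, s1: np.ndarray, h: float) -> np.ndarray:
    """Harmonic-mean face conductance (S) between two cell columns."""
    num = 2.0 * s0 * s1
    den = s0 + s1
    out = np.zeros_like(num)
    ok = den > 0
    out[ok] = num[ok] / den[ok] * h
    return out


def assemble_system(cond: ConductivityField, grid: LabelGrid,
                    montage: MontageModel | None = None,
                    dirichlet: dict[int, float] | None = None) -> LinearSystem:
    """Build the symmetric finite-volume system for a placed montage.

    ``dirichlet`` maps connector labels to applied potentials; by default
    the anode connector is at +0.5 V and the cathode at −0.5 V.  Raises
    :class:`AssemblyError` if an electrode is absent or disconnected from
    the bulk; conductive islands unreachable from any electrode are pruned
    with a warning.
    """
    if dirichlet is None:
        dirichlet = dict(DEFAULT_DIRICHLET)
    lab = grid.labels
    h = grid.voxel_size * 1e-3  # mm -> m, conductances in S
    t = cond.tensors

    conductive = t[..., 0] + t[..., 1] + t[..., 2] > 0
    for dlab in dirichlet:
        if not (conductive & (lab == dlab)).any():
            raise AssemblyError(
                f"Dirichlet label {grid.label_dictionary.get(dlab, dlab)!r} "
                f"has no conductive voxels — electrode missing?")

    # prune islands not connected (6-connectivity) to any electrode
    comp, n_comp = ndimage.label(conductive)
    if n_comp > 1:
        keep = set()
        for dlab in dirichlet:
            keep.update(np.unique(comp[conductive & (lab == dlab)]))
        keep.discard(0)
        island = conductive & ~np.isin(comp, list(keep))
        n_isl = int(island.sum())
        if n_isl:
            warnings.warn(
                f"pruning {n_isl} conductive voxels in "
                f"{n_comp - len(keep)} island(s) with no path to an "
                f"electrode", stacklevel=2)
            conductive = conductive & ~island

    nvox = lab.size
    cond_id = np.full(lab.shape, -1, dtype=np.int64)
    cond_flat = np.flatnonzero(conductive)
    n_cond = cond_flat.size
    cond_id[conductive] = np.arange(n_cond)

    rows, cols, vals = [], [], []

    def add_pairs(ids0, ids1, g):
        ok = (ids0 >= 0) & (ids1 >= 0) & (g != 0)
        rows.append(ids0[ok])
        cols.append(ids1[ok])
        vals.append(-g[ok])

    # 7-point part: face neighbors, harmonic mean of the normal component
    diag_comp = {0: 0, 1: 1, 2: 2}  # axis -> tensor component (xx, yy, zz)
    for ax in range(3):
        sl0 = [slice(None)] * 3
        sl1 = [slice(None)] * 3
        sl0[ax] = slice(None, -1)
        sl1[ax] = slice(1, None)
        sl0, sl1 = tuple(sl0), tuple(sl1)
        s0 = t[..., diag_comp[ax]][sl0]
        s1 = t[..., diag_comp[ax]][sl1]
        g = _face_conductance(s0, s1, h)
        add_pairs(cond_id[sl0].ravel(), cond_id[sl1].ravel(), g.ravel())

    # 27-point part: cross-derivative couplings from off-diagonal entries
    if cond.has_off_diagonal:
        mixed = {(0, 1): 3, (0, 2): 4, (1, 2): 5}  # (axes) -> component
        for (a1, a2), comp_i in mixed.items():
            s = t[..., comp_i]
            for sgn in (+1, -1):
                sl0 = [slice(None)] * 3
                sl1 = [slice(None)] * 3
                sl0[a1] = slice(None, -1)
                sl1[a1] = slice(1, None)
                if sgn > 0:
                    sl0[a2] = slice(None, -1)
                    sl1[a2] = slice(1, None)
                else:
                    sl0[a2] = slice(1, None)
                    sl1[a2] = slice(None, -1)
                sl0, sl1 = tuple(sl0), tuple(sl1)
                savg = 0.5 * (s[sl0] + s[sl1])
                # + diagonal neighbors couple with +σ̄h/2, − diagonals with
                # −σ̄h/2 (the 4-point cross stencil for 2σ_ab ∂²φ/∂a∂b)
                g = sgn * savg * h / 2.0
                add_pairs(cond_id[sl0].ravel(), cond_id[sl1].ravel(),
                          g.ravel())

    r = np.concatenate(rows)
    c = np.concatenate(cols)
    v = np.concatenate(vals)
    A = sparse.coo_matrix((np.concatenate([v, v]),
                           (np.concatenate([r, c]),
                            np.concatenate([c, r]))),
                          shape=(n_cond, n_cond)).tocsr()
    # zero row sums: diagonal = - sum of off-diagonal couplings
    diag = -np.asarray(A.sum(axis=1)).ravel()
    A = A + sparse.diags(diag)
    A = A.tocsr()

    # Dirichlet partition
    dval = np.full(n_cond, np.nan)
    groups: dict[int, np.ndarray] = {}
    lab_cond = lab.ravel()[cond_flat]
    for dlab, value in dirichlet.items():
        idx = np.flatnonzero(lab_cond == dlab)
        groups[dlab] = idx
        dval[idx] = value
    free = np.isnan(dval)
    if not free.any():
        raise AssemblyError("no free unknowns — grid is all electrode")

    f_idx = np.flatnonzero(free)
    d_idx = np.flatnonzero(~free)
    A_f = A[f_idx]
    A_ff = A_f[:, f_idx].tocsr()
    A_fd = A_f[:, d_idx].tocsr()
    b = -A_fd @ dval[d_idx]
    if not np.any(b):
        raise AssemblyError(
            "electrodes are disconnected from the conductive domain "
            "(zero right-hand side)")

    return LinearSystem(A_cond=A, A_ff=A_ff, b=b, cond_flat=cond_flat,
                        free_mask=free, dirichlet_values=dval,
                        dirichlet_groups=groups, shape=lab.shape,
                        voxel_size=grid.voxel_size)


def solve_potential(system: LinearSystem, tol: float = 1e-10,
                    max_iter: int = 20000,
                    x0: np.ndarray | None = None) -> PotentialField:
    """Solve the reduced SPD system by Jacobi-preconditioned CG.

    Deterministic for fixed inputs (fixed ordering, zero initial guess).
    Raises :class:`ConvergenceError` with the achieved residual if the
    iteration does not reach ``tol`` (relative to ``|b|``).
    """
    A, b = system.A_ff, system.b
    d = A.diagonal()
    if np.any(d <= 0):
        raise AssemblyError("non-positive diagonal — singular system "
                            "(isolated conductive island?)")
    M = sparse.diags(1.0 / d)
    n_it = 0

    def count(_):
        nonlocal n_it
        n_it += 1

    x, info = cg(A, b, x0=x0, rtol=tol, atol=0.0, maxiter=max_iter, M=M,
                 callback=count)
    res = float(np.linalg.norm(b - A @ x) / np.linalg.norm(b))
    if info != 0:
        raise ConvergenceError(
            f"CG did not converge in {max_iter} iterations "
            f"(achieved relative residual {res:.2e}, requested {tol:.2e})")

    phi_cond = system.dirichlet_values.copy()
    phi_cond[system.free_mask] = x
    phi = np.full(int(np.prod(system.shape)), np.nan)
    phi[system.cond_flat] = phi_cond
    return PotentialField(phi=phi.reshape(system.shape), system=system,
                          relative_residual=res, iterations=n_it)


def electrode_current(sol: PotentialField, electrode_label: int) -> float:
    """Net current (mA) injected through one connector.

    Sums the discrete face fluxes ``g·(φ_e − φ_neighbor)`` over the closed
    voxel surface of the Dirichlet region — positive for current flowing
    from the connector into the tissue.
    """
    sysm = sol.system
    idx = sysm.dirichlet_groups.get(electrode_label)
    if idx is None or idx.size == 0:
        raise AssemblyError(f"no Dirichlet group for label {electrode_label}")
    phi_cond = sol.phi.ravel()[sysm.cond_flat]
    flux = sysm.A_cond[idx] @ phi_cond  # A (conductances in S, φ in V)
    return float(flux.sum() * 1e3)


def compute_field(sol: PotentialField, cond: ConductivityField,
                  grid: LabelGrid, montage_name: str = "",
                  check_tol: float = 1e-3) -> FieldSolution:
    """Derive E = −∇φ and J = σE from a solved potential.

    Gradients are central differences where both neighbors share the
    voxel's tissue label, one-sided into the same tissue at label
    interfaces, and fall back to whatever neighbors are conductive at the
    domain boundary.  The anode/cathode currents must agree within
    ``check_tol`` (relative); a mismatch beyond 10× that signals a
    discretization bug and raises :class:`ConservationError`.
    """
    h_m = grid.voxel_size * 1e-3
    phi = sol.phi
    lab = grid.labels
    condmask = ~np.isnan(phi)

    E = np.zeros(phi.shape + (3,))
    for ax in range(3):
        fwd = np.full(phi.shape, np.nan)
        bwd = np.full(phi.shape, np.nan)
        sl0 = [slice(None)] * 3
        sl1 = [slice(None)] * 3
        sl0[ax] = slice(None, -1)
        sl1[ax] = slice(1, None)
        sl0, sl1 = tuple(sl0), tuple(sl1)
        dphi = (phi[sl1] - phi[sl0]) / h_m
        same = lab[sl1] == lab[sl0]
        fwd[sl0] = dphi
        bwd[sl1] = dphi
        same_f = np.zeros(phi.shape, bool)
        same_b = np.zeros(phi.shape, bool)
        same_f[sl0] = same
        same_b[sl1] = same
        ok_f = ~np.isnan(fwd)
        ok_b = ~np.isnan(bwd)
        fwd = np.where(ok_f, fwd, 0.0)
        bwd = np.where(ok_b, bwd, 0.0)
        central = 0.5 * (fwd + bwd)
        # selection priority: central within one tissue, one-sided into the
        # same tissue at interfaces, then any conductive neighbor
        grad = np.zeros(phi.shape)
        sel_central = same_f & ok_f & same_b & ok_b
        sel_fwd = same_f & ok_f & ~sel_central
        sel_bwd = same_b & ok_b & ~sel_central & ~sel_fwd
        rest = ~(sel_central | sel_fwd | sel_bwd)
        grad[sel_central] = central[sel_central]
        grad[sel_fwd] = fwd[sel_fwd]
        grad[sel_bwd] = bwd[sel_bwd]
        grad[rest & ok_f & ok_b] = central[rest & ok_f & ok_b]
        grad[rest & ok_f & ~ok_b] = fwd[rest & ok_f & ~ok_b]
        grad[rest & ~ok_f & ok_b] = bwd[rest & ~ok_f & ok_b]
        E[..., ax] = np.where(condmask, -grad, 0.0)

    t = cond.tensors
    J = np.empty_like(E)
    J[..., 0] = t[..., 0] * E[..., 0] + t[..., 3] * E[..., 1] + t[..., 4] * E[..., 2]
    J[..., 1] = t[..., 3] * E[..., 0] + t[..., 1] * E[..., 1] + t[..., 5] * E[..., 2]
    J[..., 2] = t[..., 4] * E[..., 0] + t[..., 5] * E[..., 1] + t[..., 2] * E[..., 2]

    currents = {}
    for dlab in sol.system.dirichlet_groups:
        name = grid.label_dictionary.get(dlab, str(dlab))
        currents[name] = electrode_current(sol, dlab)
    vals = list(currents.values())
    if len(vals) == 2:
        mismatch = abs(vals[0] + vals[1]) / max(abs(vals[0]), abs(vals[1]))
        if mismatch > 10 * check_tol:
            raise ConservationError(
                f"anode/cathode currents disagree by {mismatch:.2e} "
                f"relative ({currents}) — discretization bug")
    injected = max(abs(v) for v in vals)
    return FieldSolution(E=E, J=J, phi=phi.copy(), current_mA=injected,
                         montage_name=montage_name,
                         electrode_currents_mA=currents, potential=sol,
                         grid=grid)


def scale_to_current(fsol: FieldSolution, target_mA: float) -> FieldSolution:
    """Rescale a solution to a target injected current by linearity."""
    if fsol.current_mA == 0:
        raise ConservationError("computed electrode current is zero — "
                                "degenerate montage")
    f = target_mA / fsol.current_mA
    return FieldSolution(
        E=fsol.E * f, J=fsol.J * f, phi=fsol.phi * f,
        current_mA=target_mA, montage_name=fsol.montage_name,
        electrode_currents_mA={k: v * f
                               for k, v in fsol.electrode_currents_mA.items()},
        potential=fsol.potential, grid=fsol.grid,
        scale_factor=fsol.scale_factor * f)


def solve_montage_system(cond: ConductivityField, grid: LabelGrid,
                         montage_name: str = "", current_mA: float = 4.0,
                         tol: float = 1e-10,
                         dirichlet: dict[int, float] | None = None,
                         max_iter: int = 20000) -> FieldSolution:
    """Assemble, solve and rescale to the target current in one call."""
    system = assemble_system(cond, grid, dirichlet=dirichlet)
    pot = solve_potential(system, tol=tol, max_iter=max_iter)
    fsol = compute_field(pot, cond, grid, montage_name=montage_name)
    return scale_to_current(fsol, current_mA)
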
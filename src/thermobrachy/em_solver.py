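"""Electroquasistatic voxel field solver.

At 27 MHz the heating field of the interstitial electrodes is governed by
the electroquasistatic approximation: the complex potential V_i of each
electrode i satisfies

    div( (sigma + j 2 pi f eps) grad V_i ) = 0

with Dirichlet conditions (driven electrode at 1 V, all other electrodes
and the outer domain boundary grounded).  The per-electrode fields
E_i = -grad V_i form a linear basis: for amplitudes v the total field is
E_tot = sum_i v_i E_i and the dissipated power density is

    P = sigma |E_tot|^2 / 2

which contains the cross terms between electrodes (the quadratic form
v^H P v).  The discretization is flux-conservative finite differences with
harmonic-mean face admittances; the complex-symmetric system is solved with
a Jacobi-preconditioned conjugate-orthogonal CG (COCG), the standard Krylov
iteration for complex-symmetric matrices, which scipy does not provide.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .tissue_model import VoxelGrid, VoxelTissueModel, property_grids, rasterize_electrodes

__all__ = [
    "SolverError",
    "assemble_diffusion_system",
    "solve_dirichlet",
    "ElectroquasistaticProblem",
    "solve_potential",
    "efield",
    "superpose_efield",
    "power_density",
    "power_from_total_field",
    "unit_power_per_electrode",
]

EPS0 = 8.8541878128e-12  # vacuum permittivity, F/m


class SolverError(RuntimeError):
    """Iterative solve failed to reach the requested residual."""


def _face_coefficients(coeff: np.ndarray, grid: VoxelGrid, axis: int) -> np.ndarray:
    """Harmonic-mean face transmissibility g = a_face * A / d along ``axis``.

    ``coeff`` is the per-voxel material coefficient (admittance or thermal
    conductivity).  Geometry factors use spacing in meters.  Faces adjacent
    to a zero-coefficient voxel get zero transmissibility (insulating).
    """
    sp_m = np.asarray(grid.spacing) * 1e-3
    area = np.prod(np.delete(sp_m, axis))
    d = sp_m[axis]
    lo = np.take(coeff, range(coeff.shape[axis] - 1), axis=axis)
    hi = np.take(coeff, range(1, coeff.shape[axis]), axis=axis)
    s = lo + hi
    with np.errstate(divide="ignore", invalid="ignore"):
        hm = np.where(np.abs(s) > 0, 2.0 * lo * hi / np.where(np.abs(s) > 0, s, 1), 0.0)
    return hm * (area / d)


def assemble_diffusion_system(
    coeff: np.ndarray,
    grid: VoxelGrid,
    dirichlet_mask: np.ndarray,
    excluded_mask: np.ndarray | None = None,
    sink: np.ndarray | None = None,
):
    """Assemble ``A x = b`` for div(coeff grad u) - sink*u = -source.

    Voxels in ``dirichlet_mask`` are eliminated (their values enter the
    right-hand side through :func:`solve_dirichlet`); voxels in
    ``excluded_mask`` are removed from the system with insulating faces.
    ``sink`` is a per-voxel zeroth-order coefficient in W-per-volume units
    already multiplied by the voxel volume (or any consistent scaling).

    Returns ``(A, unknown_index, boundary_ops)`` where ``unknown_index``
    maps flat voxel index -> row (or -1) and ``boundary_ops`` is a list of
    (rows, dirichlet_flat_cols, coeffs) triplets used to build the RHS from
    Dirichlet values.
    """
    shape = grid.shape
    n = grid.n_voxels
    excluded = np.zeros(shape, bool) if excluded_mask is None else excluded_mask
    free = ~(dirichlet_mask | excluded)
    unknown_index = -np.ones(n, dtype=np.int64)
    free_flat = np.flatnonzero(free.ravel())
    unknown_index[free_flat] = np.arange(free_flat.size)

    flat = np.arange(n).reshape(shape)
    diag = np.zeros(free_flat.size, dtype=coeff.dtype)
    rows, cols, vals = [], [], []
    boundary_ops = []
    for axis in range(3):
        g = _face_coefficients(coeff, grid, axis)
        # zero out faces touching excluded voxels
        lo_ex = np.take(excluded, range(shape[axis] - 1), axis=axis)
        hi_ex = np.take(excluded, range(1, shape[axis]), axis=axis)
        g = np.where(lo_ex | hi_ex, 0.0, g)
        p = np.take(flat, range(shape[axis] - 1), axis=axis).ravel()
        q = np.take(flat, range(1, shape[axis]), axis=axis).ravel()
        gf = g.ravel()
        ip, iq = unknown_index[p], unknown_index[q]
        both = (ip >= 0) & (iq >= 0)
        np.add.at(diag, ip[ip >= 0], gf[ip >= 0])
        np.add.at(diag, iq[iq >= 0], gf[iq >= 0])
        rows.append(ip[both]); cols.append(iq[both]); vals.append(-gf[both])
        rows.append(iq[both]); cols.append(ip[both]); vals.append(-gf[both])
        # faces between an unknown and a Dirichlet voxel -> RHS contribution
        dir_flat = dirichlet_mask.ravel()
        pb = (ip >= 0) & dir_flat[q]
        qb = (iq >= 0) & dir_flat[p]
        if pb.any():
            boundary_ops.append((ip[pb], q[pb], gf[pb]))
        if qb.any():
            boundary_ops.append((iq[qb], p[qb], gf[qb]))

    if sink is not None:
        diag = diag + sink.ravel()[free_flat]
    A = sp.csr_matrix(
        (np.concatenate(vals + [diag]),
         (np.concatenate(rows + [np.arange(free_flat.size)]),
          np.concatenate(cols + [np.arange(free_flat.size)]))),
        shape=(free_flat.size, free_flat.size),
    )
    return A, unknown_index, boundary_ops


def _cocg(A, b, diag, rtol, maxiter):
    """Jacobi-preconditioned conjugate-orthogonal CG for complex-symmetric A."""
    x = np.zeros_like(b)
    r = b.copy()
    nb = np.linalg.norm(b)
    if nb == 0:
        return x, 0.0
    z = r / diag
    p = z.copy()
    rz = np.sum(r * z)
    for _ in range(maxiter):
        Ap = A @ p
        denom = np.sum(p * Ap)
        alpha = rz / denom
        x += alpha * p
        r -= alpha * Ap
        res = np.linalg.norm(r) / nb
        if res < rtol:
            return x, res
        z = r / diag
        rz_new = np.sum(r * z)
        p = z + (rz_new / rz) * p
        rz = rz_new
    return x, float(np.linalg.norm(r) / nb)


def solve_dirichlet(
    coeff: np.ndarray,
    grid: VoxelGrid,
    dirichlet_mask: np.ndarray,
    dirichlet_values: np.ndarray,
    rtol: float = 1e-8,
    maxiter: int = 20000,
) -> np.ndarray:
    """Solve div(coeff grad u) = 0 with prescribed values on the mask.

    Generic single-shot entry point (used directly by the closed-form
    oracle tests); electrode bases go through
    :class:`ElectroquasistaticProblem`, which factors the shared system out
    of the per-electrode loop.
    """
    if not dirichlet_mask.any():
        raise ValueError("no Dirichlet voxels: the system is singular")
    A, unknown_index, bops = assemble_diffusion_system(coeff, grid, dirichlet_mask)
    b = np.zeros(A.shape[0], dtype=coeff.dtype)
    dv = dirichlet_values.ravel()
    for rows_, cols_, g in bops:
        np.add.at(b, rows_, g * dv[cols_])
    x, res = _cocg(A, b.astype(complex if np.iscomplexobj(coeff) else float),
                   A.diagonal(), rtol, maxiter)
    if res >= rtol:
        raise SolverError(f"COCG did not converge: relative residual {res:.2e}")
    out = np.zeros(grid.n_voxels, dtype=x.dtype)
    out[unknown_index >= 0] = x[unknown_index[unknown_index >= 0]]
    out[dirichlet_mask.ravel()] = dv[dirichlet_mask.ravel()]
    return out.reshape(grid.shape)


def _boundary_mask(shape: tuple[int, int, int]) -> np.ndarray:
    m = np.zeros(shape, bool)
    m[0, :, :] = m[-1, :, :] = True
    m[:, 0, :] = m[:, -1, :] = True
    m[:, :, 0] = m[:, :, -1] = True
    return m


@dataclass
class ElectroquasistaticProblem:
    """Shared assembly for all per-electrode potential solves.

    The Dirichlet set (all electrode voxels + outer boundary) is identical
    for every electrode; only the right-hand side changes, so the system is
    assembled once and reused for the whole basis.
    """

    model: VoxelTissueModel
    rtol: float = 1e-8
    maxiter: int = 20000

    def __post_init__(self) -> None:
        model = self.model
        props = property_grids(model)
        omega_ang = 2 * np.pi * model.frequency
        self.admittance = props["sigma"] + 1j * omega_ang * EPS0 * props["eps_r"]
        self.sigma = props["sigma"]
        self.electrode_voxels = rasterize_electrodes(model)
        dir_mask = _boundary_mask(model.grid.shape).ravel()
        for idx in self.electrode_voxels:
            dir_mask[idx] = True
        self.dirichlet_mask = dir_mask.reshape(model.grid.shape)
        self._A, self._unknown_index, self._bops = assemble_diffusion_system(
            self.admittance, model.grid, self.dirichlet_mask
        )
        self._diag = self._A.diagonal()

    def solve(self, electrode_index: int, drive_volts: complex = 1.0) -> np.ndarray:
        """Complex potential of one electrode driven against everything else."""
        grid = self.model.grid
        dv = np.zeros(grid.n_voxels, dtype=complex)
        dv[self.electrode_voxels[electrode_index]] = drive_volts
        b = np.zeros(self._A.shape[0], dtype=complex)
        for rows_, cols_, g in self._bops:
            np.add.at(b, rows_, g * dv[cols_])
        x, res = _cocg(self._A, b, self._diag, self.rtol, self.maxiter)
        if res >= self.rtol:
            raise SolverError(
                f"electrode {electrode_index}: COCG residual {res:.2e} > rtol {self.rtol:.0e}"
            )
        out = np.zeros(grid.n_voxels, dtype=complex)
        out[self._unknown_index >= 0] = x[self._unknown_index[self._unknown_index >= 0]]
        out[self.electrode_voxels[electrode_index]] = drive_volts
        return out.reshape(grid.shape)


def solve_potential(model: VoxelTissueModel, electrode_index: int,
                    rtol: float = 1e-8, maxiter: int = 20000) -> np.ndarray:
    """One-off per-electrode potential solve (see ElectroquasistaticProblem)."""
    return ElectroquasistaticProblem(model, rtol=rtol, maxiter=maxiter).solve(electrode_index)


def efield(V: np.ndarray, grid: VoxelGrid) -> np.ndarray:
    """E = -grad V in V/m; central differences, one-sided at the boundary.

    Returns an array of shape (3, *grid.shape).
    """
    spacing_m = [s * 1e-3 for s in grid.spacing]
    grads = np.gradient(V, *spacing_m, edge_order=1)
    return -np.stack(grads, axis=0)


def superpose_efield(basis: list[np.ndarray], v: np.ndarray) -> np.ndarray:
    """Total field E_tot = sum_i v_i E_i (linear superposition)."""
    if len(basis) != len(v):
        raise ValueError(f"{len(basis)} basis fields but {len(v)} amplitudes")
    out = np.zeros_like(basis[0], dtype=complex)
    for Ei, vi in zip(basis, v):
        out += vi * Ei
    return out


def power_from_total_field(E_tot: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """P = sigma |E|^2 / 2 (W/m^3) from a total complex field."""
    return 0.5 * sigma * np.sum(np.abs(E_tot) ** 2, axis=0)


def power_density(basis: list[np.ndarray], v: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Coherent power density of the superposed field, cross terms included."""
    return power_from_total_field(superpose_efield(basis, v), sigma)


def unit_power_per_electrode(basis: list[np.ndarray], sigma: np.ndarray) -> list[np.ndarray]:
    """Diagonal (per-electrode, unit-amplitude) power densities P_i."""
    return [power_from_total_field(Ei, sigma) for Ei in basis]
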
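"""Steady-state Pennes bioheat solver and per-electrode temperature bases.

Tissue temperature under interstitial RF heating follows the Pennes
bioheat equation; during a ~1 h exposure the distribution reaches its
steady state, so the solver drops the transient term and solves for the
temperature elevation DT = T - Tb above the 37 degC baseline:

    div(k grad DT) - rho_b c_b rho omega DT + P = 0,   DT = 0 on the boundary.

Solving for the elevation makes the metabolic heat term cancel (the
baseline is the pre-heating equilibrium).  The perfusion sink — very
strong in prostate tissue — confines the elevation to a few millimeters
around each electrode, which is what makes the per-electrode superposition

    T = sum_i v_i^2 DT_i + Tb

accurate: the amplitude-cross terms of the power density are neglected,
and the package validates that against a fully coupled reference solve
(gamma-index analysis in plan_metrics).

Internal air voxels are excluded from the conduction stencil (insulating
faces), so no heat is conducted through the rectal lumen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse.linalg as spla

from .em_solver import (
    SolverError,
    assemble_diffusion_system,
    power_from_total_field,
    superpose_efield,
    _boundary_mask,
)
from .tissue_model import Tissue, VoxelTissueModel, property_grids

__all__ = [
    "solve_steady_conduction",
    "BioheatProblem",
    "solve_bioheat",
    "precompute_delta_t",
    "superpose_temperature",
    "reference_recalculation",
]


def solve_steady_conduction(
    k: np.ndarray,
    grid,
    dirichlet_mask: np.ndarray,
    P: np.ndarray,
    sink_w_m3_k: np.ndarray | None = None,
    rtol: float = 1e-8,
    maxiter: int = 20000,
) -> np.ndarray:
    """Elevation solve on an arbitrary Dirichlet set (DT = 0 on the mask).

    Low-level entry point: ``div(k grad DT) - sink*DT + P = 0`` with the
    perfusion sink given directly in W/m^3/K.  Used for non-box domains
    (e.g. spherical shells); the planning chain goes through
    :class:`BioheatProblem`.
    """
    vox_m3 = grid.voxel_volume_mm3 * 1e-9
    sink = None if sink_w_m3_k is None else sink_w_m3_k * vox_m3
    A, unknown_index, _ = assemble_diffusion_system(
        k, grid, dirichlet_mask, sink=sink)
    free = unknown_index >= 0
    b = np.zeros(A.shape[0])
    b[unknown_index[free]] = (P.ravel() * vox_m3)[free]
    precond = spla.LinearOperator(A.shape, lambda x: x / A.diagonal())
    x, info = spla.cg(A, b, rtol=rtol, atol=0.0, maxiter=maxiter, M=precond)
    if info != 0:
        raise SolverError(f"steady conduction CG did not converge (info={info})")
    out = np.zeros(grid.n_voxels)
    out[free] = x[unknown_index[free]]
    return out.reshape(grid.shape)


@dataclass
class BioheatProblem:
    """Shared assembly of the steady-state elevation system for one model.

    The conduction/perfusion operator does not depend on the power input,
    so it is assembled once and reused for every per-electrode solve and
    for the coupled reference recalculation.
    """

    model: VoxelTissueModel
    rtol: float = 1e-8
    maxiter: int = 20000

    def __post_init__(self) -> None:
        model = self.model
        props = property_grids(model)
        grid = model.grid
        blood = model.blood
        self.air_mask = model.mask(Tissue.AIR)
        if any(getattr(p, f) < 0 for p in model.properties.values()
               for f in ("thermal_conductivity", "perfusion_ml_kg_min")):
            raise ValueError("negative thermal property")
        vox_m3 = grid.voxel_volume_mm3 * 1e-9
        # perfusion sink rho_b c_b rho omega, W/m^3/K, times voxel volume
        sink = (blood.mass_density * blood.specific_heat
                * props["rho"] * props["omega"]) * vox_m3
        dirichlet = _boundary_mask(grid.shape) & ~self.air_mask
        self._A, self._unknown_index, _ = assemble_diffusion_system(
            props["k"], grid, dirichlet, excluded_mask=self.air_mask, sink=sink
        )
        self._vox_m3 = vox_m3
        self._precond = spla.LinearOperator(
            self._A.shape, lambda x: x / self._A.diagonal()
        )

    def solve_elevation(self, P: np.ndarray) -> np.ndarray:
        """Elevation field DT (K) for a power density P (W/m^3), P >= 0."""
        src = P.ravel() * self._vox_m3
        free = self._unknown_index >= 0
        b = np.zeros(self._A.shape[0])
        b[self._unknown_index[free]] = src[free]
        x, info = spla.cg(self._A, b, rtol=self.rtol, atol=0.0,
                          maxiter=self.maxiter, M=self._precond)
        if info != 0:
            res = np.linalg.norm(self._A @ x - b) / max(np.linalg.norm(b), 1e-300)
            raise SolverError(f"bioheat CG did not converge (info={info}, residual {res:.2e})")
        out = np.zeros(self.model.grid.n_voxels)
        out[self._unknown_index >= 0] = x[
            self._unknown_index[self._unknown_index >= 0]
        ]
        return out.reshape(self.model.grid.shape)

    def solve(self, P: np.ndarray) -> np.ndarray:
        """Absolute temperature T = Tb + DT (degC)."""
        return self.model.blood.temperature + self.solve_elevation(P)


def solve_bioheat(model: VoxelTissueModel, P: np.ndarray,
                  rtol: float = 1e-8, maxiter: int = 20000) -> np.ndarray:
    """One-off steady-state solve: returns T = Tb + DT for power density P."""
    return BioheatProblem(model, rtol=rtol, maxiter=maxiter).solve(P)


def precompute_delta_t(model: VoxelTissueModel,
                       unit_powers: list[np.ndarray],
                       problem: BioheatProblem | None = None) -> np.ndarray:
    """Unit-amplitude elevation basis DT_i, stacked as (n_electrodes, *shape).

    One elevation solve per electrode against the shared operator; the
    stack is what every optimizer evaluation superposes, so it is meant to
    be persisted (see workbench_io) rather than recomputed.
    """
    prob = problem or BioheatProblem(model)
    basis = np.empty((len(unit_powers),) + tuple(model.grid.shape), dtype=np.float32)
    for i, P in enumerate(unit_powers):
        try:
            basis[i] = prob.solve_elevation(P)
        except SolverError as err:
            raise SolverError(f"electrode {i}: {err}") from err
    return basis


def superpose_temperature(basis: np.ndarray, v: np.ndarray,
                          Tb: float = 37.0) -> np.ndarray:
    """T = sum_i |v_i|^2 DT_i + Tb; a weighted sum, no PDE solve.

    Phase-blind by construction: only the power share |v_i|^2 of each
    electrode enters, which is the off-diagonal-free approximation the
    coupled reference solve validates.
    """
    v = np.abs(np.asarray(v)) ** 2
    if basis.shape[0] != v.size:
        raise ValueError(f"{basis.shape[0]} basis fields but {v.size} amplitudes")
    return np.tensordot(v, basis.astype(np.float64, copy=False), axes=(0, 0)) + Tb


def reference_recalculation(model: VoxelTissueModel,
                            efield_basis: list[np.ndarray],
                            v: np.ndarray,
                            sigma: np.ndarray | None = None,
                            problem: BioheatProblem | None = None) -> np.ndarray:
    """Coupled reference: total power with cross terms, then one solve.

    This is the validation standard for the superposition method: the total
    field of the given amplitudes (including interference between
    electrodes) drives a single bioheat solve.
    """
    if sigma is None:
        sigma = property_grids(model)["sigma"]
    P = power_from_total_field(superpose_efield(efield_basis, v), sigma)
    prob = problem or BioheatProblem(model)
    return prob.solve(P)
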
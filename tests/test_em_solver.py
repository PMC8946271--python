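"""Electroquasistatic solver against closed-form oracles and identities."""

import numpy as np
import pytest

from thermobrachy.em_solver import (
    efield,
    power_density,
    power_from_total_field,
    solve_dirichlet,
    superpose_efield,
    unit_power_per_electrode,
)
from thermobrachy.tissue_model import VoxelGrid


def _capacitor(n, spacing, a, b, coeff_value=0.5 + 0j):
    """Concentric spherical shells: inner radius a at 1 V, outer b at 0 V."""
    grid = VoxelGrid((n, n, n), (spacing,) * 3, (-(n - 1) / 2 * spacing,) * 3)
    x, y, z = np.meshgrid(*grid.coordinate_axes(), indexing="ij")
    r = np.sqrt(x ** 2 + y ** 2 + z ** 2)
    dmask = (r <= a) | (r >= b)
    dv = np.where(r <= a, 1.0, 0.0)
    V = solve_dirichlet(np.full(grid.shape, coeff_value), grid, dmask, dv)
    return grid, r, V


def test_spherical_capacitor_potential_and_field():
    """V(r) and |E|(r) match the analytic shell solution away from the
    staircased conductor surfaces (1 mm grid, 12/40 mm shells)."""
    a, b = 12.0, 40.0
    grid, r, V = _capacitor(87, 1.0, a, b)
    with np.errstate(divide="ignore"):
        ana = (1 / np.maximum(r, 1e-9) - 1 / b) / (1 / a - 1 / b)
    sel = (r > 1.5 * a) & (r < 0.8 * b)
    assert np.max(np.abs(V.real - ana)[sel] / ana[sel]) < 0.05
    E = efield(V, grid)
    emag = np.sqrt(np.sum(np.abs(E) ** 2, axis=0))
    with np.errstate(divide="ignore"):
        eana = (1 / r ** 2) / (1 / a - 1 / b) * 1e3  # V/m
    assert np.max(np.abs(emag - eana)[sel] / eana[sel]) < 0.07


def test_capacitor_error_decreases_under_refinement():
    a, b = 12.0, 40.0
    errs = []
    for n, h in ((43, 2.0), (87, 1.0)):
        grid, r, V = _capacitor(n, h, a, b)
        with np.errstate(divide="ignore"):
            ana = (1 / np.maximum(r, 1e-9) - 1 / b) / (1 / a - 1 / b)
        sel = (r > 1.5 * a) & (r < 0.8 * b)
        errs.append(np.max(np.abs(V.real - ana)[sel] / ana[sel]))
    assert errs[1] < errs[0]


def test_real_conductivity_gives_real_solution():
    """With zero permittivity contribution the solve reduces to Laplace."""
    _, _, V = _capacitor(31, 2.0, 8.0, 26.0, coeff_value=0.7 + 0j)
    assert np.max(np.abs(V.imag)) < 1e-7


def test_dirichlet_linearity():
    grid = VoxelGrid((21, 21, 21), (2.0,) * 3, (-20.0,) * 3)
    x, y, z = np.meshgrid(*grid.coordinate_axes(), indexing="ij")
    r = np.sqrt(x ** 2 + y ** 2 + z ** 2)
    dmask = (r <= 6) | (r >= 18)
    coeff = np.full(grid.shape, 0.4 + 0.05j)
    V1 = solve_dirichlet(coeff, grid, dmask, np.where(r <= 6, 1.0, 0.0))
    V2 = solve_dirichlet(coeff, grid, dmask, np.where(r <= 6, 2.0, 0.0))
    assert np.allclose(V2, 2 * V1, atol=1e-6)


def test_efield_of_constant_and_linear_potential():
    grid = VoxelGrid((9, 9, 9), (1.0,) * 3)
    assert np.all(efield(np.ones(grid.shape), grid) == 0)
    x = np.meshgrid(*grid.coordinate_axes(), indexing="ij")[0]
    E = efield(0.25 * x, grid)  # slope 0.25 V/mm
    assert np.allclose(E[0], -250.0)  # -1000 * slope, V/m
    assert np.allclose(E[1], 0.0) and np.allclose(E[2], 0.0)


def test_power_density_point_value():
    # sigma = 0.838 S/m (prostate), |E| = 100 V/m -> P = 4190 W/m^3
    E = np.zeros((3, 1, 1, 1), dtype=complex)
    E[0] = 100.0
    P = power_from_total_field(E, np.full((1, 1, 1), 0.838))
    assert P[0, 0, 0] == pytest.approx(4190.0)


def test_power_quadratic_scaling_and_cross_cancellation(rng):
    shape = (6, 5, 4)
    E = (rng.normal(size=(3,) + shape) + 1j * rng.normal(size=(3,) + shape))
    sigma = rng.uniform(0.1, 1.0, shape)
    P1 = power_density([E], np.array([1.0]), sigma)
    P2 = power_density([E], np.array([2.0]), sigma)
    assert np.allclose(P2, 4 * P1)
    # identical fields driven in opposition annihilate
    P0 = power_density([E, E.copy()], np.array([1.0, -1.0]), sigma)
    assert np.allclose(P0, 0.0)
    assert np.all(P1 >= 0)


def test_unit_power_diagonal_identity(rng):
    """For non-overlapping (orthogonal) fields the diagonal sum equals the
    coherent power of the superposed field."""
    shape = (8, 8, 8)
    sigma = rng.uniform(0.2, 0.9, shape)
    E1 = np.zeros((3,) + shape, complex)
    E2 = np.zeros((3,) + shape, complex)
    E1[:, :4] = rng.normal(size=(3, 4, 8, 8)) + 1j * rng.normal(size=(3, 4, 8, 8))
    E2[:, 4:] = rng.normal(size=(3, 4, 8, 8)) + 1j * rng.normal(size=(3, 4, 8, 8))
    v = np.array([1.3, 0.7])
    diag = unit_power_per_electrode([E1, E2], sigma)
    total = power_density([E1, E2], v, sigma)
    assert np.allclose(v[0] ** 2 * diag[0] + v[1] ** 2 * diag[1], total)
    zero = unit_power_per_electrode([np.zeros_like(E1)], sigma)[0]
    assert np.all(zero == 0)


def test_superpose_length_mismatch():
    E = np.zeros((3, 2, 2, 2), complex)
    with pytest.raises(ValueError, match="amplitudes"):
        superpose_efield([E, E], np.array([1.0]))


def test_no_dirichlet_voxels_rejected():
    grid = VoxelGrid((5, 5, 5), (1.0,) * 3)
    with pytest.raises(ValueError, match="singular"):
        solve_dirichlet(np.ones(grid.shape, complex), grid,
                        np.zeros(grid.shape, bool), np.zeros(grid.shape))
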
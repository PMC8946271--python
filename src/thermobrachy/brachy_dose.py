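"""HDR brachytherapy dose on the voxel grid.

The afterloader steps a high-activity ^192Ir source through the implanted
applicators; the absorbed dose is the time-weighted sum of per-dwell
kernels.  The kernel here is the TG-43 point-source form

    D(r) = t * K * (r0/r)^2 * g(r) * phi_an

with reference distance r0 = 10 mm, radial dose function g (defaults to 1,
an ^192Ir-like polynomial preset is available) and a constant anisotropy
factor.  A dwell-weight heuristic (nonnegative least squares on
prostate-surface sampling points, followed by a coverage rescale) produces
protocol-conforming surrogate plans on the synthetic phantom; uniform dose
scaling supports the dose-reduction study.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.optimize import nnls

from .tissue_model import Tissue, VoxelGrid, VoxelTissueModel

__all__ = [
    "Dwell",
    "SourceModel",
    "IR192_RADIAL_POLY",
    "tg43_dose",
    "heuristic_dwell_weights",
    "scale_dose",
    "PRESCRIPTION_DOSE",
]

#: Prescription dose per fraction (Gy) of the ultrahypofractionated
#: monotherapy protocol the planning criteria are expressed against.
PRESCRIPTION_DOSE = 13.5

#: Optional generic ^192Ir-like radial dose function g(r), polynomial in r
#: (mm); mild build-up/attenuation shape normalized to g(r0 = 10 mm) = 1.
IR192_RADIAL_POLY = (1.0042, 1.810e-4, -1.453e-5)


@dataclass(frozen=True)
class Dwell:
    """Source stopping point: world position (mm) and time-weight."""

    position: tuple[float, float, float]
    weight: float  # proportional to dwell time; kernel units per unit weight

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("dwell weight must be >= 0")


@dataclass(frozen=True)
class SourceModel:
    """Point-source TG-43 kernel parameters.

    ``strength`` is the dose (Gy) at the reference distance per unit dwell
    weight (the product of air-kerma strength, dose-rate constant and dwell
    time absorbed into one scale).
    """

    strength: float = 1.0
    reference_distance: float = 10.0  # r0, mm
    radial_poly: tuple[float, ...] = (1.0,)  # g(r) polynomial coefficients in r (mm)
    anisotropy: float = 1.0

    def g(self, r_mm: np.ndarray) -> np.ndarray:
        out = np.zeros_like(r_mm)
        for k, c in enumerate(self.radial_poly):
            out += c * r_mm ** k
        # enforce g(r0) = 1 regardless of coefficient rounding
        g0 = sum(c * self.reference_distance ** k for k, c in enumerate(self.radial_poly))
        return out / g0


def _dose_at_points(source: SourceModel, dwells: list[Dwell],
                    points: np.ndarray, r_min: float) -> np.ndarray:
    """Summed kernel at arbitrary points (n, 3); r capped below at r_min."""
    dose = np.zeros(len(points))
    r0 = source.reference_distance
    for dw in dwells:
        r = np.linalg.norm(points - np.asarray(dw.position), axis=1)
        r = np.maximum(r, r_min)
        dose += dw.weight * source.strength * (r0 / r) ** 2 * source.g(r) * source.anisotropy
    return dose


def tg43_dose(source: SourceModel, dwells: list[Dwell], grid: VoxelGrid) -> np.ndarray:
    """Dose grid (Gy) from a dwell list; additive over dwells.

    Near-field singularity is capped at half the voxel diagonal.  Dwells
    outside the grid still contribute (a warning-level situation handled by
    the caller's geometry checks).
    """
    if not dwells:
        raise ValueError("dwell list is empty")
    axes = grid.coordinate_axes()
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    r_min = 0.5 * float(np.linalg.norm(grid.spacing))
    return _dose_at_points(source, dwells, pts, r_min).reshape(grid.shape)


def candidate_dwells(model: VoxelTissueModel, step_mm: float = 2.5,
                     margin_mm: float = 3.0) -> list[Dwell]:
    """Unit-weight dwell candidates along each track inside the target.

    Positions are spaced ``step_mm`` along the applicator, restricted to
    the z-extent of the prostate plus ``margin_mm``.
    """
    prost = model.mask(Tissue.PROSTATE)
    if not prost.any():
        raise ValueError("model has no prostate voxels")
    zc = model.grid.coordinate_axes()[2]
    z_idx = np.flatnonzero(prost.any(axis=(0, 1)))
    z_lo, z_hi = zc[z_idx[0]] - margin_mm, zc[z_idx[-1]] + margin_mm
    out = []
    for app in model.applicators:
        arcs = np.arange(0.0, app.length + 1e-9, step_mm)
        for a in arcs:
            p = app.point_at(a)
            if z_lo <= p[2] <= z_hi:
                out.append(Dwell(tuple(float(c) for c in p), 1.0))
    return out


def _surface_points(model: VoxelTissueModel, max_points: int = 600) -> np.ndarray:
    """World coordinates of prostate surface voxels (subsampled evenly)."""
    prost = model.mask(Tissue.PROSTATE) | model.mask(Tissue.URETHRA)
    surf = prost & ~ndimage.binary_erosion(prost)
    idx = np.argwhere(surf)
    if len(idx) > max_points:
        idx = idx[:: len(idx) // max_points + 1]
    return model.grid.index_to_world(idx)


def heuristic_dwell_weights(
    model: VoxelTissueModel,
    source: SourceModel | None = None,
    prescription: float = PRESCRIPTION_DOSE,
    coverage_target: float = 96.5,
    step_mm: float = 2.5,
) -> tuple[list[Dwell], dict[str, float]]:
    """Surrogate BT-only plan: NNLS surface fit + coverage rescale.

    Dwell weights are fit by nonnegative least squares so the prescription
    dose is approximated on prostate-surface sampling points, then rescaled
    uniformly so the target coverage V100% reaches ``coverage_target``
    percent (clinical plans carry headroom above the >= 95% objective).

    Returns the weighted dwell list and a report of achieved protocol
    metrics (V100/V150/V200, urethra D0.1cc, rectum/bladder D1cc, in % of
    the prescription where applicable).
    """
    from . import plan_metrics  # local import: metrics layer sits above dose

    src = source or SourceModel()
    cands = candidate_dwells(model, step_mm=step_mm)
    pts = _surface_points(model)
    r_min = 0.5 * float(np.linalg.norm(model.grid.spacing))
    A = np.empty((len(pts), len(cands)))
    for j, dw in enumerate(cands):
        A[:, j] = _dose_at_points(src, [dw], pts, r_min)
    w, _ = nnls(A, np.full(len(pts), prescription))
    dwells = [Dwell(d.position, float(wi)) for d, wi in zip(cands, w) if wi > 0]
    dose = tg43_dose(src, dwells, model.grid)

    prost = model.mask(Tissue.PROSTATE)
    d_prost = dose[prost]
    # scale so that coverage_target % of the prostate receives >= prescription
    dcov = np.percentile(d_prost, 100.0 - coverage_target)
    scale = prescription / dcov
    dwells = [Dwell(d.position, d.weight * scale) for d in dwells]
    dose = dose * scale

    vv = model.grid.voxel_volume_cc
    report = {
        "V100_pct": plan_metrics.volume_fraction_at(dose, prost, prescription),
        "V150_pct": plan_metrics.volume_fraction_at(dose, prost, 1.5 * prescription),
        "V200_pct": plan_metrics.volume_fraction_at(dose, prost, 2.0 * prescription),
        "urethra_D01cc_Gy": plan_metrics.dose_at_volume_cc(
            dose, model.mask(Tissue.URETHRA), 0.1, vv),
        "rectum_D1cc_Gy": plan_metrics.dose_at_volume_cc(
            dose, model.mask(Tissue.RECTUM), 1.0, vv),
        "bladder_D1cc_Gy": plan_metrics.dose_at_volume_cc(
            dose, model.mask(Tissue.BLADDER), 1.0, vv),
    }
    return dwells, report


def scale_dose(dose: np.ndarray, s: float) -> np.ndarray:
    """Uniform scaling of the physical dose grid (s > 0)."""
    if s <= 0:
        raise ValueError(f"dose scaling must be > 0, got {s}")
    return dose * s
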
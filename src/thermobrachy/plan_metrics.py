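"""Dose-volume / temperature-volume metrics and 3D gamma-index analysis.

Conventions
-----------
* ``V_x`` uses the >= threshold convention (a voxel exactly at the
  threshold counts as covered).
* ``D_xcc`` (dose to the hottest x cm^3) and the temperature percentiles
  ``T_p`` (temperature reached in at least p% of the volume) both follow
  the sorted-cumulative-volume rule: voxel values are sorted descending
  and linearly interpolated on cumulative volume.
* The gamma index compares an evaluated distribution against a reference
  with a dose-difference criterion (percent of a global normalization
  value) and a distance-to-agreement (DTA) criterion; a voxel passes when
  gamma <= 1.  For temperature comparisons the inputs should be
  *elevations* above baseline so the percent criterion acts on the
  temperature-increase scale.  Because the DTA (0.5 mm) is finer than
  typical grids, the reference is subsampled by trilinear interpolation
  on a spherical offset lattice around each evaluated voxel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .tissue_model import VoxelGrid

__all__ = [
    "DVHCurve",
    "GammaResult",
    "volume_fraction_at",
    "dose_at_volume_cc",
    "temperature_percentiles",
    "cumulative_histogram",
    "gamma_index_3d",
]


class MetricError(ValueError):
    """Metric requested on an empty mask or out-of-range volume."""


def volume_fraction_at(values: np.ndarray, mask: np.ndarray, threshold: float) -> float:
    """Percent of the organ volume at or above ``threshold``."""
    sel = values[mask]
    if sel.size == 0:
        raise MetricError("empty organ mask")
    return 100.0 * float(np.count_nonzero(sel >= threshold)) / sel.size


def _value_at_cumulative_volume(sorted_desc: np.ndarray, vol_cc: float,
                                voxel_cc: float) -> float:
    """Linear interpolation of descending-sorted values on cumulative volume."""
    cum = voxel_cc * np.arange(1, sorted_desc.size + 1)
    if vol_cc <= cum[0]:
        return float(sorted_desc[0])
    return float(np.interp(vol_cc, cum, sorted_desc))


def dose_at_volume_cc(values: np.ndarray, mask: np.ndarray, x_cc: float,
                      voxel_cc: float) -> float:
    """Highest dose received by at least ``x_cc`` of the organ (D_xcc)."""
    sel = values[mask]
    if sel.size == 0:
        raise MetricError("empty organ mask")
    total = sel.size * voxel_cc
    if x_cc > total + 1e-12:
        raise MetricError(f"requested {x_cc} cc of a {total:.2f} cc organ")
    return _value_at_cumulative_volume(np.sort(sel)[::-1], x_cc, voxel_cc)


def temperature_percentiles(values: np.ndarray, mask: np.ndarray) -> tuple[float, float, float]:
    """(T10, T50, T90): temperature reached in at least 10/50/90% of volume."""
    sel = values[mask]
    if sel.size == 0:
        raise MetricError("empty organ mask")
    srt = np.sort(sel)[::-1]
    out = []
    for p in (10.0, 50.0, 90.0):
        out.append(_value_at_cumulative_volume(srt, p / 100.0 * srt.size, 1.0))
    return tuple(out)


@dataclass(frozen=True)
class DVHCurve:
    """Cumulative histogram: volume fraction (and cc) at or above threshold."""

    organ: str
    thresholds: np.ndarray
    fraction: np.ndarray
    volume_cc: np.ndarray

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"threshold": self.thresholds, "fraction": self.fraction,
             "volume_cc": self.volume_cc}
        )


def cumulative_histogram(values: np.ndarray, mask: np.ndarray, organ: str,
                         voxel_cc: float, n_bins: int = 200,
                         upper: float | None = None) -> DVHCurve:
    sel = values[mask]
    if sel.size == 0:
        raise MetricError("empty organ mask")
    hi = upper if upper is not None else float(sel.max())
    thr = np.linspace(0.0, max(hi, 1e-12), n_bins)
    frac = np.array([np.count_nonzero(sel >= t) / sel.size for t in thr])
    return DVHCurve(organ, thr, frac, frac * sel.size * voxel_cc)


@dataclass(frozen=True)
class GammaResult:
    gamma: np.ndarray           # gamma map; NaN outside the analysis region
    passing_rate: float         # % of analyzed voxels with gamma <= 1
    dd_percent: float
    dta_mm: float
    normalization: float
    n_evaluated: int


def gamma_index_3d(
    reference: np.ndarray,
    evaluated: np.ndarray,
    grid: VoxelGrid,
    dd_percent: float = 5.0,
    dta_mm: float = 0.5,
    normalization: float | None = None,
    cutoff_fraction: float = 0.1,
    search_radius_mm: float | None = None,
    search_step_mm: float | None = None,
) -> GammaResult:
    """3D gamma analysis of ``evaluated`` against ``reference``.

    gamma(x) = min over reference sample points y of
    sqrt( ((ref(y) - eval(x)) / (dd% * norm))^2 + (|y - x| / dta)^2 ).

    ``normalization`` defaults to the global maximum of the reference (so
    dd_percent acts on the reference scale); the analysis region is
    restricted to voxels with reference value >= ``cutoff_fraction`` of
    the maximum.  The reference is sampled on a spherical offset lattice
    (default radius 3*dta, step dta/2) by trilinear interpolation, which
    is required whenever the DTA is finer than the grid spacing.
    """
    if reference.shape != evaluated.shape:
        raise ValueError("reference and evaluated grids must share one raster")
    if dd_percent <= 0 or dta_mm <= 0:
        raise ValueError("criteria must be positive")
    norm = float(np.max(reference)) if normalization is None else float(normalization)
    if norm <= 0:
        raise ValueError("normalization value must be positive")
    crit = dd_percent / 100.0 * norm
    radius = 3.0 * dta_mm if search_radius_mm is None else search_radius_mm
    step = dta_mm / 2.0 if search_step_mm is None else search_step_mm

    region = reference >= cutoff_fraction * np.max(reference)
    pts = np.argwhere(region).astype(float)  # voxel-index coordinates
    ev = evaluated[region]

    # offset lattice in mm, sorted by distance so the cheap zero-offset
    # dose-difference term seeds the running minimum
    n_steps = int(np.floor(radius / step))
    ticks = step * np.arange(-n_steps, n_steps + 1)
    ox, oy, oz = np.meshgrid(ticks, ticks, ticks, indexing="ij")
    offs = np.column_stack([ox.ravel(), oy.ravel(), oz.ravel()])
    dist = np.linalg.norm(offs, axis=1)
    keep = dist <= radius + 1e-9
    offs, dist = offs[keep], dist[keep]
    order = np.argsort(dist)
    offs, dist = offs[order], dist[order]

    spacing = np.asarray(grid.spacing)
    gamma2 = np.full(ev.shape, np.inf)
    for off, d in zip(offs, dist):
        dta_term = (d / dta_mm) ** 2
        if dta_term >= gamma2.max():
            break  # no voxel can improve at larger distances
        coords = (pts + off / spacing).T
        ref_s = ndimage.map_coordinates(reference, coords, order=1,
                                        mode="constant", cval=np.nan)
        g2 = ((ref_s - ev) / crit) ** 2 + dta_term
        np.fmin(gamma2, g2, out=gamma2)  # fmin ignores NaN samples
    gamma_flat = np.sqrt(gamma2)
    gmap = np.full(reference.shape, np.nan)
    gmap[region] = gamma_flat
    passing = 100.0 * float(np.count_nonzero(gamma_flat <= 1.0)) / gamma_flat.size
    return GammaResult(gmap, passing, dd_percent, dta_mm, norm, int(gamma_flat.size))
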
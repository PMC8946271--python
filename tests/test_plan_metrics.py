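"""Volume metrics and gamma index against brute-force oracles."""

import numpy as np
import pytest

from thermobrachy.plan_metrics import (
    MetricError,
    cumulative_histogram,
    dose_at_volume_cc,
    gamma_index_3d,
    temperature_percentiles,
    volume_fraction_at,
)
from thermobrachy.tissue_model import VoxelGrid


def test_volume_fraction_examples():
    d = np.array([1.0, 2.0, 3.0, 4.0]).reshape(1, 1, 4)
    m = np.ones_like(d, bool)
    assert volume_fraction_at(d, m, 2.5) == 50.0
    assert volume_fraction_at(d, m, 0.0) == 100.0
    assert volume_fraction_at(np.full((2, 2, 2), 5.0), np.ones((2, 2, 2), bool),
                              5.0) == 100.0  # >= convention at the threshold
    with pytest.raises(MetricError):
        volume_fraction_at(d, np.zeros_like(m), 1.0)


def test_dose_at_volume_examples():
    d = np.array([20.0, 18.0, 16.0, 14.0, 12.0]).reshape(1, 1, 5)
    m = np.ones_like(d, bool)
    # 0.05 cc voxels: hottest 0.1 cc = two voxels -> 18 Gy
    assert dose_at_volume_cc(d, m, 0.1, 0.05) == 18.0
    assert dose_at_volume_cc(d, m, 0.05, 0.05) == 20.0  # one voxel -> max
    u = np.full((3, 3, 3), 7.5)
    assert dose_at_volume_cc(u, np.ones_like(u, bool), 0.2, 0.01) == 7.5
    with pytest.raises(MetricError):
        dose_at_volume_cc(d, m, 10.0, 0.05)


def test_dose_at_volume_matches_sort_oracle(rng):
    for _ in range(20):
        vals = rng.uniform(0, 30, (4, 5, 6))
        mask = rng.uniform(size=vals.shape) > 0.4
        if not mask.any():
            continue
        vv = 0.037
        x = rng.uniform(vv, mask.sum() * vv)
        srt = np.sort(vals[mask])[::-1]
        cum = vv * np.arange(1, srt.size + 1)
        expected = srt[0] if x <= cum[0] else np.interp(x, cum, srt)
        assert dose_at_volume_cc(vals, mask, x, vv) == pytest.approx(expected)


def test_temperature_percentiles_examples():
    t = np.arange(37.0, 47.0).reshape(1, 2, 5)  # 10 voxels 37..46
    m = np.ones_like(t, bool)
    t10, t50, t90 = temperature_percentiles(t, m)
    assert t90 == 38.0  # reached in at least 9 of 10 voxels
    assert t10 >= t50 >= t90
    u = np.full((2, 2, 2), 41.3)
    assert temperature_percentiles(u, np.ones_like(u, bool)) == (41.3, 41.3, 41.3)


def test_metrics_invariant_under_voxel_order(rng):
    vals = rng.uniform(0, 10, (3, 4, 5))
    mask = np.ones_like(vals, bool)
    perm = rng.permutation(vals.size).reshape(vals.shape)
    shuffled = vals.ravel()[perm]
    assert volume_fraction_at(vals, mask, 5.0) == volume_fraction_at(
        shuffled, mask, 5.0)
    assert dose_at_volume_cc(vals, mask, 0.3, 0.01) == pytest.approx(
        dose_at_volume_cc(shuffled, mask, 0.3, 0.01))


def test_cumulative_histogram_monotone(rng):
    vals = rng.uniform(0, 20, (6, 6, 6))
    curve = cumulative_histogram(vals, np.ones_like(vals, bool), "organ", 0.008)
    assert curve.fraction[0] == 1.0
    assert np.all(np.diff(curve.fraction) <= 1e-12)


def test_gamma_identical_grids_pass_everywhere(rng):
    grid = VoxelGrid((9, 9, 9), (1.0,) * 3)
    ref = rng.uniform(1.0, 10.0, grid.shape)
    res = gamma_index_3d(ref, ref.copy(), grid, cutoff_fraction=0.0)
    assert res.passing_rate == 100.0
    assert np.nanmax(res.gamma) < 1e-9


def test_gamma_uniform_offset_at_criterion():
    """A spatially uniform reference shifted by exactly the dose criterion
    gives gamma = 1 everywhere (DTA term minimized at zero distance)."""
    grid = VoxelGrid((7, 7, 7), (1.0,) * 3)
    ref = np.full(grid.shape, 10.0)
    ev = ref + 0.05 * 10.0  # +dd% of the normalization
    res = gamma_index_3d(ref, ev, grid, dd_percent=5.0, dta_mm=0.5,
                         normalization=10.0, cutoff_fraction=0.0)
    assert np.allclose(res.gamma, 1.0, atol=1e-9)
    assert res.passing_rate == 100.0


def test_gamma_matches_exhaustive_oracle(rng):
    """On a 9^3 grid, searching the full voxel lattice must reproduce the
    brute-force min over all reference voxels exactly."""
    grid = VoxelGrid((9, 9, 9), (1.0,) * 3)
    ref = rng.uniform(0.0, 10.0, grid.shape)
    ev = ref + rng.normal(0, 0.8, grid.shape)
    dd, dta, norm = 5.0, 2.0, 10.0
    big = 20.0  # radius covering the whole grid
    res = gamma_index_3d(ref, ev, grid, dd_percent=dd, dta_mm=dta,
                         normalization=norm, cutoff_fraction=0.0,
                         search_radius_mm=big, search_step_mm=1.0)
    crit = dd / 100.0 * norm
    pts = np.argwhere(np.ones(grid.shape, bool)).astype(float)
    oracle = np.empty(grid.shape)
    for i, p in enumerate(pts):
        dist2 = np.sum((pts - p) ** 2, axis=1)
        keep = dist2 <= big ** 2
        g2 = ((ref.ravel()[keep] - ev.ravel()[int(i)]) / crit) ** 2 \
            + dist2[keep] / dta ** 2
        oracle.ravel()[int(i)] = np.sqrt(g2.min())
    assert np.allclose(res.gamma, oracle, atol=1e-12)


def test_gamma_raster_mismatch_rejected():
    grid = VoxelGrid((5, 5, 5), (1.0,) * 3)
    with pytest.raises(ValueError, match="raster"):
        gamma_index_3d(np.ones(grid.shape), np.ones((4, 5, 5)), grid)
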
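"""Objective construction, PSO behavior, and the plan-level contracts."""

import numpy as np
import pytest

from thermobrachy.plan_optimizer import (
    ConstraintSpec,
    ObjectiveSpec,
    PSOConfig,
    PlanProblem,
    limits_from_bt_plan,
    pso_optimize,
)
from thermobrachy.brachy_dose import SourceModel, heuristic_dwell_weights, tg43_dose
from thermobrachy.tdlq import PRESETS


def test_penalty_and_score_forms():
    # high-pass coverage constraint: V100 = 93% against limit 95% -> 2% short
    c = ConstraintSpec("prostate_V100", limit=95.0, polarity=-1)
    assert 1e3 * c.penalty(93.0) == pytest.approx(2000.0)
    assert c.penalty(96.0) == 0.0
    # low-pass dose constraint
    lp = ConstraintSpec("urethra_D01cc", limit=15.0, polarity=+1)
    assert lp.penalty(16.5) == pytest.approx(1.5)
    assert lp.penalty(14.0) == 0.0
    # scoring: urethra dose 10 Gy against goal 0 with weight 1
    o = ObjectiveSpec("urethra_D01cc", goal=0.0, weight=1.0)
    assert o.score(10.0) == 10.0
    v150 = ObjectiveSpec("prostate_V150", goal=30.0, weight=0.01)
    assert v150.score(25.0) == 0.0  # below goal contributes nothing


class _Surrogate:
    """Duck-typed problem exposing the optimizer contract for oracles."""

    def __init__(self, fn, n, v_max):
        self.fn = fn
        self.n_electrodes = n
        self.v_max = np.asarray(v_max, float)

    def evaluate(self, v):
        return self.fn(np.asarray(v)), {"penalties": {}}

    def report(self, v):
        return {}


def test_pso_recovers_convex_minimum():
    target = np.array([0.3, 1.2, 0.7, 0.05, 0.9])
    prob = _Surrogate(lambda v: float(np.sum((v - target) ** 2)), 5, np.full(5, 2.0))
    res = pso_optimize(prob, PSOConfig(max_iter=400, stagnation=400), seed=3)
    assert np.linalg.norm(res.v_best - target) < 1e-2
    assert np.all(np.diff(res.trace) <= 1e-15)  # global best never worsens


def test_pso_deterministic_for_fixed_seed():
    prob = _Surrogate(lambda v: float(np.sum((v - 1.0) ** 2)), 3, np.full(3, 2.0))
    a = pso_optimize(prob, seed=11)
    b = pso_optimize(prob, seed=11)
    assert np.array_equal(a.v_best, b.v_best)
    assert np.array_equal(a.trace, b.trace)


def test_pso_penalty_drives_feasibility_vs_grid_search():
    """2-D objective with the constraint v0 + v1 <= 3 active at the
    unconstrained optimum (2, 2); compared against an exhaustive grid."""

    def fn(v):
        return float(np.sum((v - 2.0) ** 2) + 1e3 * max(0.0, v[0] + v[1] - 3.0))

    prob = _Surrogate(fn, 2, np.full(2, 3.0))
    res = pso_optimize(prob, PSOConfig(max_iter=400, stagnation=400), seed=5)
    xs = np.linspace(0, 3, 301)
    gx, gy = np.meshgrid(xs, xs, indexing="ij")
    vals = (gx - 2) ** 2 + (gy - 2) ** 2 + 1e3 * np.maximum(0.0, gx + gy - 3)
    i, j = np.unravel_index(np.argmin(vals), vals.shape)
    grid_best = np.array([xs[i], xs[j]])
    assert res.v_best[0] + res.v_best[1] <= 3.0 + 1e-6
    assert np.linalg.norm(res.v_best - grid_best) < 0.05
    assert res.omega == pytest.approx(vals[i, j], abs=1e-3)


def test_zero_dimensional_problem_rejected():
    prob = _Surrogate(lambda v: 0.0, 0, np.zeros(0))
    with pytest.raises(ValueError):
        pso_optimize(prob, seed=1)


@pytest.fixture(scope="module")
def small_plan(small_model, small_bases):
    basis, elec = small_bases
    dwells, _ = heuristic_dwell_weights(small_model)
    dose = tg43_dose(SourceModel(), dwells, small_model.grid)
    limits = limits_from_bt_plan(dose, small_model, 13.5)
    return small_model, basis, elec, dose, limits


def test_limits_self_consistency(small_plan):
    """The BT-only plan evaluated as its own combined plan with heating off
    reproduces its limit metrics exactly and carries no penalty."""
    model, basis, elec, dose, limits = small_plan
    problem = PlanProblem(model, basis, dose, 13.5, limits, PRESETS["AVG"],
                          electrode_voxels=elec)
    omega, detail = problem.evaluate(np.zeros(model.n_electrodes))
    m = detail["metrics"]
    assert m["prostate_V100"] == pytest.approx(limits["prostate_V100"])
    assert m["urethra_D01cc"] == pytest.approx(limits["urethra_D01cc"])
    assert m["rectum_D1cc"] == pytest.approx(limits["rectum_D1cc"])
    assert m["bladder_D1cc"] == pytest.approx(limits["bladder_D1cc"])
    assert m["tmax"] == pytest.approx(37.0)
    assert all(p == 0.0 for p in detail["penalties"].values())


def test_scaled_dose_without_heating_violates_coverage(small_plan):
    model, basis, elec, dose, limits = small_plan
    problem = PlanProblem(model, basis, dose * 0.8, 13.5, limits,
                          PRESETS["AVG"], electrode_voxels=elec)
    omega, detail = problem.evaluate(np.zeros(model.n_electrodes))
    assert detail["penalties"]["prostate_V100"] > 0
    assert omega >= 1e3 * detail["penalties"]["prostate_V100"]


def test_temperature_ceiling_penalized(small_plan):
    model, basis, elec, dose, limits = small_plan
    problem = PlanProblem(model, basis, dose, 13.5, limits, PRESETS["AVG"],
                          electrode_voxels=elec)
    hot = 1.5 * problem.v_max  # beyond the single-electrode calibration
    m = problem.metrics(hot)
    assert m["tmax"] > 47.5
    _, detail = problem.evaluate(hot)
    assert detail["penalties"]["tmax"] > 0


def test_amplitude_bounds_calibrated_to_tmax(small_plan):
    """One electrode at its full drive heats to ~Tmax somewhere."""
    model, basis, elec, dose, limits = small_plan
    problem = PlanProblem(model, basis, dose, 13.5, limits, PRESETS["AVG"],
                          electrode_voxels=elec)
    i = 0
    v = np.zeros(model.n_electrodes)
    v[i] = problem.v_max[i]
    peak = 37.0 + problem.v_max[i] ** 2 * float(basis[i].max())
    assert peak == pytest.approx(47.5, abs=1e-3)


def test_missing_organ_rejected(small_model):
    labels = small_model.labels.copy()
    labels[labels == 7] = 1  # erase the bladder
    import dataclasses

    broken = dataclasses.replace(small_model, labels=labels)
    with pytest.raises(ValueError, match="BLADDER"):
        limits_from_bt_plan(np.ones(broken.grid.shape), broken, 13.5)
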
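"""Constrained electrode-amplitude optimization.

The planning objective mirrors the radiotherapeutic protocol: the
equivalent physical dose of the combined plan must keep the target
coverage of the brachytherapy-only plan while not exceeding its
organ-at-risk metrics, under an overall temperature ceiling
Tmax = 47.5 degC.  Violated constraints contribute penalty terms

    PF_i = max(0, p_i (C_i - L_i)),   p_i = +1 low-pass / -1 high-pass,

and scoring terms SF_j = w_j max(0, O_j - G_j) push the urethra and
rectum doses down and the prostate V150 toward its 30% soft limit.  The
total objective

    Omega = W sum_i PF_i + sum_j SF_j,     W = 10^3,

is minimized over the (real, nonnegative) electrode amplitudes with a
global-best particle swarm.  Every candidate evaluation is a cheap
weighted superposition of the precomputed per-electrode temperature
bases restricted to the organ masks plus a dilated electrode envelope
for the temperature ceiling, so no PDE is solved inside the loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import plan_metrics
from .tdlq import PRESETS, TDLQParams, eqd_phys_scalar, tissue_param_map
from .tissue_model import Tissue, VoxelTissueModel

__all__ = [
    "ConstraintSpec",
    "ObjectiveSpec",
    "PSOConfig",
    "PlanProblem",
    "OptResult",
    "evaluate_objective",
    "pso_optimize",
    "limits_from_bt_plan",
    "dose_scaling_study",
]

TMAX_LIMIT = 47.5  # degC, overall upper temperature limit
PENALTY_WEIGHT = 1e3

ORGANS = (Tissue.PROSTATE, Tissue.URETHRA, Tissue.RECTUM, Tissue.BLADDER)


@dataclass(frozen=True)
class ConstraintSpec:
    """One protocol constraint: criterion C against limit L with polarity p."""

    name: str
    limit: float
    polarity: int  # +1 low pass (C <= L), -1 high pass (C >= L)

    def penalty(self, value: float) -> float:
        return max(0.0, self.polarity * (value - self.limit))


@dataclass(frozen=True)
class ObjectiveSpec:
    """One scoring term: weight w toward goal G (nonnegative contribution)."""

    name: str
    goal: float
    weight: float

    def score(self, value: float) -> float:
        return self.weight * max(0.0, value - self.goal)


@dataclass(frozen=True)
class PSOConfig:
    """Global-best particle swarm hyperparameters (constriction defaults)."""

    n_particles: int = 40
    inertia: float = 0.7298
    cognitive: float = 1.49618
    social: float = 1.49618
    max_iter: int = 300
    velocity_clamp: float = 0.2   # fraction of the bound range
    stagnation: int = 50          # early stop after this many stalled iterations
    include_baseline: bool = True  # seed one particle at v = 0 (heating off)


def limits_from_bt_plan(bt_dose: np.ndarray, model: VoxelTissueModel,
                        prescription: float) -> dict[str, float]:
    """Constraint limits taken from the (unscaled) BT-only plan's metrics."""
    vv = model.grid.voxel_volume_cc
    for organ in ORGANS:
        if not model.mask(organ).any():
            raise ValueError(f"model lacks organ {organ.name} required by the protocol")
    return {
        "prostate_V100": plan_metrics.volume_fraction_at(
            bt_dose, model.mask(Tissue.PROSTATE), prescription),
        "urethra_D01cc": plan_metrics.dose_at_volume_cc(
            bt_dose, model.mask(Tissue.URETHRA), 0.1, vv),
        "rectum_D1cc": plan_metrics.dose_at_volume_cc(
            bt_dose, model.mask(Tissue.RECTUM), 1.0, vv),
        "bladder_D1cc": plan_metrics.dose_at_volume_cc(
            bt_dose, model.mask(Tissue.BLADDER), 1.0, vv),
        "tmax": TMAX_LIMIT,
    }


def _electrode_envelope(model: VoxelTissueModel, electrode_voxels, radius_mm: float) -> np.ndarray:
    """Tissue voxels within ``radius_mm`` of any electrode (Tmax region)."""
    seed = np.zeros(model.grid.n_voxels, bool)
    for idx in electrode_voxels:
        seed[idx] = True
    seed = seed.reshape(model.grid.shape)
    r_vox = np.maximum(np.ceil(radius_mm / np.asarray(model.grid.spacing)), 1).astype(int)
    zz, yy, xx = np.meshgrid(*[np.arange(-r, r + 1) for r in r_vox], indexing="ij")
    ball = ((zz * model.grid.spacing[0] / radius_mm) ** 2
            + (yy * model.grid.spacing[1] / radius_mm) ** 2
            + (xx * model.grid.spacing[2] / radius_mm) ** 2) <= 1.0
    env = ndimage.binary_dilation(seed, structure=ball)
    return env & (model.labels != int(Tissue.AIR))


class PlanProblem:
    """Precomputed evaluation state for one (phantom, basis, dose) triple.

    Holds, per organ, the scaled physical dose vector and the
    ``(n_voxels, n_electrodes)`` slab of the elevation basis so a candidate
    amplitude vector is scored by dense matrix products only.
    """

    def __init__(
        self,
        model: VoxelTissueModel,
        delta_t_basis: np.ndarray,
        dose: np.ndarray,
        prescription: float,
        limits: dict[str, float],
        tumor_params: TDLQParams,
        normal_mode: str = "worst",
        electrode_voxels=None,
        envelope_mm: float = 12.0,
        penalty_weight: float = PENALTY_WEIGHT,
    ) -> None:
        from .tissue_model import rasterize_electrodes

        self.model = model
        self.prescription = prescription
        self.penalty_weight = penalty_weight
        self.tumor_params = tumor_params
        self.normal_mode = normal_mode
        self.params = tissue_param_map(tumor_params, normal_mode)
        self.n_electrodes = delta_t_basis.shape[0]
        self.tb = model.blood.temperature
        self.voxel_cc = model.grid.voxel_volume_cc

        flat_basis = delta_t_basis.reshape(self.n_electrodes, -1)
        dose_flat = dose.ravel()
        self._organ: dict[Tissue, dict] = {}
        for organ in ORGANS:
            idx = np.flatnonzero(model.mask(organ).ravel())
            self._organ[organ] = {
                "A": np.ascontiguousarray(flat_basis[:, idx].T, dtype=np.float64),
                "dose": dose_flat[idx],
            }
        ev = electrode_voxels if electrode_voxels is not None else rasterize_electrodes(model)
        env = _electrode_envelope(model, ev, envelope_mm).ravel()
        self._A_env = np.ascontiguousarray(
            flat_basis[:, np.flatnonzero(env)].T, dtype=np.float64)

        self.constraints = {
            "prostate_V100": ConstraintSpec("prostate_V100", limits["prostate_V100"], -1),
            "urethra_D01cc": ConstraintSpec("urethra_D01cc", limits["urethra_D01cc"], +1),
            "rectum_D1cc": ConstraintSpec("rectum_D1cc", limits["rectum_D1cc"], +1),
            "bladder_D1cc": ConstraintSpec("bladder_D1cc", limits["bladder_D1cc"], +1),
            "tmax": ConstraintSpec("tmax", limits.get("tmax", TMAX_LIMIT), +1),
        }
        self.objectives = {
            "urethra_D01cc": ObjectiveSpec("urethra_D01cc", goal=0.0, weight=1.0),
            "rectum_D1cc": ObjectiveSpec("rectum_D1cc", goal=0.0, weight=1.0),
            "prostate_V150": ObjectiveSpec("prostate_V150", goal=30.0, weight=0.01),
        }

        # Amplitude bounds: one electrode at full drive reaches ~Tmax locally.
        peaks = flat_basis.max(axis=1).astype(np.float64)
        headroom = self.constraints["tmax"].limit - self.tb
        self.v_max = np.sqrt(headroom / np.maximum(peaks, 1e-12))

    def _organ_fields(self, v: np.ndarray, organ: Tissue):
        data = self._organ[organ]
        T = data["A"] @ (np.asarray(v, float) ** 2) + self.tb
        eqd = eqd_phys_scalar(data["dose"], T, self.params[organ])
        return T, eqd

    def metrics(self, v: np.ndarray) -> dict[str, float]:
        """Protocol criteria for one amplitude vector (EQD_phys scale)."""
        out: dict[str, float] = {}
        _, eqd_p = self._organ_fields(v, Tissue.PROSTATE)
        dp = self.prescription
        out["prostate_V100"] = 100.0 * np.count_nonzero(eqd_p >= dp) / eqd_p.size
        out["prostate_V150"] = 100.0 * np.count_nonzero(eqd_p >= 1.5 * dp) / eqd_p.size
        out["prostate_V200"] = 100.0 * np.count_nonzero(eqd_p >= 2.0 * dp) / eqd_p.size
        for organ, key, x_cc in ((Tissue.URETHRA, "urethra_D01cc", 0.1),
                                 (Tissue.RECTUM, "rectum_D1cc", 1.0),
                                 (Tissue.BLADDER, "bladder_D1cc", 1.0)):
            _, eqd = self._organ_fields(v, organ)
            srt = np.sort(eqd)[::-1]
            out[key] = plan_metrics._value_at_cumulative_volume(srt, x_cc, self.voxel_cc)
        t_env = self._A_env @ (np.asarray(v, float) ** 2)
        out["tmax"] = self.tb + (float(t_env.max()) if t_env.size else 0.0)
        return out

    def evaluate(self, v: np.ndarray) -> tuple[float, dict]:
        """Objective Omega and its penalty/score breakdown."""
        m = self.metrics(v)
        penalties = {k: c.penalty(m[k]) for k, c in self.constraints.items()}
        scores = {k: o.score(m[k]) for k, o in self.objectives.items()}
        omega = self.penalty_weight * sum(penalties.values()) + sum(scores.values())
        return omega, {"metrics": m, "penalties": penalties, "scores": scores}

    def report(self, v: np.ndarray) -> dict[str, float]:
        """Full metric report: protocol criteria, prostate temperature
        percentiles, and OAR metrics under both normal-tissue modes."""
        out = dict(self.metrics(v))
        T_p, _ = self._organ_fields(v, Tissue.PROSTATE)
        srt = np.sort(T_p)[::-1]
        for p in (10, 50, 90):
            out[f"prostate_T{p}"] = plan_metrics._value_at_cumulative_volume(
                srt, p / 100.0 * srt.size, 1.0)
        other = PlanProblem.__new__(PlanProblem)
        other.__dict__.update(self.__dict__)
        other.normal_mode = "none" if self.normal_mode == "worst" else "worst"
        other.params = tissue_param_map(self.tumor_params, other.normal_mode)
        m2 = other.metrics(v)
        for key in ("urethra_D01cc", "rectum_D1cc", "bladder_D1cc"):
            out[f"{key}_{other.normal_mode}"] = m2[key]
        return out


def evaluate_objective(v: np.ndarray, problem: PlanProblem) -> tuple[float, dict]:
    return problem.evaluate(v)


@dataclass
class OptResult:
    v_best: np.ndarray
    omega: float
    trace: np.ndarray            # global-best objective per iteration
    metrics: dict[str, float]    # recomputed from v_best
    penalties: dict[str, float]
    feasible: bool
    seed: int
    n_iterations: int = 0


def pso_optimize(problem: PlanProblem, config: PSOConfig | None = None,
                 seed: int = 0) -> OptResult:
    """Global-best PSO over amplitudes in [0, v_max]; seeded, reproducible."""
    cfg = config or PSOConfig()
    n = problem.n_electrodes
    if n == 0:
        raise ValueError("zero-dimensional problem")
    rng = np.random.default_rng(seed)
    lo = np.zeros(n)
    hi = np.asarray(problem.v_max, float)
    rng_range = hi - lo
    vmax = cfg.velocity_clamp * rng_range

    x = lo + rng.uniform(size=(cfg.n_particles, n)) * rng_range
    if cfg.include_baseline:
        x[0] = 0.0
    vel = rng.uniform(-1, 1, size=(cfg.n_particles, n)) * vmax

    fx = np.array([problem.evaluate(p)[0] for p in x])
    pbest, fpbest = x.copy(), fx.copy()
    g = int(np.argmin(fpbest))
    gbest, fgbest = pbest[g].copy(), float(fpbest[g])
    trace = [fgbest]
    stall = 0
    it = 0
    for it in range(1, cfg.max_iter + 1):
        r1 = rng.uniform(size=(cfg.n_particles, n))
        r2 = rng.uniform(size=(cfg.n_particles, n))
        vel = (cfg.inertia * vel
               + cfg.cognitive * r1 * (pbest - x)
               + cfg.social * r2 * (gbest[None, :] - x))
        vel = np.clip(vel, -vmax, vmax)
        xn = x + vel
        hit = (xn < lo) | (xn > hi)
        vel[hit] = 0.0  # absorbing walls: a clipped particle stops drifting
        x = np.clip(xn, lo, hi)
        fx = np.array([problem.evaluate(p)[0] for p in x])
        better = fx < fpbest
        pbest[better], fpbest[better] = x[better], fx[better]
        g = int(np.argmin(fpbest))
        if fpbest[g] < fgbest - 1e-15:
            gbest, fgbest = pbest[g].copy(), float(fpbest[g])
            stall = 0
        else:
            stall += 1
        trace.append(fgbest)
        if stall >= cfg.stagnation:
            break

    omega, detail = problem.evaluate(gbest)
    feasible = all(p <= 1e-9 for p in detail["penalties"].values())
    return OptResult(
        v_best=gbest,
        omega=omega,
        trace=np.asarray(trace),
        metrics=problem.report(gbest),
        penalties=detail["penalties"],
        feasible=feasible,
        seed=seed,
        n_iterations=it,
    )


def dose_scaling_study(
    model: VoxelTissueModel,
    delta_t_basis: np.ndarray,
    bt_dose: np.ndarray,
    prescription: float,
    scalings=(0.70, 0.75, 0.80, 0.85, 0.90, 0.95),
    presets=("PC3", "DU145", "AVG"),
    seed: int = 0,
    pso_config: PSOConfig | None = None,
    electrode_voxels=None,
):
    """Optimize the combined plan for each (dose scaling, preset) pair.

    The constraint limits come from the *unscaled* BT-only plan; for every
    scaled dose grid the electrode amplitudes are re-optimized and the full
    metric report (coverage, high-dose volumes, temperature percentiles,
    OAR doses under both sensitization modes) is recorded.  Returns a
    pandas DataFrame, one row per run.
    """
    import pandas as pd

    limits = limits_from_bt_plan(bt_dose, model, prescription)
    children = np.random.SeedSequence(seed).spawn(len(presets) * len(scalings))
    rows = []
    k = 0
    for preset in presets:
        tumor = PRESETS[preset] if isinstance(preset, str) else preset
        for s in scalings:
            problem = PlanProblem(
                model, delta_t_basis, bt_dose * s, prescription, limits,
                tumor, normal_mode="worst", electrode_voxels=electrode_voxels,
            )
            sub_seed = int(children[k].generate_state(1)[0] % (2 ** 31))
            k += 1
            res = pso_optimize(problem, pso_config, seed=sub_seed)
            row = {"preset": preset if isinstance(preset, str) else "custom",
                   "scaling": s, "omega": res.omega, "feasible": res.feasible,
                   "n_iterations": res.n_iterations}
            row.update(res.metrics)
            rows.append(row)
    return pd.DataFrame(rows)
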
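"""Volume/plan I/O, run configuration, and basis caching.

Volumes travel as NIfTI (spacing and origin encoded in the affine), the
applicator geometry and plans as JSON, run settings as YAML, and the
heavy per-electrode elevation bases as compressed ``.npz`` keyed by a
content hash of (model, solver settings) so optimizer runs and studies
never re-solve the PDEs for an unchanged phantom.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from . import bioheat, em_solver
from .brachy_dose import Dwell
from .tissue_model import (
    Applicator,
    BloodProperties,
    ElectrodeSegment,
    PhantomConfig,
    VoxelGrid,
    VoxelTissueModel,
)

__all__ = [
    "write_volume",
    "read_volume",
    "save_model",
    "load_model",
    "save_dwells",
    "load_dwells",
    "load_run_config",
    "model_hash",
    "compute_bases",
    "validation_amplitudes",
]


class FormatError(ValueError):
    """Malformed or raster-incompatible file."""


def _affine(grid: VoxelGrid) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(grid.spacing)
    aff[:3, 3] = grid.origin
    return aff


def write_volume(path: str | Path, values: np.ndarray, grid: VoxelGrid) -> None:
    if tuple(values.shape) != tuple(grid.shape):
        raise FormatError(f"array shape {values.shape} != raster {grid.shape}")
    img = nib.Nifti1Image(np.asarray(values), _affine(grid))
    nib.save(img, str(path))


def read_volume(path: str | Path) -> tuple[np.ndarray, VoxelGrid]:
    try:
        img = nib.load(str(path))
    except Exception as err:  # nibabel raises several format-specific types
        raise FormatError(f"cannot read volume {path}: {err}") from err
    aff = img.affine
    grid = VoxelGrid(
        shape=tuple(int(s) for s in img.shape[:3]),
        spacing=tuple(float(aff[i, i]) for i in range(3)),
        origin=tuple(float(aff[i, 3]) for i in range(3)),
    )
    return np.asarray(img.dataobj), grid


def require_same_raster(grid: VoxelGrid, other: VoxelGrid, what: str = "volume") -> None:
    if not grid.same_raster(other):
        raise FormatError(
            f"{what} raster {other.shape}@{other.spacing} does not match "
            f"model raster {grid.shape}@{grid.spacing}"
        )


def save_model(directory: str | Path, model: VoxelTissueModel) -> None:
    """Persist a tissue model as labels.nii.gz + model.json."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_volume(d / "labels.nii.gz", model.labels.astype(np.int16), model.grid)
    meta = {
        "frequency": model.frequency,
        "catheter_radius": model.catheter_radius,
        "blood": asdict(model.blood),
        "applicators": [
            {
                "identifier": a.identifier,
                "track_start": list(a.track_start),
                "track_end": list(a.track_end),
                "electrodes": [[e.start, e.end] for e in a.electrodes],
                "coating_thickness": a.coating_thickness,
            }
            for a in model.applicators
        ],
    }
    (d / "model.json").write_text(json.dumps(meta, indent=2))


def load_model(directory: str | Path) -> VoxelTissueModel:
    d = Path(directory)
    labels, grid = read_volume(d / "labels.nii.gz")
    meta = json.loads((d / "model.json").read_text())
    apps = tuple(
        Applicator(
            identifier=a["identifier"],
            track_start=tuple(a["track_start"]),
            track_end=tuple(a["track_end"]),
            electrodes=tuple(ElectrodeSegment(*e) for e in a["electrodes"]),
            coating_thickness=a.get("coating_thickness", 0.0),
        )
        for a in meta["applicators"]
    )
    return VoxelTissueModel(
        grid=grid,
        labels=np.asarray(labels, dtype=np.int16),
        applicators=apps,
        blood=BloodProperties(**meta["blood"]),
        frequency=meta["frequency"],
        catheter_radius=meta["catheter_radius"],
    )


def save_dwells(path: str | Path, dwells: list[Dwell]) -> None:
    Path(path).write_text(json.dumps(
        [{"position": list(d.position), "weight": d.weight} for d in dwells], indent=2))


def load_dwells(path: str | Path) -> list[Dwell]:
    data = json.loads(Path(path).read_text())
    return [Dwell(tuple(d["position"]), float(d["weight"])) for d in data]


@dataclass(frozen=True)
class RunConfig:
    """Validated run settings with defaults traceable to the protocol."""

    phantom: PhantomConfig
    seed: int = 1
    em_rtol: float = 1e-8
    thermal_rtol: float = 1e-8
    prescription: float = 13.5
    coverage_target: float = 96.5
    gamma_dd_percent: float = 5.0
    gamma_dta_mm: float = 0.5
    gamma_cutoff_fraction: float = 0.1
    tumor_preset: str = "AVG"
    normal_mode: str = "worst"
    dose_scaling: float = 1.0
    pso: dict | None = None


def load_run_config(path: str | Path | None) -> RunConfig:
    """Load YAML settings on top of the defaults; unknown keys rejected."""
    data = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    phantom = PhantomConfig(**data.pop("phantom", {}))
    known = {f for f in RunConfig.__dataclass_fields__ if f != "phantom"}
    unknown = set(data) - known
    if unknown:
        raise FormatError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(phantom=phantom, **data)


def model_hash(model: VoxelTissueModel, *extras: float) -> str:
    """Content hash of the model + solver settings (basis cache key)."""
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(model.labels).tobytes())
    h.update(np.asarray(model.grid.spacing).tobytes())
    h.update(np.asarray(model.grid.origin).tobytes())
    h.update(np.float64(model.frequency).tobytes())
    h.update(np.float64(model.catheter_radius).tobytes())
    for a in model.applicators:
        h.update(np.asarray(a.track_start).tobytes())
        h.update(np.asarray(a.track_end).tobytes())
        for e in a.electrodes:
            h.update(np.asarray([e.start, e.end]).tobytes())
    for x in extras:
        h.update(np.float64(x).tobytes())
    return h.hexdigest()[:16]


def compute_bases(
    model: VoxelTissueModel,
    em_rtol: float = 1e-8,
    thermal_rtol: float = 1e-8,
    cache_dir: str | Path | None = None,
    keep_efields: bool = False,
    progress: bool = False,
):
    """Per-electrode elevation basis (and optionally the E-field basis).

    Returns ``(delta_t_basis, electrode_voxels, efields)`` where
    ``delta_t_basis`` is the (n_electrodes, *shape) stack of unit-amplitude
    temperature elevations, ``electrode_voxels`` the rasterized voxel sets,
    and ``efields`` the complex field basis (None unless requested; the
    E-fields are large and only the coupled validation solve needs them).

    With ``cache_dir`` set, the elevation basis is loaded from / saved to a
    compressed archive keyed by the model content hash.
    """
    from .tissue_model import rasterize_electrodes

    electrode_voxels = rasterize_electrodes(model)
    cache_path = None
    if cache_dir is not None:
        key = model_hash(model, em_rtol, thermal_rtol)
        cache_path = Path(cache_dir) / f"basis_{key}.npz"
        if cache_path.exists() and not keep_efields:
            with np.load(cache_path) as z:
                return z["delta_t"], electrode_voxels, None

    em = em_solver.ElectroquasistaticProblem(model, rtol=em_rtol)
    th = bioheat.BioheatProblem(model, rtol=thermal_rtol)
    n = len(electrode_voxels)
    delta_t = np.empty((n,) + tuple(model.grid.shape), dtype=np.float32)
    efields = [] if keep_efields else None
    for i in range(n):
        if progress:
            print(f"  electrode {i + 1}/{n}", flush=True)
        V = em.solve(i)
        E = em_solver.efield(V, model.grid)
        P = em_solver.power_from_total_field(E, em.sigma)
        delta_t[i] = th.solve_elevation(P)
        if keep_efields:
            efields.append(E.astype(np.complex64))
    if cache_path is not None:
        cache_path.parent.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(cache_path, delta_t=delta_t)
    return delta_t, electrode_voxels, efields


def validation_amplitudes(delta_t_basis: np.ndarray, seed: int,
                          peak_temperature: float = 46.0,
                          tb: float = 37.0) -> np.ndarray:
    """Seeded random complex drive at a plausible heating level.

    Per-electrode amplitudes are drawn uniformly and rescaled so the
    superposed peak temperature sits at ``peak_temperature`` (below the
    47.5 degC planning ceiling).  The returned drive is complex: the
    multi-channel RF system controls amplitude only, so the relative
    channel phases of the coupled reference solve are a frozen random
    snapshot (the superposition method is phase-blind, using |v_i|^2).
    """
    rng = np.random.default_rng(seed)
    amp = rng.uniform(0.25, 1.0, size=delta_t_basis.shape[0])
    peak = float(np.tensordot(amp ** 2, delta_t_basis.astype(np.float64, copy=False),
                              axes=(0, 0)).max())
    amp *= np.sqrt((peak_temperature - tb) / peak)
    return amp * np.exp(2j * np.pi * rng.uniform(size=amp.size))
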
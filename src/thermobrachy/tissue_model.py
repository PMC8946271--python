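"""Voxelized anatomy, tissue property tables, and applicator geometry.

The planning chain operates on a voxel model of the pelvic region in which
every voxel carries a tissue label (prostate, urethra, rectum, bladder,
muscle, fat, bone, air, applicator dielectric).  Electric properties are
given at the 27 MHz operating frequency of the capacitively coupled RF
heating system; thermal properties feed the Pennes bioheat solver.

Because no clinical dataset ships with the package, :func:`generate_phantom`
builds a synthetic pelvic phantom — an ellipsoidal prostate with a coaxial
urethra, a posterior rectum with an air lumen, a superior bladder, lateral
bone, and a fat rim in a muscle background — implanted with dual-electrode
interstitial applicators on a 5 mm template grid.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Tissue",
    "VoxelGrid",
    "TissueProperties",
    "BloodProperties",
    "ElectrodeSegment",
    "Applicator",
    "VoxelTissueModel",
    "PhantomConfig",
    "TISSUE_PROPERTIES",
    "generate_phantom",
    "rasterize_electrodes",
    "property_grids",
]


class Tissue(enum.IntEnum):
    """Integer labels used in the voxel label grid."""

    AIR = 0
    MUSCLE = 1
    FAT = 2
    BONE = 3
    PROSTATE = 4
    URETHRA = 5
    RECTUM = 6
    BLADDER = 7
    DIELECTRIC = 8


@dataclass(frozen=True)
class VoxelGrid:
    """Regular raster: shape, spacing (mm) and world origin (mm).

    The origin is the world coordinate of the *center* of voxel (0, 0, 0);
    the world<->index mapping is the invertible affine
    ``world = origin + index * spacing``.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(s <= 0 for s in self.shape):
            raise ValueError(f"shape must be 3 positive integers, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_cc(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(idx) * np.asarray(self.spacing)

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Continuous (fractional) voxel index of a world point."""
        return (np.asarray(xyz) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def coordinate_axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis world coordinates of voxel centers (mm)."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        )

    def same_raster(self, other: "VoxelGrid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


@dataclass(frozen=True)
class TissueProperties:
    """Electric (at the heating frequency) and thermal material properties."""

    name: str
    mass_density: float          # rho, kg/m^3
    electrical_conductivity: float  # sigma, S/m at 27 MHz
    relative_permittivity: float    # eps_r at 27 MHz
    specific_heat: float         # c, J/kg/K
    thermal_conductivity: float  # k, W/m/K
    perfusion_ml_kg_min: float   # omega, ml blood / kg tissue / min

    def __post_init__(self) -> None:
        for f in ("mass_density", "electrical_conductivity", "specific_heat",
                  "thermal_conductivity", "perfusion_ml_kg_min"):
            if getattr(self, f) < 0:
                raise ValueError(f"{self.name}: {f} must be >= 0")

    @property
    def perfusion_si(self) -> float:
        """Volumetric perfusion in m^3 blood / kg tissue / s (x1e-6 / 60)."""
        return self.perfusion_ml_kg_min * 1e-6 / 60.0


#: Bundled defaults: electric (27 MHz) and thermal properties of the
#: applicator material and the tissues.  Perfusion "-" entries are 0.
TISSUE_PROPERTIES: dict[Tissue, TissueProperties] = {
    Tissue.DIELECTRIC: TissueProperties("Applicator Dielectric", 1289.0, 1e-5, 2.4, 712.0, 0.084, 0.0),
    Tissue.AIR: TissueProperties("Air", 1.164, 0.0, 1.0, 1004.0, 0.0273, 0.0),
    Tissue.MUSCLE: TissueProperties("Muscle", 1090.4, 0.654, 95.8, 3421.0, 0.495, 40.0),
    Tissue.FAT: TissueProperties("Fat", 911.0, 0.061, 17.9, 2348.0, 0.211, 33.0),
    Tissue.BONE: TissueProperties("Bone", 1908.0, 0.052, 21.8, 1313.0, 0.320, 10.0),
    Tissue.PROSTATE: TissueProperties("Prostate", 1045.0, 0.838, 120.1, 3760.0, 0.512, 394.0),
    Tissue.RECTUM: TissueProperties("Rectum", 1045.0, 0.654, 95.8, 3801.0, 0.557, 0.0),
    Tissue.URETHRA: TissueProperties("Urethra", 1102.0, 0.375, 88.8, 3306.0, 0.462, 394.0),
    Tissue.BLADDER: TissueProperties("Bladder", 1086.0, 0.276, 31.5, 3581.0, 0.522, 78.0),
}


@dataclass(frozen=True)
class BloodProperties:
    """Arterial blood parameters of the perfusion sink term."""

    temperature: float = 37.0     # Tb, degC
    mass_density: float = 1050.0  # rho_b, kg/m^3
    specific_heat: float = 3617.0  # c_b, J/kg/K

    def __post_init__(self) -> None:
        if self.mass_density <= 0 or self.specific_heat <= 0:
            raise ValueError("blood density and specific heat must be > 0")


@dataclass(frozen=True)
class ElectrodeSegment:
    """One cylindrical electrode: arc-length interval along the track (mm)."""

    start: float
    end: float

    @property
    def length(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class Applicator:
    """Straight dual-electrode interstitial applicator.

    The track is an ordered pair of world points (tip to hub); each
    applicator carries a distal and a proximal 20 mm electrode with a 5 mm
    inter-electrode gap.
    """

    identifier: str
    track_start: tuple[float, float, float]
    track_end: tuple[float, float, float]
    electrodes: tuple[ElectrodeSegment, ElectrodeSegment]
    coating_thickness: float = 0.0

    def __post_init__(self) -> None:
        a, b = self.electrodes
        lo, hi = (a, b) if a.start <= b.start else (b, a)
        if lo.end > hi.start:
            raise ValueError(f"{self.identifier}: electrode segments overlap")

    @property
    def direction(self) -> np.ndarray:
        d = np.asarray(self.track_end) - np.asarray(self.track_start)
        return d / np.linalg.norm(d)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.asarray(self.track_end) - np.asarray(self.track_start)))

    def point_at(self, arc_length: float) -> np.ndarray:
        return np.asarray(self.track_start) + arc_length * self.direction


class GeometryError(ValueError):
    """Applicator or electrode geometry incompatible with the voxel domain."""


@dataclass(frozen=True)
class VoxelTissueModel:
    """Label grid + property table + blood + implanted applicators."""

    grid: VoxelGrid
    labels: np.ndarray  # integer Tissue labels, shape == grid.shape
    applicators: tuple[Applicator, ...]
    properties: dict[Tissue, TissueProperties] = field(default_factory=lambda: dict(TISSUE_PROPERTIES))
    blood: BloodProperties = field(default_factory=BloodProperties)
    frequency: float = 27e6  # Hz
    catheter_radius: float = 1.0  # mm

    def __post_init__(self) -> None:
        if tuple(self.labels.shape) != tuple(self.grid.shape):
            raise ValueError("label grid shape does not match raster")
        present = set(np.unique(self.labels).tolist())
        known = {int(t) for t in self.properties}
        missing = present - known
        if missing:
            raise KeyError(f"labels without properties: {missing}")

    @property
    def n_electrodes(self) -> int:
        return 2 * len(self.applicators)

    def mask(self, tissue: Tissue) -> np.ndarray:
        return self.labels == int(tissue)

    def organ_volume_cc(self, tissue: Tissue) -> float:
        return float(self.mask(tissue).sum()) * self.grid.voxel_volume_cc


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the synthetic pelvic phantom.

    Defaults give a 128 mm cube at 2 mm resolution (64^3 voxels) holding a
    ~35 cc prostate, with applicators implanted through the perineum
    (parallel to z) on a 5 mm template grid.
    """

    domain_mm: float = 128.0
    spacing_mm: float = 2.0
    prostate_semiaxes: tuple[float, float, float] = (22.0, 19.0, 20.0)  # ~35 cc
    urethra_radius: float = 3.0
    rectum_center_y: float = 34.0
    rectum_outer_radius: float = 12.0
    rectum_lumen_radius: float = 7.0
    bladder_center: tuple[float, float, float] = (0.0, -8.0, 44.0)
    bladder_radius: float = 20.0
    bone_offset_x: float = 48.0
    bone_radius: float = 10.0
    fat_rim_mm: float = 10.0
    n_applicators: int = 16
    template_spacing: float = 5.0
    template_margin: float = 0.9      # fraction of the prostate cross-section used
    urethra_clearance: float = 6.0    # mm, applicators keep clear of the urethra
    jitter_mm: float = 0.5            # seeded placement jitter per needle
    electrode_length: float = 20.0
    electrode_gap: float = 5.0

    def __post_init__(self) -> None:
        if self.spacing_mm >= self.electrode_gap:
            raise ValueError(
                "grid spacing must resolve the inter-electrode gap "
                f"({self.spacing_mm} mm >= {self.electrode_gap} mm)"
            )


def _ellipsoid_mask(axes: tuple[np.ndarray, np.ndarray, np.ndarray],
                    center: tuple[float, float, float],
                    semi: tuple[float, float, float]) -> np.ndarray:
    x, y, z = np.meshgrid(*axes, indexing="ij")
    return (((x - center[0]) / semi[0]) ** 2
            + ((y - center[1]) / semi[1]) ** 2
            + ((z - center[2]) / semi[2]) ** 2) <= 1.0


def _select_template_positions(cfg: PhantomConfig, rng: np.random.Generator) -> np.ndarray:
    """Pick applicator (x, y) positions on the 5 mm template.

    Candidate nodes are template intersections inside the (margin-shrunk)
    prostate mid-gland cross-section, excluding a clearance zone around the
    urethra.  Needles are then spread by greedy farthest-point selection
    starting from the most peripheral node, mimicking the peripheral loading
    of clinical implants, and jittered to emulate placement uncertainty.
    """
    ax, ay = cfg.prostate_semiaxes[0] * cfg.template_margin, cfg.prostate_semiaxes[1] * cfg.template_margin
    half = cfg.domain_mm / 2 - cfg.fat_rim_mm
    n_steps = int(half // cfg.template_spacing)
    ticks = cfg.template_spacing * np.arange(-n_steps, n_steps + 1)
    gx, gy = np.meshgrid(ticks, ticks, indexing="ij")
    cand = np.column_stack([gx.ravel(), gy.ravel()])
    rho = np.sqrt((cand[:, 0] / ax) ** 2 + (cand[:, 1] / ay) ** 2)
    inside = rho <= 1.0
    clear = np.hypot(cand[:, 0], cand[:, 1]) >= cfg.urethra_clearance
    cand, rho = cand[inside & clear], rho[inside & clear]
    if len(cand) < cfg.n_applicators:
        raise GeometryError(
            f"template holds only {len(cand)} usable positions; "
            f"{cfg.n_applicators} applicators requested"
        )
    chosen = [int(np.argmax(rho))]
    for _ in range(cfg.n_applicators - 1):
        d = np.min(
            np.linalg.norm(cand[:, None, :] - cand[chosen][None, :, :], axis=2), axis=1
        )
        d[chosen] = -1.0
        chosen.append(int(np.argmax(d)))
    pos = cand[chosen]
    pos = pos + rng.uniform(-cfg.jitter_mm, cfg.jitter_mm, size=pos.shape)
    return pos


def generate_phantom(config: PhantomConfig | None = None, seed: int = 0) -> VoxelTissueModel:
    """Build the synthetic pelvic phantom; deterministic for fixed (config, seed)."""
    cfg = config or PhantomConfig()
    n = int(round(cfg.domain_mm / cfg.spacing_mm))
    half = cfg.domain_mm / 2
    grid = VoxelGrid(
        shape=(n, n, n),
        spacing=(cfg.spacing_mm,) * 3,
        origin=(-half + cfg.spacing_mm / 2,) * 3,
    )
    axes = grid.coordinate_axes()
    x, y, z = np.meshgrid(*axes, indexing="ij")

    labels = np.full(grid.shape, int(Tissue.MUSCLE), dtype=np.int16)

    rim = (np.abs(x) > half - cfg.fat_rim_mm) | (np.abs(y) > half - cfg.fat_rim_mm)
    labels[rim] = int(Tissue.FAT)

    for sx in (-1.0, 1.0):
        bone = (x - sx * cfg.bone_offset_x) ** 2 + y ** 2 <= cfg.bone_radius ** 2
        labels[bone] = int(Tissue.BONE)

    bladder = _ellipsoid_mask(axes, cfg.bladder_center, (cfg.bladder_radius,) * 3)
    labels[bladder] = int(Tissue.BLADDER)

    rect_wall = (y - cfg.rectum_center_y) ** 2 + x ** 2 <= cfg.rectum_outer_radius ** 2
    rect_lumen = (y - cfg.rectum_center_y) ** 2 + x ** 2 <= cfg.rectum_lumen_radius ** 2
    labels[rect_wall] = int(Tissue.RECTUM)
    labels[rect_lumen] = int(Tissue.AIR)

    prostate = _ellipsoid_mask(axes, (0.0, 0.0, 0.0), cfg.prostate_semiaxes)
    labels[prostate] = int(Tissue.PROSTATE)

    urethra = (x ** 2 + y ** 2 <= cfg.urethra_radius ** 2) & (
        np.abs(z) <= cfg.prostate_semiaxes[2]
    )
    labels[urethra] = int(Tissue.URETHRA)

    rng = np.random.default_rng(seed)
    positions = _select_template_positions(cfg, rng)

    # Electrode pair centered on the prostate mid-gland: distal electrode,
    # 5 mm gap, proximal electrode (total active length 45 mm along z).
    span = cfg.electrode_length + cfg.electrode_gap / 2
    track_lo, track_hi = -half + cfg.spacing_mm, half - cfg.spacing_mm
    applicators = []
    for i, (px, py) in enumerate(positions):
        if abs(px) >= half or abs(py) >= half:
            raise GeometryError(f"applicator {i} placed outside the domain")
        start_arc = -track_lo  # arc length measured from track start at z=track_lo
        applicators.append(
            Applicator(
                identifier=f"A{i:02d}",
                track_start=(float(px), float(py), track_lo),
                track_end=(float(px), float(py), track_hi),
                electrodes=(
                    ElectrodeSegment(start_arc - span, start_arc - cfg.electrode_gap / 2),
                    ElectrodeSegment(start_arc + cfg.electrode_gap / 2, start_arc + span),
                ),
            )
        )

    return VoxelTissueModel(grid=grid, labels=labels, applicators=tuple(applicators))


class ResolutionError(ValueError):
    """Raster too coarse to capture an electrode."""


def rasterize_electrodes(model: VoxelTissueModel) -> list[np.ndarray]:
    """Voxel index sets (flat indices) covered by each electrode cylinder.

    A voxel belongs to an electrode when its center lies within the electrode
    segment along the track and within the capture radius of the axis.  The
    capture radius is the catheter radius widened to half the voxel diagonal
    so that thin electrodes remain representable on coarse grids.

    Returns a list of ``2 * n_applicators`` arrays, ordered (applicator 0
    distal, applicator 0 proximal, applicator 1 distal, ...).
    """
    grid = model.grid
    axes = grid.coordinate_axes()
    pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    capture = max(model.catheter_radius,
                  0.5 * float(np.linalg.norm(grid.spacing)))
    out: list[np.ndarray] = []
    for app in model.applicators:
        p0 = np.asarray(app.track_start, dtype=float)
        d = app.direction
        rel = pts - p0
        arc = rel @ d
        radial = np.linalg.norm(rel - arc[:, None] * d[None, :], axis=1)
        for k, seg in enumerate(app.electrodes):
            sel = (arc >= seg.start) & (arc <= seg.end) & (radial <= capture)
            idx = np.flatnonzero(sel)
            if idx.size == 0:
                raise ResolutionError(
                    f"{app.identifier} electrode {k}: no voxel centers captured "
                    f"(spacing {grid.spacing}, capture radius {capture:.2f} mm)"
                )
            out.append(idx)
    return out


def property_grids(model: VoxelTissueModel) -> dict[str, np.ndarray]:
    """Per-voxel property grids from the label grid.

    Returns ``sigma`` (S/m), ``eps_r``, ``rho`` (kg/m^3), ``c`` (J/kg/K),
    ``k`` (W/m/K) and ``omega`` (volumetric perfusion, m^3/kg/s).
    """
    n_labels = max(int(t) for t in model.properties) + 1
    tables = {key: np.zeros(n_labels) for key in ("sigma", "eps_r", "rho", "c", "k", "omega")}
    for tissue, props in model.properties.items():
        i = int(tissue)
        tables["sigma"][i] = props.electrical_conductivity
        tables["eps_r"][i] = props.relative_permittivity
        tables["rho"][i] = props.mass_density
        tables["c"][i] = props.specific_heat
        tables["k"][i] = props.thermal_conductivity
        tables["omega"][i] = props.perfusion_si
    labels = model.labels.astype(np.intp)
    return {key: tab[labels] for key, tab in tables.items()}


def with_applicator_count(cfg: PhantomConfig, n: int) -> PhantomConfig:
    """Convenience: same phantom with a different implant density."""
    return replace(cfg, n_applicators=n)
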
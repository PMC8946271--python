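"""Temperature-dependent linear-quadratic (TDLQ) radiobiology.

Hyperthermia delivered simultaneously with radiation radiosensitizes
tissue; in the TDLQ model the linear-quadratic coefficients scale
exponentially with temperature between the 37 degC baseline and a
reference temperature Tref (43 degC here):

    alpha(T) = alpha37 * exp( (T-37)/(Tref-37) * ln(alpha(Tref)/alpha37) )

(and likewise for beta), so survival after a simultaneous exposure of
dose D at temperature T for 1 h is S = exp(-alpha(T) D - beta(T) D^2).

The planning quantity is the *equivalent physical dose*: the
radiation-only dose producing the same cell kill, normalized to the
physical dose, which needs only the alpha/beta ratio (3 Gy for all
tissues here) and the two thermal enhancement ratios:

    EQD_phys = [ (a/b) r_a(T) D + r_b(T) D^2 ] / [ (a/b) + D ].

At T = 37 this collapses to D exactly.  Bundled parameter presets follow
in vitro prostate carcinoma data: the thermosensitive PC-3 line
(r_a = 2.4, r_b = 6.8 at 43 degC), the less sensitive DU-145 line
(0.8, 1.8), their arithmetic average (1.6, 4.3), and NONE (no
sensitization, EQD = D at every temperature) used as the optimistic
normal-tissue mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tissue_model import Tissue

__all__ = [
    "TDLQParams",
    "AbsoluteLQParams",
    "PRESETS",
    "thermal_ratio",
    "survival_fraction",
    "eqd_phys",
    "eqd_phys_scalar",
    "average_params",
    "tissue_param_map",
]


@dataclass(frozen=True)
class TDLQParams:
    """Relative thermoradiobiological parameter set for one tissue."""

    alpha_ratio: float          # alpha(Tref)/alpha(37)
    beta_ratio: float           # beta(Tref)/beta(37)
    alpha_beta_37: float = 3.0  # alpha/beta at 37 degC, Gy
    t_ref: float = 43.0         # degC
    protraction: float = 1.0    # Lea-Catcheside G; 1 for an HDR source

    def __post_init__(self) -> None:
        if self.alpha_ratio <= 0 or self.beta_ratio <= 0:
            raise ValueError("thermal enhancement ratios must be > 0")
        if self.alpha_beta_37 <= 0:
            raise ValueError("alpha/beta must be > 0")
        if self.t_ref <= 37.0:
            raise ValueError("Tref must exceed the 37 degC baseline")


PRESETS: dict[str, TDLQParams] = {
    "PC3": TDLQParams(alpha_ratio=2.4, beta_ratio=6.8),
    "DU145": TDLQParams(alpha_ratio=0.8, beta_ratio=1.8),
    "AVG": TDLQParams(alpha_ratio=1.6, beta_ratio=4.3),
    "NONE": TDLQParams(alpha_ratio=1.0, beta_ratio=1.0),
}


@dataclass(frozen=True)
class AbsoluteLQParams:
    """Absolute LQ coefficients at 37 degC (needed only for survival)."""

    alpha37: float  # 1/Gy
    beta37: float   # 1/Gy^2

    def __post_init__(self) -> None:
        if self.alpha37 <= 0 or self.beta37 <= 0:
            raise ValueError("alpha37 and beta37 must be > 0")


def thermal_ratio(T, ratio_at_tref: float, t_ref: float = 43.0):
    """Enhancement factor exp((T-37)/(Tref-37) * ln(ratio)).

    Equals 1 at 37 degC and ``ratio_at_tref`` at Tref; the same exponential
    law extrapolates outside [37, Tref] (the optimizer's 47.5 degC ceiling
    bounds the extrapolation range).
    """
    if ratio_at_tref <= 0:
        raise ValueError("ratio must be > 0")
    T = np.asarray(T, dtype=float)
    return np.exp((T - 37.0) / (t_ref - 37.0) * np.log(ratio_at_tref))


def survival_fraction(D, T, abs_params: AbsoluteLQParams, params: TDLQParams):
    """Surviving fraction S(D, T) for simultaneous dose and heat (1 h)."""
    D = np.asarray(D, dtype=float)
    if np.any(D < 0):
        raise ValueError("dose must be >= 0")
    ra = thermal_ratio(T, params.alpha_ratio, params.t_ref)
    rb = thermal_ratio(T, params.beta_ratio, params.t_ref)
    return np.exp(-abs_params.alpha37 * ra * D
                  - params.protraction * abs_params.beta37 * rb * D ** 2)


def eqd_phys_scalar(D, T, params: TDLQParams):
    """EQD_phys for dose/temperature arrays sharing one parameter set."""
    D = np.asarray(D, dtype=float)
    ab = params.alpha_beta_37
    ra = thermal_ratio(T, params.alpha_ratio, params.t_ref)
    rb = thermal_ratio(T, params.beta_ratio, params.t_ref)
    return (ab * ra * D + params.protraction * rb * D ** 2) / (ab + D)


def eqd_phys(D: np.ndarray, T: np.ndarray,
             tissue_params: dict[Tissue, TDLQParams],
             labels: np.ndarray) -> np.ndarray:
    """Per-voxel EQD_phys grid with tissue-specific parameter sets.

    ``labels`` assigns every voxel a tissue whose entry in
    ``tissue_params`` is applied; tissues mapped to the NONE preset keep
    EQD = D at all temperatures.
    """
    if D.shape != T.shape or D.shape != labels.shape:
        raise ValueError("dose, temperature and label grids must share one raster")
    out = np.empty_like(D, dtype=float)
    done = np.zeros(D.shape, dtype=bool)
    for tissue, params in tissue_params.items():
        m = labels == int(tissue)
        if m.any():
            out[m] = eqd_phys_scalar(D[m], T[m], params)
            done |= m
    if not done.all():
        missing = np.unique(labels[~done])
        raise KeyError(f"no TDLQ parameters for labels {missing.tolist()}")
    return out


def average_params(a: TDLQParams, b: TDLQParams) -> TDLQParams:
    """Arithmetic mean of two parameter sets (same Tref and alpha/beta)."""
    if a.t_ref != b.t_ref:
        raise ValueError("Tref mismatch")
    if a.alpha_beta_37 != b.alpha_beta_37:
        raise ValueError("alpha/beta mismatch")
    return TDLQParams(
        alpha_ratio=(a.alpha_ratio + b.alpha_ratio) / 2,
        beta_ratio=(a.beta_ratio + b.beta_ratio) / 2,
        alpha_beta_37=a.alpha_beta_37,
        t_ref=a.t_ref,
        protraction=(a.protraction + b.protraction) / 2,
    )


def tissue_param_map(tumor: TDLQParams,
                     normal_mode: str = "worst") -> dict[Tissue, TDLQParams]:
    """Assign TDLQ parameters per tissue.

    ``normal_mode='worst'`` gives normal tissue the same sensitization as
    the tumor (worst-case OAR assumption); ``'none'`` assumes no normal
    tissue sensitization (EQD = physical dose in the OARs).
    """
    if normal_mode not in ("worst", "none"):
        raise ValueError("normal_mode must be 'worst' or 'none'")
    normal = tumor if normal_mode == "worst" else PRESETS["NONE"]
    out = {t: normal for t in Tissue}
    out[Tissue.PROSTATE] = tumor
    return out
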
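"""Closed-form transport and fracture models for point-source injection.

A drug solution injected at volumetric rate ``q`` from a needle tip into a
homogeneous porous tissue forms a (near-)spherical depot.  Treating the flow
as quasi-steady Darcy flow from a point source gives the radial velocity
``v(r) = q / (4 pi r^2)`` and, after integrating the pressure gradient, the
needle-tip pressure ``p_t = q / (4 pi k r_t)`` at depot radius ``r_t``.
Combined with the empirical pressure/flow correlation this inverts to the
tissue permeability ``k``.

Volume balance of the injection region gives the cube-root wetting-front law
``WF(t) = (3 q t / (4 pi eps))^(1/3)`` and its normalized form
``R(t) = (q t / Q)^(1/3)``, which is fitted to measured traces here.

Pressurized injection can open micro-crack networks; the energy release rate
of a tunnelling crack of width ``h`` in tissue of Young's modulus ``E`` under
pressure ``P`` is ``J = P^2 h / (1.27 E)``, compared against the tissue
threshold ``J_a``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from . import constants as C

__all__ = [
    "InjectionProtocol",
    "TissueParameters",
    "PermeabilityEstimate",
    "FitResult",
    "FractureAssessment",
    "injection_pressure",
    "tissue_resistance_pressure",
    "radial_velocity",
    "permeability_darcy",
    "permeability_correlation",
    "wf_spherical",
    "normalized_wf",
    "fit_normalized_wf",
    "fracture_toughness",
    "youngs_modulus_from_fracture",
    "assess_fracture",
]


# --------------------------------------------------------------------------- #
# domain types
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class InjectionProtocol:
    """Injection settings for one experiment.

    Parameters
    ----------
    flow_rate_ul_min : float
        Volumetric infusion rate q [uL/min].
    total_volume_ul : float
        Total injected bolus Q [uL].
    mode : {"single_shot", "continuous"}
        Syringe-pump bolus vs long-term pump infusion.
    needle_tip : (int, int)
        Needle-tip position in image coordinates (row, col) [pixels].
    frame_interval_s : float
        Nominal time between radiograph frames [s].
    """

    flow_rate_ul_min: float
    total_volume_ul: float
    mode: Literal["single_shot", "continuous"] = "continuous"
    needle_tip: tuple[int, int] = (0, 0)
    frame_interval_s: float = 1.0

    def __post_init__(self) -> None:
        if self.flow_rate_ul_min <= 0:
            raise ValueError("flow_rate must be positive")
        if self.total_volume_ul <= 0:
            raise ValueError("total_volume must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def duration_s(self) -> float:
        """Infusion duration T = Q/q [s]."""
        return self.total_volume_ul / self.flow_rate_ul_min * 60.0


@dataclass(frozen=True)
class TissueParameters:
    """Material and model parameters of the target tissue."""

    epsilon: float = C.DEFAULT_EPSILON
    anisotropy: float = 1.0  # vertical / horizontal depot semi-axis ratio
    crack_width_um: float = C.DEFAULT_CRACK_WIDTH_UM
    youngs_modulus_kpa: float = C.DEFAULT_YOUNGS_MODULUS_KPA
    fracture_threshold_kj_m2: float = C.DEFAULT_JA_KJ_M2
    lag_volume_ul: float = 0.0
    mu_abs_per_mm: float = C.DEFAULT_MU_ABS_PER_MM

    def __post_init__(self) -> None:
        if not 0 < self.epsilon <= 1:
            raise ValueError("epsilon must lie in (0, 1]")
        if self.anisotropy <= 0:
            raise ValueError("anisotropy must be positive")
        for name in ("crack_width_um", "youngs_modulus_kpa", "fracture_threshold_kj_m2", "mu_abs_per_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.lag_volume_ul < 0:
            raise ValueError("lag_volume must be nonnegative")


@dataclass(frozen=True)
class PermeabilityEstimate:
    """Darcy permeability per direction with the inputs used to derive it."""

    k_horizontal: float  # [m^4/(N s)]
    k_vertical: float  # [m^4/(N s)]
    pressure_kpa: float  # applied pressure p_t at the depot surface
    radius_used_m: float  # depot radius r_t entering the estimate
    flow_rate_ul_min: float

    def __post_init__(self) -> None:
        if self.k_horizontal <= 0 or self.k_vertical <= 0:
            raise ValueError("permeability values must be positive")
        if self.radius_used_m <= 0:
            raise ValueError("radius_used must be positive")


@dataclass(frozen=True)
class FitResult:
    """Result of fitting a wetting-front trace to the cube-root growth law."""

    wf_max_m: float
    r_squared: float
    residuals_m: tuple[float, ...] = field(default=())
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.r_squared > 1 + 1e-12:
            raise ValueError("R^2 cannot exceed 1")


@dataclass(frozen=True)
class FractureAssessment:
    """Energy release rate J and the resulting fracture regime."""

    J_j_m2: float
    regime: Literal["no_fracture", "fracture"]

    def __post_init__(self) -> None:
        if self.J_j_m2 < 0:
            raise ValueError("J must be nonnegative")


# --------------------------------------------------------------------------- #
# pressure correlations
# --------------------------------------------------------------------------- #


def injection_pressure(q_ul_s: float) -> float:
    """Pressure applied to the tissue at infusion rate ``q`` [uL/s], in kPa.

    Empirical linear correlation ``p = 0.74 q + 23`` with q in uL/s; at
    25 uL/min (0.4167 uL/s) it gives 23.3 kPa.
    """
    if q_ul_s < 0:
        raise ValueError("flow rate must be nonnegative")
    return C.PRESSURE_FLOW_SLOPE_KPA_PER_UL_S * q_ul_s + C.PRESSURE_FLOW_INTERCEPT_KPA


def tissue_resistance_pressure(q_ml_min: float) -> float:
    """Tissue resistance pressure (TRP) at infusion rate ``q`` [mL/min], in kPa.

    Empirical correlation ``TRP = 10.4 q + 1.14`` with q in mL/min; the
    back-pressure an injection device must overcome before solution enters
    the tissue.
    """
    if q_ml_min < 0:
        raise ValueError("flow rate must be nonnegative")
    return C.TRP_SLOPE_KPA_PER_ML_MIN * q_ml_min + C.TRP_INTERCEPT_KPA


# --------------------------------------------------------------------------- #
# Darcy point source
# --------------------------------------------------------------------------- #


def radial_velocity(q_m3_s: float, r_m: float) -> float:
    """Radial Darcy velocity v(r) = q / (4 pi r^2) [m/s] for SI inputs."""
    if r_m <= 0:
        raise ValueError("radius must be positive")
    return q_m3_s / (4.0 * math.pi * r_m**2)


def permeability_darcy(q_ul_min: float, r_t_m: float, p_kpa: float) -> float:
    """Darcy permeability k = q / (4 pi p r_t) [m^4/(N s)].

    Parameters are given in laboratory units (q in uL/min, p in kPa, r_t in m)
    and converted to SI internally.  Equivalent to the closed-form
    :func:`permeability_correlation` whenever ``p`` comes from
    :func:`injection_pressure`.
    """
    if q_ul_min <= 0 or r_t_m <= 0 or p_kpa <= 0:
        raise ValueError("flow, radius and pressure must all be positive")
    q_si = q_ul_min * C.UL_PER_MIN_TO_M3_PER_S
    p_si = p_kpa * C.KPA_TO_PA
    return q_si / (4.0 * math.pi * p_si * r_t_m)


def permeability_correlation(q_ul_min: float, r_t_m: float) -> float:
    """Permeability via the folded correlation k = q / (2.96 pi r_t (q + 31.08)).

    ``q`` enters the bracket in uL/s (the unit of the pressure correlation);
    the leading conversion restores SI output.  Provided as the closed form
    obtained by substituting the pressure correlation into the Darcy estimate.
    """
    if q_ul_min <= 0 or r_t_m <= 0:
        raise ValueError("flow and radius must be positive")
    q_ul_s = q_ul_min / 60.0
    # uL/s / kPa / m -> m^4/(N s) carries a factor 1e-9 / 1e3.
    scale = C.UL_PER_S_TO_M3_PER_S / C.KPA_TO_PA
    return scale / (C.PERMEABILITY_FORM_FACTOR * r_t_m) * (
        q_ul_s / (q_ul_s + C.PERMEABILITY_FLOW_OFFSET_UL_S)
    )


def estimate_permeability(
    q_ul_min: float,
    r_h_m: float,
    r_v_m: float,
    p_kpa: float | None = None,
) -> PermeabilityEstimate:
    """Directional permeability estimate from final wetting-front radii.

    If ``p_kpa`` is omitted the pressure correlation at ``q`` is used.
    """
    if p_kpa is None:
        p_kpa = injection_pressure(q_ul_min / 60.0)
    return PermeabilityEstimate(
        k_horizontal=permeability_darcy(q_ul_min, r_h_m, p_kpa),
        k_vertical=permeability_darcy(q_ul_min, r_v_m, p_kpa),
        pressure_kpa=p_kpa,
        radius_used_m=max(r_h_m, r_v_m),
        flow_rate_ul_min=q_ul_min,
    )


# --------------------------------------------------------------------------- #
# spherical depot growth
# --------------------------------------------------------------------------- #


def wf_spherical(q_ul_min: float, t_s: float, epsilon: float = C.DEFAULT_EPSILON) -> float:
    """Wetting-front radius [m] of a spherical depot after time ``t``.

    Volume balance ``eps * (4/3) pi WF^3 = q t`` gives the cube-root law
    ``WF(t) = (3 q t / (4 pi eps))^(1/3)``.
    """
    if not 0 < epsilon <= 1:
        raise ValueError("epsilon must lie in (0, 1]")
    if t_s < 0:
        raise ValueError("time must be nonnegative")
    vol_m3 = q_ul_min * C.UL_PER_MIN_TO_M3_PER_S * t_s
    return (3.0 * vol_m3 / (4.0 * math.pi * epsilon)) ** (1.0 / 3.0)


def normalized_wf(q_ul_min: float, t_s: float, total_volume_ul: float) -> float:
    """Normalized wetting front R(t) = WF(t)/WF_m = (q t / Q)^(1/3).

    Independent of epsilon; equals 1 at the end of infusion t = Q/q.
    """
    if total_volume_ul <= 0:
        raise ValueError("total volume must be positive")
    qt_ul = q_ul_min / 60.0 * t_s
    if qt_ul < 0:
        raise ValueError("q*t must be nonnegative")
    return (qt_ul / total_volume_ul) ** (1.0 / 3.0)


def fit_normalized_wf(
    times_s: Sequence[float],
    wf_m: Sequence[float],
    protocol: InjectionProtocol,
) -> FitResult:
    """Fit a measured injection-region WF trace to the cube-root law.

    The model ``WF(t) = WF_max * (q t / Q)^(1/3)`` is linear in the single
    free amplitude ``WF_max``, which is found by least squares on the WF
    values; R^2 is then computed on the normalized trace ``WF/WF_max``
    against ``R(t)``.

    Parameters
    ----------
    times_s, wf_m : sequences
        Sample times [s] and wetting-front distances [m], restricted to the
        injection region.  At least 3 samples with strictly increasing times.
    protocol : InjectionProtocol
        Supplies q and Q.
    """
    t = np.asarray(times_s, dtype=float)
    w = np.asarray(wf_m, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 injection-region samples")
    if t.size != w.size:
        raise ValueError("times and WF values must have equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")

    degenerate = False
    if np.all(np.diff(w) <= 0) or np.ptp(w) == 0:
        degenerate = True
        warnings.warn("WF trace is constant or decreasing; fit is degenerate", stacklevel=2)

    x = np.array([
        normalized_wf(protocol.flow_rate_ul_min, ti, protocol.total_volume_ul) for ti in t
    ])
    denom = float(np.dot(x, x))
    if denom == 0:
        raise ValueError("all model values are zero; cannot fit amplitude")
    wf_max = float(np.dot(x, w) / denom)
    if wf_max <= 0:
        degenerate = True
        warnings.warn("fitted WF_max is non-positive", stacklevel=2)
        wf_max = max(wf_max, np.finfo(float).tiny)

    r_meas = w / wf_max
    ss_res = float(np.sum((r_meas - x) ** 2))
    ss_tot = float(np.sum((r_meas - r_meas.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    residuals = tuple((w - wf_max * x).tolist())
    return FitResult(wf_max_m=wf_max, r_squared=min(r2, 1.0), residuals_m=residuals, degenerate=degenerate)


# --------------------------------------------------------------------------- #
# fracture mechanics
# --------------------------------------------------------------------------- #


def fracture_toughness(p_kpa: float, h_um: float, e_kpa: float) -> float:
    """Energy release rate J = P^2 h / (1.27 E) [J/m^2] of a tunnelling crack."""
    if p_kpa <= 0 or h_um <= 0 or e_kpa <= 0:
        raise ValueError("pressure, crack width and modulus must be positive")
    p = p_kpa * C.KPA_TO_PA
    h = h_um * C.UM_TO_M
    e = e_kpa * C.KPA_TO_PA
    return p**2 * h / (C.FRACTURE_GEOMETRY_FACTOR * e)


def youngs_modulus_from_fracture(p_kpa: float, j_j_m2: float, h_um: float) -> float:
    """Young's modulus [kPa] consistent with one (P, J) pair at crack width h."""
    if p_kpa <= 0 or j_j_m2 <= 0 or h_um <= 0:
        raise ValueError("inputs must be positive")
    p = p_kpa * C.KPA_TO_PA
    h = h_um * C.UM_TO_M
    return p**2 * h / (C.FRACTURE_GEOMETRY_FACTOR * j_j_m2) / C.KPA_TO_PA


def assess_fracture(j_j_m2: float, j_a_j_m2: float) -> FractureAssessment:
    """Compare J against the tissue threshold J_a (fracture iff J >= J_a)."""
    if j_j_m2 < 0 or j_a_j_m2 < 0:
        raise ValueError("J and J_a must be nonnegative")
    regime = "fracture" if j_j_m2 >= j_a_j_m2 else "no_fracture"
    return FractureAssessment(J_j_m2=j_j_m2, regime=regime)
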
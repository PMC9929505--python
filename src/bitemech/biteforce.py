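"""Forward bite-force model, sensor corrections, and minimal models.

The forward model composes the lever mechanics (:mod:`bitemech.geometry`)
with the muscle kinematics and physiology (:mod:`bitemech.muscle`):

    |F_b|(theta) = sigma(theta) * A_phys * cos(phi(theta)) * MA(theta)

evaluated per fibre population (stress and pennation differ between direct
and filament-attached fibres) with the physiological cross-section
partitioned by number fraction.  Sensor relations convert one-dimensional
force-transducer readings into bite-force magnitudes, and the minimal
model predicts an upper bound on peak bite force from head dimensions and
sarcomere length alone.

Units: forces N, stresses MPa internally, lengths mm, sarcomere lengths
micrometres; all conversions are centralized here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from .geometry import JointFrame, LeverSet, apodeme_displacement, effective_levers
from .muscle import (
    ForceLengthParams,
    MuscleArchitecture,
    fibre_length,
    pennation_angle,
    physiological_cross_section,
    stress,
)

__all__ = [
    "BiteApparatus",
    "BiteMeasurement",
    "MinimalModelInputs",
    "bite_force",
    "measured_to_bite",
    "stimulated_rescale",
    "minimal_max_force",
    "stress_proxy_kpa",
    "allometric_bound",
    "SARCOMERE_STRESS_SLOPE_KPA_PER_UM",
]

# Stress-per-sarcomere-length proxy (kPa per micrometre), valid for
# sarcomere lengths of 3-17 um: sigma_max ~= 50 * S_l kPa.
SARCOMERE_STRESS_SLOPE_KPA_PER_UM = 50.0
_SL_RANGE_UM = (3.0, 17.0)

# Minimal-model first-order constants: intermediate mechanical advantage,
# cos(pennation) ~ 1, and A_phys ~ 0.3 H_w H_l from head dimensions.
_MA_TYPICAL = 0.55
_COS_PHI_TYPICAL = 1.0
_APHYS_HEAD_FRACTION = 0.3


@dataclass(frozen=True)
class BiteApparatus:
    """Complete description of one head side, sufficient to predict force.

    Parameters
    ----------
    frame : JointFrame
    levers : LeverSet
    muscle : MuscleArchitecture
    physiology : ForceLengthParams
        Force-length parameters of the *reference* population (the one
        with the largest number fraction; in mixed muscles typically the
        filament-attached fibres).  Other populations share sigma_max and
        beta; their optimal length is tied by the equivalent-stretch rule
        ``l_opt_pop = l_opt * fibre_length0_pop / fibre_length0_ref``.
    theta_range : (float, float)
        Admissible opening-angle range in degrees (defaults to the
        morphologically scanned range 35-105 deg).
    pooled_a_phys : bool
        If True (default) the physiological cross-section is a single
        pooled area partitioned across populations by number fraction; if
        False each population's area is computed from its own share of the
        muscle volume and its own optimal length.
    """

    frame: JointFrame
    levers: LeverSet
    muscle: MuscleArchitecture
    physiology: ForceLengthParams
    theta_range: tuple[float, float] = (35.0, 105.0)
    pooled_a_phys: bool = True

    @property
    def a_phys(self) -> float:
        """Pooled physiological cross-section V_m / l_opt (mm^2)."""
        return physiological_cross_section(self.muscle.volume, self.physiology.l_opt)

    def population_l_opt(self, pop) -> float:
        """Optimal length of ``pop``, tied by equivalent stretch (mm)."""
        ref = self.muscle.reference_population
        return self.physiology.l_opt * pop.fibre_length0 / ref.fibre_length0

    def with_physiology(self, physiology: ForceLengthParams) -> "BiteApparatus":
        """Same apparatus with different force-length parameters."""
        return replace(self, physiology=physiology)

    def _check_theta(self, theta):
        theta = np.asarray(theta, dtype=float)
        lo, hi = self.theta_range
        if np.any(theta < lo) or np.any(theta > hi):
            raise ValueError(
                f"opening angle outside the admissible range "
                f"[{lo}, {hi}] deg"
            )
        return theta

    def terms(self, theta) -> dict:
        """Per-term breakdown of the forward model at ``theta`` (degrees).

        Returns a dict with keys ``ma``, ``delta_mm`` and, per population
        ``i``, ``cos_phi_i``, ``sigma_MPa_i``, ``fibre_length_i`` and
        ``a_phys_i``; plus aggregate ``cos_phi`` and ``sigma_MPa``
        (area-weighted means) and ``force_N``.
        """
        theta = self._check_theta(theta)
        _, _, ma = effective_levers(theta, self.levers, self.frame)
        delta, _, _ = apodeme_displacement(theta, self.levers, self.frame)
        out = {"ma": ma, "delta_mm": delta}
        apodeme_force = 0.0  # MPa * mm^2 = N
        wsum_cos = 0.0
        wsum_sig = 0.0
        for i, pop in enumerate(self.muscle.populations):
            if self.pooled_a_phys:
                a_i = self.a_phys * pop.number_fraction
            else:
                a_i = physiological_cross_section(
                    self.muscle.volume * pop.number_fraction,
                    self.population_l_opt(pop),
                )
            params_i = replace(self.physiology, l_opt=self.population_l_opt(pop))
            L_i = fibre_length(delta, pop)
            phi_i = pennation_angle(delta, pop.phi0, pop.total_length0)
            sig_i = stress(L_i, params_i)
            cos_i = np.cos(np.radians(phi_i))
            out[f"fibre_length_{i}"] = L_i
            out[f"cos_phi_{i}"] = cos_i
            out[f"sigma_MPa_{i}"] = sig_i
            out[f"a_phys_{i}"] = a_i
            apodeme_force = apodeme_force + sig_i * a_i * cos_i
            wsum_cos = wsum_cos + a_i * cos_i
            wsum_sig = wsum_sig + a_i * sig_i
        a_total = sum(out[f"a_phys_{i}"] for i in range(len(self.muscle.populations)))
        out["cos_phi"] = wsum_cos / a_total
        out["sigma_MPa"] = wsum_sig / a_total
        out["force_N"] = apodeme_force * ma
        return out

    def bite_force(self, theta):
        """Bite force magnitude (N) at opening angle ``theta`` (degrees).

        Vectorized over ``theta``; raises ValueError outside the
        admissible range.
        """
        return self.terms(theta)["force_N"]


def bite_force(theta, apparatus: BiteApparatus):
    """Functional alias for :meth:`BiteApparatus.bite_force`."""
    return apparatus.bite_force(theta)


@dataclass(frozen=True)
class BiteMeasurement:
    """One in-vivo bite-force observation and its correction geometry.

    ``outlever`` and ``sensor_axis`` are expressed in the same (head-fixed)
    coordinate system as the joint frame used for correction.  The plate
    moment arms encode where the mandible touched the bite plate relative
    to the lever geometry used during sensor calibration.
    """

    theta: float
    force_measured: float
    outlever: np.ndarray = field(default_factory=lambda: np.array([0.0, -1.0, 0.0]))
    sensor_axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    plate_moment_cal: float = 1.0
    plate_moment_bite: float = 1.0
    contact: Literal["distal", "other"] = "distal"

    def __post_init__(self):
        object.__setattr__(self, "outlever", np.asarray(self.outlever, float))
        axis = np.asarray(self.sensor_axis, float)
        n = np.linalg.norm(axis)
        if n == 0:
            raise ValueError("sensor_axis must be non-zero")
        object.__setattr__(self, "sensor_axis", axis / n)
        if self.force_measured < 0:
            raise ValueError("force_measured must be non-negative")
        if self.plate_moment_cal <= 0 or self.plate_moment_bite <= 0:
            raise ValueError("plate moment arms must be positive")

    @property
    def gamma_correction(self) -> float:
        """Moment-arm correction Gamma = L_p,cal / L_p,b."""
        return self.plate_moment_cal / self.plate_moment_bite


def measured_to_bite(
    meas: BiteMeasurement, frame: JointFrame, cos_alpha_floor: float = 0.2
) -> float:
    """Bite-force magnitude (N) from a one-dimensional sensor reading.

    The bite force is directed along ``L_o x R̂`` (perpendicular to both
    outlever and rotation axis); the sensor reads its projection onto the
    sensitive axis.  The reading is therefore divided by ``cos(alpha)``,
    with ``alpha`` the angle between sensor axis and bite-force direction,
    and multiplied by the plate moment-arm correction Gamma.

    Raises
    ------
    ValueError
        If ``cos(alpha) <= cos_alpha_floor`` (near-perpendicular sensor:
        the measurement is unusable because the projection correction
        would blow up).
    """
    direction = np.cross(meas.outlever, frame.axis)
    norm = np.linalg.norm(direction)
    if norm < 1e-12:
        raise ValueError("outlever is parallel to the rotation axis")
    cos_alpha = abs(float(direction @ meas.sensor_axis)) / norm
    if cos_alpha <= cos_alpha_floor:
        raise ValueError(
            f"sensor nearly perpendicular to the bite force: cos(alpha) = "
            f"{cos_alpha:.3f} <= floor {cos_alpha_floor} - measurement unusable"
        )
    return meas.gamma_correction * meas.force_measured / cos_alpha


def stimulated_rescale(
    force: float, outlever_contact_eff: float, outlever_distal_eff: float
) -> float:
    """Rescale a non-distal (e.g. stimulated) bite to the distal tooth tip.

    ``|F_b,s| = |F_b| * |L_o,c,eff| / |L_o,d,eff|``: torque about the joint
    is what the muscle controls, so force scales inversely with the
    effective outlever at the actual contact point.
    """
    if outlever_contact_eff <= 0 or outlever_distal_eff <= 0:
        raise ValueError("effective outlevers must be positive")
    return force * outlever_contact_eff / outlever_distal_eff


@dataclass(frozen=True)
class MinimalModelInputs:
    """Inputs of the minimal bite-force model.

    Head width/length/height in mm, sarcomere length in micrometres
    (valid range 3-17 um for the stress proxy), body mass in kg.
    """

    head_width: float
    head_length: float
    head_height: float
    sarcomere_length: float
    body_mass: float

    def __post_init__(self):
        for name in ("head_width", "head_length", "head_height", "body_mass"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = _SL_RANGE_UM
        if not lo <= self.sarcomere_length <= hi:
            raise ValueError(
                f"sarcomere_length = {self.sarcomere_length} um outside the "
                f"stress proxy's validity range [{lo}, {hi}] um"
            )


def stress_proxy_kpa(sarcomere_length_um: float) -> float:
    """Peak-stress proxy sigma_max ~= 50 * S_l (kPa), valid for 3-17 um."""
    lo, hi = _SL_RANGE_UM
    if not lo <= sarcomere_length_um <= hi:
        raise ValueError(
            f"sarcomere_length = {sarcomere_length_um} um outside the stress "
            f"proxy's validity range [{lo}, {hi}] um"
        )
    return SARCOMERE_STRESS_SLOPE_KPA_PER_UM * sarcomere_length_um


def minimal_max_force(inputs: MinimalModelInputs) -> float:
    """Upper-bound peak bite force (N) from head dimensions and sarcomere length.

    ``F_max = MA * cos(phi) * A_phys * sigma_max(S_l)`` with the first-order
    constants MA = 0.55, cos(phi) = 1, A_phys = 0.3 H_w H_l and the
    sarcomere stress proxy 50 S_l kPa; the combined prefactor is
    8.25 kPa/um.  Head dimensions in mm, result in newtons.
    """
    sigma_pa = stress_proxy_kpa(inputs.sarcomere_length) * 1e3
    a_phys_m2 = _APHYS_HEAD_FRACTION * inputs.head_width * inputs.head_length * 1e-6
    return _MA_TYPICAL * _COS_PHI_TYPICAL * a_phys_m2 * sigma_pa


def allometric_bound(mass_kg: float, coefficient: float = 20.0) -> float:
    """Allometric upper bound on weight-specific force: c * m^(-1/3).

    With ``coefficient = 20`` this is the classical bound on the maximum
    force exerted during any activity, normalized by body weight; with
    ``coefficient = 50`` the analogous bound for weight-specific *muscle*
    force.  ``mass_kg`` in kilograms; the result is dimensionless
    (force / body weight).
    """
    if mass_kg <= 0:
        raise ValueError("mass must be positive")
    return coefficient * mass_kg ** (-1.0 / 3.0)
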
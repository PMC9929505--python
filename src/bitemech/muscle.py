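"""Muscle architecture and physiology.

Fibres run from the head capsule to the apodeme, either inserting directly
or through a thin, effectively inextensible cuticular filament.  As the
apodeme displaces by ``delta`` along its main axis, the fibre-plus-filament
triangle deforms with its height above the apodeme axis conserved: this
single constraint yields both the pennation-angle kinematics and the
fibre-length kinematics below.  Stress follows a Gaussian force-length
curve with peak ``sigma_max`` at the optimal fibre length ``l_opt`` and
width controlled by the shape parameter ``beta``.

Units: lengths mm, stresses MPa, angles degrees at interfaces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "FibrePopulation",
    "ForceLengthParams",
    "MuscleArchitecture",
    "pennation_angle",
    "fibre_length",
    "stress",
    "physiological_cross_section",
]


@dataclass(frozen=True)
class FibrePopulation:
    """One homogeneous fibre population of a pennate muscle.

    Parameters
    ----------
    phi0 : float
        Reference pennation angle (degrees, in [0, 90)), measured against
        the apodeme main axis at the reference pose.
    fibre_length0 : float
        Reference fibre length (mm, > 0): ``L_d,0`` for direct attachment,
        ``L_f,0`` for filament attachment.
    filament_length : float
        Filament length ``L_fil`` (mm, >= 0); 0 means direct attachment.
        Treated as strictly constant (filament strain is < 2 % across the
        opening range, so elasticity is neglected).
    number_fraction : float
        Share of fibres in this population (0-1; fractions sum to 1 across
        a muscle).
    """

    phi0: float
    fibre_length0: float
    filament_length: float = 0.0
    number_fraction: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.phi0 < 90.0:
            raise ValueError(f"phi0 must lie in [0, 90) deg, got {self.phi0}")
        if self.fibre_length0 <= 0:
            raise ValueError("fibre_length0 must be positive")
        if self.filament_length < 0:
            raise ValueError("filament_length must be non-negative")
        if not 0.0 <= self.number_fraction <= 1.0:
            raise ValueError("number_fraction must lie in [0, 1]")

    @property
    def total_length0(self) -> float:
        """Reference origin-to-insertion distance ``L_t,0`` (mm)."""
        return self.fibre_length0 + self.filament_length

    @property
    def is_direct(self) -> bool:
        return self.filament_length == 0.0


@dataclass(frozen=True)
class ForceLengthParams:
    """Gaussian force-length physiology: (sigma_max [MPa], l_opt [mm], beta)."""

    sigma_max: float
    l_opt: float
    beta: float

    def __post_init__(self):
        if self.sigma_max <= 0:
            raise ValueError("sigma_max must be positive")
        if self.l_opt <= 0:
            raise ValueError("l_opt must be positive")
        if self.beta <= 0:
            raise ValueError("beta must be positive")


@dataclass(frozen=True)
class MuscleArchitecture:
    """Volume and fibre populations of one mandible closer muscle.

    The physiological cross-section ``A_phys = volume / l_opt`` is *not*
    stored: it depends on the optimal fibre length carried by
    :class:`ForceLengthParams` and is computed where both are in scope
    (see :meth:`bitemech.biteforce.BiteApparatus.a_phys`), so the defining
    relation holds by construction.
    """

    volume: float
    populations: tuple[FibrePopulation, ...]

    def __init__(self, volume: float, populations: Sequence[FibrePopulation]):
        if volume <= 0:
            raise ValueError("muscle volume must be positive")
        pops = tuple(populations)
        if not pops:
            raise ValueError("at least one fibre population is required")
        total = sum(p.number_fraction for p in pops)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(
                f"population number fractions must sum to 1, got {total:.6g}"
            )
        object.__setattr__(self, "volume", float(volume))
        object.__setattr__(self, "populations", pops)

    @property
    def reference_population(self) -> FibrePopulation:
        """The population with the largest number fraction.

        Its reference fibre length anchors the 'equivalent stretch' scaling
        of per-population optimal lengths and the A_phys definition.
        """
        return max(self.populations, key=lambda p: p.number_fraction)


def pennation_angle(delta, phi0: float, total_length0: float):
    """Pennation angle (degrees) after an apodeme displacement ``delta`` (mm).

    ``phi = arctan( sin(phi0) / (cos(phi0) - delta / L_t,0) )``, evaluated
    with ``atan2`` so the angle continues smoothly past 90 deg when the
    denominator becomes negative (fibre tilted beyond perpendicular).  This
    branch choice is exactly the one that conserves the fibre-triangle
    height ``L_t sin(phi)``.

    Vectorized over ``delta``.
    """
    if total_length0 <= 0:
        raise ValueError("total_length0 must be positive")
    delta = np.asarray(delta, dtype=float)
    p0 = np.radians(phi0)
    s, c = np.sin(p0), np.cos(p0)
    denom = c - delta / total_length0
    if s == 0.0 and np.any(np.abs(denom) < 1e-12):
        raise ValueError(
            "fibre orientation undefined: phi0 = 0 and the fibre end point "
            "coincides with the origin (denominator of the pennation "
            "relation vanished)"
        )
    phi = np.degrees(np.arctan2(s, denom))
    return phi if phi.ndim else float(phi)


def fibre_length(delta, pop: FibrePopulation):
    """Fibre length (mm) after an apodeme displacement ``delta`` (mm).

    For a directly attached fibre (``filament_length == 0``) this is the
    planar triangle relation

    ``L_d = sqrt( (cos(phi0) L_d,0 - delta)^2 + (sin(phi0) L_d,0)^2 )``;

    for filament attachment the same relation applies to the total length
    ``L_t,0 = L_f,0 + L_fil`` and the constant filament length is
    subtracted from the result.  Vectorized over ``delta``.

    Raises
    ------
    ValueError
        If the resulting fibre length is not positive (displacement beyond
        the physically admissible range).
    """
    delta = np.asarray(delta, dtype=float)
    lt0 = pop.total_length0
    p0 = np.radians(pop.phi0)
    total = np.hypot(np.cos(p0) * lt0 - delta, np.sin(p0) * lt0)
    length = total - pop.filament_length
    if np.any(length <= 0):
        raise ValueError(
            "non-physical fibre length <= 0 mm: apodeme displacement "
            "exceeds the admissible range for this population"
        )
    return length if length.ndim else float(length)


def stress(fibre_len, params: ForceLengthParams):
    """Active muscle stress (MPa) at fibre length ``fibre_len`` (mm).

    Gaussian force-length curve ``sigma_max * exp(-beta (1 - L/L_opt)^2)``:
    positive everywhere, equal to ``sigma_max`` iff ``L == l_opt`` and
    symmetric in the relative deviation ``1 - L/L_opt``.
    """
    L = np.asarray(fibre_len, dtype=float)
    if np.any(L <= 0):
        raise ValueError("fibre length must be positive")
    out = params.sigma_max * np.exp(-params.beta * (1.0 - L / params.l_opt) ** 2)
    return out if out.ndim else float(out)


def physiological_cross_section(volume: float, l_opt: float) -> float:
    """Physiological cross-sectional area A_phys = volume / l_opt (mm^2).

    Defined at the optimal fibre length so the area is strain-invariant and
    comparable across muscles whose relaxed lengths sit at different points
    of the force-length curve.
    """
    if volume <= 0 or l_opt <= 0:
        raise ValueError("volume and l_opt must both be positive")
    return volume / l_opt
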
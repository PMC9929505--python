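"""Lever-arm and joint kinematics of a hinged mandible.

The mandible is modelled as a rigid body rotating about a single fixed axis
R̂ through a joint centre.  Muscle force arrives through the apodeme (the
insect analogue of a tendon) whose main axis Â stays fixed in the head while
the inlever L_i rotates with the mandible.  All lever arms are therefore
projections onto the plane of rotation, computed as rejection lengths
|R̂ × v|.

Conventions
-----------
* Angles are degrees at every public interface, radians internally.
* Lengths are millimetres; coordinates are right-handed with the origin at
  the joint centre unless stated otherwise.
* The opening angle ``theta`` is measured between the lateral head axis and
  the projected (distal) outlever; the apodeme angle ``gamma`` between the
  projected inlever and the projected apodeme axis.  They are linked by the
  linear relation ``gamma(theta) = theta0 - theta + gamma0`` where
  ``gamma0`` is measured at the reference opening angle ``theta0``.
* The rotation-axis sign is fixed so that its dot product with the
  dorso-ventral head axis is non-negative (see :func:`orient_axis`),
  making ``gamma`` and ``theta`` single-valued.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEGENERATE_TOL",
    "JointFrame",
    "LeverSet",
    "apodeme_angle",
    "effective_levers",
    "apodeme_displacement",
    "gape",
    "orient_axis",
    "rejection_norm",
]

#: Projections shorter than this (mm) are treated as geometrically degenerate.
DEGENERATE_TOL = 1e-9

_UNIT_TOL = 1e-9


def _as_vec3(v, name: str) -> np.ndarray:
    a = np.asarray(v, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"{name} must be a 3-vector, got shape {a.shape}")
    return a


def _check_unit(v: np.ndarray, name: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if abs(n - 1.0) > 1e-6:
        raise ValueError(f"{name} must be a unit vector (|{name}| = {n:.3g})")
    return v / n  # renormalize residual float error down to ~1e-16


def rejection_norm(axis: np.ndarray, v: np.ndarray) -> float:
    """Length of the rejection of ``v`` from the unit ``axis``, |axis x v|.

    Equals the shortest distance between the tip of ``v`` (rooted on the
    axis) and the axis line, i.e. the projected length in the rotation
    plane.
    """
    return float(np.linalg.norm(np.cross(axis, v)))


def orient_axis(axis, dorsoventral=(0.0, 0.0, 1.0)) -> np.ndarray:
    """Fix the sign of a rotation axis against the dorso-ventral head axis.

    Returns ``axis`` flipped if needed so that ``axis . dorsoventral >= 0``.
    """
    a = _check_unit(_as_vec3(axis, "axis"), "axis")
    d = _as_vec3(dorsoventral, "dorsoventral")
    return -a if float(a @ d) < 0.0 else a


@dataclass(frozen=True)
class JointFrame:
    """A mandible joint: reference point on the rotation axis plus the axis.

    Parameters
    ----------
    centre : (3,) array_like
        Reference point on the rotational axis, mm.  The choice of point
        along the axis does not affect any lever computation.
    axis : (3,) array_like
        Unit rotation axis R̂ (sign per :func:`orient_axis` convention).
    """

    centre: np.ndarray
    axis: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "centre", _as_vec3(self.centre, "centre"))
        object.__setattr__(
            self, "axis", _check_unit(_as_vec3(self.axis, "axis"), "axis")
        )


@dataclass(frozen=True)
class LeverSet:
    """Lever vectors of one head side, rooted at the joint centre (mm).

    ``gamma0`` is the apodeme angle (degrees, in (0, 180)) measured at the
    reference opening angle ``theta0`` (degrees).
    """

    inlever: np.ndarray
    outlever_distal: np.ndarray
    outlever_proximal: np.ndarray
    apodeme_axis: np.ndarray
    gamma0: float
    theta0: float

    def __post_init__(self):
        object.__setattr__(self, "inlever", _as_vec3(self.inlever, "inlever"))
        object.__setattr__(
            self,
            "outlever_distal",
            _as_vec3(self.outlever_distal, "outlever_distal"),
        )
        object.__setattr__(
            self,
            "outlever_proximal",
            _as_vec3(self.outlever_proximal, "outlever_proximal"),
        )
        object.__setattr__(
            self,
            "apodeme_axis",
            _check_unit(_as_vec3(self.apodeme_axis, "apodeme_axis"), "apodeme_axis"),
        )
        if not 0.0 < self.gamma0 < 180.0:
            raise ValueError(f"gamma0 must lie in (0, 180) deg, got {self.gamma0}")


def apodeme_angle(theta, levers: LeverSet):
    """Apodeme angle gamma (degrees) at opening angle ``theta`` (degrees).

    Linear in theta with slope -1: ``gamma = theta0 - theta + gamma0``.
    Values outside (0, 180) are returned as-is; the caller interprets them
    as geometrically degenerate.
    """
    theta = np.asarray(theta, dtype=float)
    return levers.theta0 - theta + levers.gamma0


def effective_levers(theta, levers: LeverSet, frame: JointFrame):
    """Effective in-/outlever (mm) and mechanical advantage at ``theta``.

    The effective inlever is ``sin(gamma(theta)) |R̂ x L_i| |R̂ x Â|``: the
    projected inlever, shortened by the apodeme angle and by the fraction of
    the apodeme force lying in the rotation plane.  The effective outlever
    is ``|R̂ x L_o,d|`` at every opening angle, because the bite force is by
    definition perpendicular to both the outlever and the rotation axis.

    Returns ``(inlever_eff, outlever_eff, mechanical_advantage)``;
    vectorized over ``theta``.

    Raises
    ------
    ValueError
        If the outlever (or inlever/apodeme) projection is degenerate,
        i.e. shorter than :data:`DEGENERATE_TOL`.
    """
    r_li = rejection_norm(frame.axis, levers.inlever)
    r_lo = rejection_norm(frame.axis, levers.outlever_distal)
    r_a = rejection_norm(frame.axis, levers.apodeme_axis)
    for val, name in ((r_li, "inlever"), (r_lo, "outlever_distal"), (r_a, "apodeme_axis")):
        if val < DEGENERATE_TOL:
            raise ValueError(
                f"degenerate projection: |axis x {name}| = {val:.3g} mm "
                f"< {DEGENERATE_TOL} mm (vector parallel to rotation axis)"
            )
    gamma = np.radians(apodeme_angle(theta, levers))
    in_eff = np.sin(gamma) * r_li * r_a
    out_eff = np.broadcast_to(r_lo, np.shape(gamma)).copy() if np.ndim(gamma) else r_lo
    return in_eff, out_eff, in_eff / r_lo


def apodeme_displacement(theta, levers: LeverSet, frame: JointFrame):
    """Apodeme displacement at opening angle ``theta`` (degrees).

    Returns ``(delta, longitudinal, lateral)`` in mm, vectorized over
    ``theta``:

    * ``delta`` — displacement of the apodeme along its main axis,
      ``[cos(gamma0) - cos(gamma(theta))] |R̂ x L_i| |R̂ x Â|``.  Zero at the
      reference angle ``theta0`` and increasing as the mandible closes.
    * ``longitudinal`` — in-plane path component of the apodeme attachment
      point along the projected apodeme axis (equal to ``delta`` without the
      out-of-plane factor ``|R̂ x Â|``).
    * ``lateral`` — in-plane path component perpendicular to the projected
      apodeme axis; accommodated by the apodeme ligament, not by apodeme
      translation.  For a closure of 40 deg from gamma0 = 90 deg the
      lateral component is about one third of the longitudinal one.
    """
    r_li = rejection_norm(frame.axis, levers.inlever)
    r_a = rejection_norm(frame.axis, levers.apodeme_axis)
    g0 = np.radians(levers.gamma0)
    gamma = np.radians(apodeme_angle(theta, levers))
    longitudinal = (np.cos(g0) - np.cos(gamma)) * r_li
    lateral = (np.sin(gamma) - np.sin(g0)) * r_li
    delta = longitudinal * r_a
    return delta, longitudinal, lateral


def gape(tooth_tip, plane_point, plane_normal) -> float:
    """Mandible gape: twice the signed tip distance to the sagittal plane.

    Parameters
    ----------
    tooth_tip : (3,) array_like
        Distal tooth tip, mm.
    plane_point, plane_normal : (3,) array_like
        Sagittal plane as a point plus a *unit* normal.  Orient the normal
        laterally, away from the mid-plane on the mandible's own side: the
        gape is then negative when the mandibles overlap (tip crossed to
        the other side).
    """
    tip = _as_vec3(tooth_tip, "tooth_tip")
    p0 = _as_vec3(plane_point, "plane_point")
    n = _as_vec3(plane_normal, "plane_normal")
    if abs(np.linalg.norm(n) - 1.0) > 1e-6:
        raise ValueError("plane_normal must be a unit vector")
    return 2.0 * float((tip - p0) @ n)
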
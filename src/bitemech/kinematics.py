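"""Joint-axis and apodeme-displacement estimation from multi-pose landmarks.

If the mandible rotates about a single fixed axis, the angle between that
axis and *any* vector connecting two points on the mandible is the same in
every pose.  The rotation axis is therefore estimated by minimizing the
squared deviations of those angles from their per-vector means, across
poses, for the three mandible-fixed vectors (inlever, distal outlever,
proximal outlever).

The apodeme, in contrast, translates: its centre-of-mass positions across
poses fall on a line.  The displacement axis is the first principal
component of those positions, and signed positions along it (times the
average head length, since coordinates are head-length normalized) give
the apodeme displacement per pose.

Landmark coordinate convention: +x anterior, +y lateral towards the left,
+z dorsal; the sagittal plane of the normalized frame is y = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import optimize

from .geometry import orient_axis

__all__ = [
    "VECTOR_NAMES",
    "PoseLandmarks",
    "AxisEstimate",
    "normalize_landmarks",
    "estimate_rotation_axis",
    "displacement_axis",
]

#: The mandible-fixed vectors used for axis estimation.
VECTOR_NAMES = ("inlever", "outlever_distal", "outlever_proximal")


@dataclass(frozen=True)
class PoseLandmarks:
    """Normalized landmark vectors of one scan pose (one head side).

    Vectors are rooted at the joint centre and divided by head length
    (anterior-posterior joint-to-rear distance); right-hemisphere lateral
    coordinates have been mirrored so both sides share one frame.
    """

    pose_id: str
    hemisphere: Literal["left", "right"]
    head_length: float
    vectors: dict
    apodeme_com: np.ndarray | None = None

    def __post_init__(self):
        if self.head_length <= 0:
            raise ValueError(f"pose {self.pose_id}: head_length must be positive")
        missing = [n for n in VECTOR_NAMES if n not in self.vectors]
        if missing:
            raise ValueError(
                f"pose {self.pose_id}: missing landmark vector(s) {missing}"
            )


@dataclass(frozen=True)
class AxisEstimate:
    """Estimated rotation axis with its fit quality.

    ``residual`` is the mean squared angular deviation (degrees^2) of the
    per-pose vector angles about their per-vector means.
    """

    axis: np.ndarray
    residual: float
    n_poses: int
    per_vector_angles: dict | None = None


def _require(df_pose, landmark: str, pose) -> np.ndarray:
    sub = df_pose[df_pose["landmark"] == landmark]
    if len(sub) == 0:
        raise ValueError(f"pose {pose!r}: missing landmark {landmark!r}")
    return sub[["x", "y", "z"]].to_numpy(dtype=float)[0]


def normalize_landmarks(raw) -> list[PoseLandmarks]:
    """Normalize raw landmark rows into per-pose vector sets.

    Parameters
    ----------
    raw : pandas.DataFrame
        Long-format landmarks with columns ``pose``, ``hemisphere``
        (left/right), ``landmark``, ``x``, ``y``, ``z`` (mm).  Required
        landmarks per pose: ``joint_centre``, ``head_rear``,
        ``inlever``, ``outlever_distal``, ``outlever_proximal``; optional
        ``apodeme_com``.

    The origin is moved to the joint centre, coordinates are divided by
    head length (the anterior-posterior distance between joint and head
    rear, |x_rear - x_joint|), and right-hemisphere lateral (y)
    coordinates are negated, mirroring across the sagittal plane y = 0 of
    the normalized frame.  Already-normalized left-hemisphere input passes
    through unchanged; rigid whole-head translations drop out.
    """
    poses = []
    for (pose, hemi), df_pose in raw.groupby(["pose", "hemisphere"], sort=False):
        joint = _require(df_pose, "joint_centre", pose)
        rear = _require(df_pose, "head_rear", pose)
        head_length = abs(rear[0] - joint[0])
        if head_length <= 0:
            raise ValueError(
                f"pose {pose!r}: joint and head rear coincide along the "
                "anterior-posterior axis; head length undefined"
            )
        mirror = np.array([1.0, -1.0, 1.0]) if hemi == "right" else np.ones(3)
        vectors = {
            name: (_require(df_pose, name, pose) - joint) / head_length * mirror
            for name in VECTOR_NAMES
        }
        com = None
        if (df_pose["landmark"] == "apodeme_com").any():
            com = (_require(df_pose, "apodeme_com", pose) - joint) / head_length * mirror
        poses.append(
            PoseLandmarks(
                pose_id=str(pose),
                hemisphere=hemi,
                head_length=head_length,
                vectors=vectors,
                apodeme_com=com,
            )
        )
    return poses


def _axis_from_angles(az: float, el: float) -> np.ndarray:
    return np.array(
        [np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)]
    )


def axis_objective(axis: np.ndarray, unit_vectors: np.ndarray) -> float:
    """Sum of squared angular deviations (deg^2) about per-vector means.

    ``unit_vectors`` has shape (n_vectors, n_poses, 3), rows normalized.
    """
    cosines = np.clip(unit_vectors @ axis, -1.0, 1.0)
    angles = np.degrees(np.arccos(cosines))  # (n_vectors, n_poses)
    dev = angles - angles.mean(axis=1, keepdims=True)
    return float(np.sum(dev**2))


def _lattice_starts():
    # 26 directions of the 3x3x3 integer lattice around the origin.
    pts = []
    for i in (-1, 0, 1):
        for j in (-1, 0, 1):
            for k in (-1, 0, 1):
                if i == j == k == 0:
                    continue
                v = np.array([i, j, k], dtype=float)
                pts.append(v / np.linalg.norm(v))
    return pts


def estimate_rotation_axis(
    poses: list[PoseLandmarks],
    dorsoventral=(0.0, 0.0, 1.0),
    n_refine: int = 5,
) -> AxisEstimate:
    """Estimate the mandible rotation axis from >= 2 poses.

    Minimizes the squared angular residuals of the three mandible-fixed
    vectors about their per-vector mean angles, over axis orientations
    parametrized by azimuth/elevation on the unit sphere.  The objective
    is evaluated at 26 lattice directions and derivative-free local
    searches (Nelder-Mead) are launched from the ``n_refine`` best of
    them; the best refined solution is kept and the axis sign is fixed
    against the dorso-ventral head axis.

    Raises
    ------
    ValueError
        If fewer than 2 poses are given or all poses are identical (the
        axis is then unidentifiable).
    """
    if len(poses) < 2:
        raise ValueError("at least 2 poses at distinct opening angles required")
    vecs = np.array(
        [[p.vectors[name] for p in poses] for name in VECTOR_NAMES], dtype=float
    )  # (3, n_poses, 3)
    norms = np.linalg.norm(vecs, axis=2, keepdims=True)
    if np.any(norms < 1e-12):
        raise ValueError("zero-length landmark vector")
    unit = vecs / norms
    spread = max(
        float(np.linalg.norm(unit[i] - unit[i, :1], axis=1).max())
        for i in range(unit.shape[0])
    )
    if spread < 1e-12:
        raise ValueError(
            "all poses are identical: the rotation axis is unidentifiable"
        )

    starts = _lattice_starts()
    coarse = sorted(
        ((axis_objective(s, unit), s) for s in starts), key=lambda t: t[0]
    )
    best_x, best_f = None, np.inf
    for _, start in coarse[: max(1, n_refine)]:
        az0 = np.arctan2(start[1], start[0])
        el0 = np.arcsin(np.clip(start[2], -1, 1))
        res = optimize.minimize(
            lambda p: axis_objective(_axis_from_angles(*p), unit),
            x0=(az0, el0),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 400},
        )
        if res.fun < best_f:
            best_f, best_x = res.fun, res.x
    axis = orient_axis(_axis_from_angles(*best_x), dorsoventral)
    cosines = np.clip(unit @ axis, -1.0, 1.0)
    angles = np.degrees(np.arccos(cosines))
    per_vector = {
        name: angles[i].tolist() for i, name in enumerate(VECTOR_NAMES)
    }
    n_angles = angles.size
    return AxisEstimate(
        axis=axis,
        residual=best_f / n_angles,
        n_poses=len(poses),
        per_vector_angles=per_vector,
    )


def displacement_axis(coms, mean_head_length: float, orient=None):
    """Apodeme displacement axis and per-pose displacements.

    Parameters
    ----------
    coms : (n, 3) array_like
        Normalized apodeme centre-of-mass coordinates (head-length units),
        one row per pose; n >= 3.
    mean_head_length : float
        Average head length (mm) used to convert normalized positions
        back to millimetres.
    orient : (3,) array_like, optional
        If given, the sign of the principal direction is chosen so that
        ``axis . orient >= 0`` (e.g. pass the apodeme main axis so that
        positive displacements point posteriorly, towards the muscle
        pull); otherwise the sign is arbitrary.

    Returns
    -------
    axis : (3,) ndarray
        First principal direction of the centre-of-mass cloud.
    r2 : float
        Fraction of coordinate variance explained by that direction.
    displacements : (n,) ndarray
        Signed positions along the axis in mm, centred on their mean
        (displacements relative to the average apodeme position).
    """
    pts = np.asarray(coms, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("coms must be an (n, 3) array")
    if pts.shape[0] < 3:
        raise ValueError("at least 3 poses are required for the PCA")
    centred = pts - pts.mean(axis=0)
    if np.linalg.norm(centred) < 1e-12:
        warnings.warn(
            "all centre-of-mass points coincide: displacement axis is "
            "rank-deficient",
            UserWarning,
            stacklevel=2,
        )
        return np.array([1.0, 0.0, 0.0]), 0.0, np.zeros(pts.shape[0])
    _, s, vt = np.linalg.svd(centred, full_matrices=False)
    axis = vt[0]
    if orient is not None and float(axis @ np.asarray(orient, dtype=float)) < 0:
        axis = -axis
    r2 = float(s[0] ** 2 / np.sum(s**2))
    disp = centred @ axis * mean_head_length
    disp = disp - disp.mean()
    return axis, r2, disp
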
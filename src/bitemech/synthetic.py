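"""Synthetic-data generators for every part of the bite-force pipeline.

Every generator is a pure function of its arguments and an explicit seed;
no module-level random state exists.  Generators return ground truth
alongside the data wherever there is any, so closed-loop (generate ->
analyse -> compare) tests need no external data.

The reference apparatus encodes the study conditions of a leaf-cutter ant
(*Atta cephalotes*) major head side, reconstructed from published summary
statistics; see :func:`make_reference_apparatus` for the back-solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .biteforce import BiteApparatus, BiteMeasurement
from .geometry import JointFrame, LeverSet, apodeme_angle, apodeme_displacement
from .kinematics import VECTOR_NAMES, PoseLandmarks
from .morphometry import FibreField
from .muscle import FibrePopulation, ForceLengthParams, MuscleArchitecture

__all__ = [
    "SyntheticSpec",
    "make_reference_apparatus",
    "simulate_bite_measurements",
    "make_pose_series",
    "make_apodeme_com_track",
    "make_attachment_path",
    "make_fibre_field",
]


@dataclass(frozen=True)
class SyntheticSpec:
    """Design of one synthetic bite-force experiment.

    Defaults mirror the in-vivo study design: 138 accepted measurements,
    opening angles uniform in 50-105 deg, multiplicative force noise with
    a 5 % standard deviation.
    """

    seed: int
    n: int = 138
    noise_scale: float = 0.05
    ranges: dict = field(default_factory=lambda: {"theta": (50.0, 105.0)})

    def __post_init__(self):
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be non-negative")
        if self.n < 1:
            raise ValueError("n must be positive")


# ---------------------------------------------------------------------------
# Reference apparatus
# ---------------------------------------------------------------------------
# Back-solved from published summary statistics of A. cephalotes majors.
# Known directly: MA_max = 0.29 at theta = 51 deg where gamma = 90 deg
# (hence theta0 = 51, gamma0 = 90); apodeme displacement range ~0.7 mm over
# theta in 35..105 deg; mean filament length 0.60 mm; fitted physiology
# sigma_max = 1.16 MPa, L_opt = 0.92 mm (filament-attached), beta = 5.34;
# A_phys = V_m / L_opt = 4.3 mm^2 => V_m = 3.956 mm^3; 15 % of fibres
# directly attached.
#
# Derived lever magnitudes:
#   Delta(35) - Delta(105) = [cos(36 deg) - cos(106 deg)] * k = 0.7 mm
#     with k = |R x L_i| |R x A|  =>  k = 0.6453668856591264 mm
#   MA_max = k / |R x L_o,d| = 0.29  =>  |R x L_o,d| = 2.225403053996988 mm
#
# Per-population (phi0, reference length) pairs were fitted by weighted
# least squares against four printed targets each -- pennation 41 deg at
# theta = 35 and 27 deg at theta = 105, and the fibre lengths at both ends
# of the range (filament-attached 0.85/1.47 mm, direct 1.51/2.11 mm) --
# because the four targets are mutually inconsistent at the ~5 % level
# under the model's height-conservation constraint (2 free parameters per
# population).  Length residuals were weighted 10 mm^-1 against 1 deg^-1.
# Resulting reproduction: pennation 40.6 -> 27.6 deg, filament-attached
# fibre lengths 0.848 -> 1.432 mm (ratio 1.69), direct 1.494 -> 2.077 mm
# (ratio 1.39).
_K_INLEVER_MM = 0.6453668856591264  # |R x L_i| (with |R x A| = 1)
_R_OUTLEVER_MM = 2.225403053996988  # |R x L_o,d|
_THETA0_DEG = 51.0
_GAMMA0_DEG = 90.0
_PHI0_FILAMENT_DEG = 36.376906
_LF0_FILAMENT_MM = 0.987855
_FILAMENT_MM = 0.60
_PHI0_DIRECT_DEG = 36.371557
_LD0_DIRECT_MM = 1.633478
_DIRECT_FRACTION = 0.15
_SIGMA_MAX_MPA = 1.16
_L_OPT_MM = 0.92
_BETA = 5.34
_VOLUME_MM3 = 4.3 * _L_OPT_MM  # 3.956 mm^3


def make_reference_apparatus() -> BiteApparatus:
    """Reference *A. cephalotes* major head side (one mandible).

    Coordinate frame: origin at the joint centre, +x anterior, +y lateral
    (left), +z dorsal; the rotation axis is dorso-ventral, so the rotation
    plane is the x-y plane.  The apodeme main axis points posteriorly
    (muscle pull direction) and lies in the rotation plane, so
    ``|R x A| = 1``.  The inlever is placed at gamma0 = 90 deg from the
    projected apodeme axis and the distal outlever at theta0 = 51 deg from
    the lateral head axis; only the projection magnitudes and the
    (gamma0, theta0) pair enter the model, the in-plane directions are
    cosmetic.
    """
    frame = JointFrame(centre=(0.0, 0.0, 0.0), axis=(0.0, 0.0, 1.0))
    a_hat = np.array([-1.0, 0.0, 0.0])  # posterior pull
    th0 = np.radians(_THETA0_DEG)
    levers = LeverSet(
        inlever=(0.0, -_K_INLEVER_MM, 0.0),  # 90 deg from projected A
        outlever_distal=_R_OUTLEVER_MM * np.array([np.sin(th0), np.cos(th0), 0.0]),
        outlever_proximal=0.6
        * _R_OUTLEVER_MM
        * np.array([np.sin(np.radians(30.0)), np.cos(np.radians(30.0)), 0.0]),
        apodeme_axis=a_hat,
        gamma0=_GAMMA0_DEG,
        theta0=_THETA0_DEG,
    )
    muscle = MuscleArchitecture(
        volume=_VOLUME_MM3,
        populations=[
            FibrePopulation(
                phi0=_PHI0_FILAMENT_DEG,
                fibre_length0=_LF0_FILAMENT_MM,
                filament_length=_FILAMENT_MM,
                number_fraction=1.0 - _DIRECT_FRACTION,
            ),
            FibrePopulation(
                phi0=_PHI0_DIRECT_DEG,
                fibre_length0=_LD0_DIRECT_MM,
                filament_length=0.0,
                number_fraction=_DIRECT_FRACTION,
            ),
        ],
    )
    physiology = ForceLengthParams(
        sigma_max=_SIGMA_MAX_MPA, l_opt=_L_OPT_MM, beta=_BETA
    )
    return BiteApparatus(
        frame=frame,
        levers=levers,
        muscle=muscle,
        physiology=physiology,
        theta_range=(35.0, 105.0),
    )


# ---------------------------------------------------------------------------
# Bite-force measurements
# ---------------------------------------------------------------------------


def simulate_bite_measurements(
    apparatus: BiteApparatus, spec: SyntheticSpec
) -> list[BiteMeasurement]:
    """Simulate an in-vivo bite-force experiment.

    Opening angles are drawn uniformly from ``spec.ranges['theta']``;
    forces are the forward model times ``(1 + eps)`` with
    ``eps ~ N(0, noise_scale)``, redrawn where necessary so every force is
    strictly positive (truncation at zero).  Reproducible: the output is a
    pure function of ``(apparatus, spec)``.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.ranges.get("theta", (50.0, 105.0))
    theta = rng.uniform(lo, hi, size=spec.n)
    model = apparatus.bite_force(theta)
    force = model * (1.0 + rng.normal(0.0, spec.noise_scale, size=spec.n))
    bad = force <= 0
    while np.any(bad):
        force[bad] = model[bad] * (
            1.0 + rng.normal(0.0, spec.noise_scale, size=int(bad.sum()))
        )
        bad = force <= 0
    return [
        BiteMeasurement(theta=float(t), force_measured=float(f))
        for t, f in zip(theta, force)
    ]


# ---------------------------------------------------------------------------
# Pose series for axis estimation
# ---------------------------------------------------------------------------

_BASE_VECTORS = {
    # normalized (head-length) landmark vectors of a left head side:
    # the apodeme attachment sits postero-medial and slightly dorsal of
    # the joint; the distal tooth antero-lateral and ventral; the most
    # proximal tooth much closer to the joint and more medial (the tooth
    # row runs distal-lateral to proximal-medial), so the three vectors
    # point in genuinely distinct directions -- the premise of the
    # constant-angle axis criterion
    "inlever": np.array([-0.05, -0.21, 0.05]),
    "outlever_distal": np.array([0.60, 0.48, -0.10]),
    "outlever_proximal": np.array([-0.02, 0.40, -0.12]),
}


def _rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    # Rodrigues rotation about a unit axis
    k = np.asarray(axis, dtype=float)
    K = np.array(
        [[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]]
    )
    return (
        np.eye(3) * np.cos(angle_rad)
        + np.sin(angle_rad) * K
        + (1 - np.cos(angle_rad)) * np.outer(k, k)
    )


def make_pose_series(
    axis,
    angles_deg,
    noise: float = 0.0,
    seed: int | None = None,
    base_vectors: dict | None = None,
    head_length: float = 2.9,
) -> list[PoseLandmarks]:
    """Rigidly rotated landmark poses about a known axis.

    Each pose rotates the base mandible vectors about the unit ``axis``
    (through the joint centre) by the corresponding angle; optional
    isotropic Gaussian landmark noise is added whose total displacement
    has root-mean-square magnitude ``noise`` times the vector norm
    (per-coordinate standard deviation ``noise * |v| / sqrt(3)``).
    ``noise > 0`` requires a seed.

    Raises ValueError for fewer than 2 angles or a non-unit axis.
    """
    axis = np.asarray(axis, dtype=float)
    if abs(np.linalg.norm(axis) - 1.0) > 1e-6:
        raise ValueError("axis must be a unit vector")
    angles = np.atleast_1d(np.asarray(angles_deg, dtype=float))
    if angles.size < 2:
        raise ValueError("at least 2 pose angles are required")
    if noise > 0 and seed is None:
        raise ValueError("noisy pose series require an explicit seed")
    rng = np.random.default_rng(seed)
    base = dict(_BASE_VECTORS if base_vectors is None else base_vectors)
    poses = []
    for i, ang in enumerate(angles):
        R = _rotation_matrix(axis, np.radians(float(ang)))
        vectors = {}
        for name in VECTOR_NAMES:
            v = R @ base[name]
            if noise > 0:
                sigma = noise * np.linalg.norm(v) / np.sqrt(3.0)
                v = v + rng.normal(0.0, sigma, size=3)
            vectors[name] = v
        poses.append(
            PoseLandmarks(
                pose_id=f"pose{i}",
                hemisphere="left",
                head_length=head_length,
                vectors=vectors,
            )
        )
    return poses


def make_apodeme_com_track(apparatus: BiteApparatus, thetas_deg):
    """Apodeme centre-of-mass positions across poses (pure translation).

    The apodeme translates along its main axis by the displacement
    Delta(theta); the centre of mass therefore moves collinearly.  Returns
    ``(coms, delta)``: normalized (head-length-free, still in mm here)
    COM coordinates per pose and the generating Delta values.
    """
    thetas = np.atleast_1d(np.asarray(thetas_deg, dtype=float))
    delta, _, _ = apodeme_displacement(thetas, apparatus.levers, apparatus.frame)
    com0 = np.array([-1.2, 0.4, 0.2])  # arbitrary resting position
    a_hat = apparatus.levers.apodeme_axis
    coms = com0[None, :] + delta[:, None] * a_hat[None, :]
    return coms, delta


def make_attachment_path(levers: LeverSet, frame: JointFrame, thetas_deg):
    """Circular-arc path of the apodeme attachment point across poses.

    The attachment point sits at the tip of the inlever and rotates with
    the mandible: in the rotation plane its polar angle from the projected
    apodeme axis equals gamma(theta).  Its longitudinal path component
    reproduces Delta(theta)/|R x A| exactly; the full path is an arc, so a
    straight-line (PCA) fit to it carries a curvature error that grows
    with the angular range.

    Returns ``(points, delta)`` with one 3-D point per pose.
    """
    thetas = np.atleast_1d(np.asarray(thetas_deg, dtype=float))
    axis = frame.axis
    # in-plane orthonormal pair: a_dir along the projected apodeme axis
    a_proj = levers.apodeme_axis - (levers.apodeme_axis @ axis) * axis
    a_dir = a_proj / np.linalg.norm(a_proj)
    b_dir = np.cross(axis, a_dir)
    r = np.linalg.norm(np.cross(axis, levers.inlever))
    gamma = np.radians(apodeme_angle(thetas, levers))
    # polar angle gamma measured from the -A direction so that closing the
    # mandible (growing gamma) moves the point towards +A, the pull
    # direction, matching the sign convention of the displacement relation
    points = r * (
        -np.cos(gamma)[:, None] * a_dir[None, :]
        + np.sin(gamma)[:, None] * b_dir[None, :]
    )
    delta, _, _ = apodeme_displacement(thetas, levers, frame)
    return points, delta


# ---------------------------------------------------------------------------
# Fibre fields for morphometry
# ---------------------------------------------------------------------------


def make_fibre_field(
    n: int,
    seed: int,
    pennation_deg: float = 30.0,
    corridor_px: float = 12.0,
    voxel_size: float = 0.02,
    spacing_px: float = 2.0,
    total_length_px: tuple[float, float] = (45.0, 60.0),
    fibre_diameter_px: float = 5.0,
    with_mask: bool = True,
):
    """Non-crossing pennate fibre fan with known per-fibre ground truth.

    Apodeme surface points lie on a line along +x (the apodeme main axis
    and anterior axis coincide) at lateral height y = 5 px; fibres leave
    each insertion at the given pennation angle towards +y with
    anterior-posterior order preserved, so the rank pairing of seeds to
    insertions is the identity permutation.  Muscle tissue fills
    ``y >= 5 + corridor_px``: the muscle-free corridor makes the true
    filament length ``corridor_px / sin(pennation)`` voxels (0 when
    ``corridor_px = 0``, i.e. all fibres directly attached).

    Returns ``(field, truth)`` where ``truth`` is a dict of arrays with
    keys ``insertion_index``, ``l_fil_px``, ``l_fil_mm``,
    ``pennation_deg``, ``total_length_px``.
    """
    if n < 1:
        raise ValueError("n must be positive")
    if not 0.0 < pennation_deg < 90.0:
        raise ValueError("pennation_deg must lie in (0, 90)")
    rng = np.random.default_rng(seed)
    phi = np.radians(pennation_deg)
    u = np.array([np.cos(phi), np.sin(phi), 0.0])

    x0, y_surf = 10.0, 5.0
    xs = x0 + spacing_px * np.arange(n)
    z_mid = 7.0
    surface = np.column_stack(
        [xs, np.full(n, y_surf), np.full(n, z_mid)]
    )
    lt = rng.uniform(*total_length_px, size=n)
    # keep anterior-posterior order strictly monotone (non-crossing fan):
    # successive seed x-positions must increase despite length jitter
    seed_x = xs + lt * u[0]
    order_ok = np.all(np.diff(seed_x) > 0)
    if not order_ok:  # enforce by sorting lengths along the fan
        lt = np.sort(lt)
        seed_x = xs + lt * u[0]
    seeds = surface + lt[:, None] * u[None, :]

    l_fil_px = np.full(n, corridor_px / np.sin(phi) if corridor_px > 0 else 0.0)

    mask = None
    if with_mask:
        nx = int(np.ceil(seeds[:, 0].max() + 8))
        ny = int(np.ceil(seeds[:, 1].max() + 8))
        nz = int(z_mid * 2 + 2)
        mask = np.zeros((nz, ny, nx), dtype=bool)
        y_muscle = y_surf + corridor_px
        yy = np.arange(ny)
        mask[:, yy >= y_muscle, :] = True

    field = FibreField(
        seeds=seeds,
        apodeme_surface=surface,
        apodeme_axis=np.array([1.0, 0.0, 0.0]),
        voxel_size=voxel_size,
        muscle_mask=mask,
        fibre_diameter_px=fibre_diameter_px,
        anterior_axis=np.array([1.0, 0.0, 0.0]),
    )
    truth = {
        "insertion_index": np.arange(n),
        "l_fil_px": l_fil_px,
        "l_fil_mm": l_fil_px * voxel_size,
        "pennation_deg": np.full(n, pennation_deg),
        "total_length_px": lt,
    }
    return field, truth
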
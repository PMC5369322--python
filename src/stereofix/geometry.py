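"""Rigid-pose mathematics of an active binocular head.

The head rotates on a Fick gimbal (vertical axis outermost, no torsion);
each camera/eye rotates on a Helmholtz gimbal (horizontal axis outermost)
and carries an additional cyclotorsion about its line of sight.  Torsion
follows the binocular extension of Listing's law (L2): with vergence the
two Listing planes tilt temporally and antisymmetrically by an angle
controlled by the gain ``delta``.

Conventions (fixed once, used everywhere):

* Right-handed frames; ``x`` to the right, ``y`` up, ``z`` toward the
  viewer.  The reference optical/nose axis is ``-z``.
* Angles are degrees at every public interface, radians internally.
* Positive azimuth ``beta`` is leftward gaze, so convergence on a near
  target gives a positive vergence ``nu = beta_R - beta_L``.
* The left camera sits at ``(-b/2, 0, 0)`` and the right at
  ``(+b/2, 0, 0)`` in the head frame; the cyclopic camera at the origin.
* Translations are millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation as _ScipyRotation

__all__ = [
    "GeometryError",
    "DegenerateTargetError",
    "OutOfRangeError",
    "SingularConfigurationError",
    "HeadState",
    "EyeState",
    "BinocularState",
    "elemental_rotation",
    "head_rotation",
    "head_pose",
    "helmholtz_angles_to_target",
    "eye_rotation",
    "listing_plane_tilt",
    "l2_torsion",
    "fixate",
    "parallel_axes_state",
    "fick_angles",
    "helmholtz_angles",
    "pose_matrix",
    "invert_pose",
    "apply_pose",
    "rotation_to_quaternion",
    "quaternion_to_rotation",
    "REFERENCE_AXIS",
]

#: Reference optical / nose axis in the local frame.
REFERENCE_AXIS = np.array([0.0, 0.0, -1.0])

DEFAULT_BASELINE_MM = 60.0
DEFAULT_DELTA = 0.8


class GeometryError(ValueError):
    """Base class for geometric configuration errors."""


class DegenerateTargetError(GeometryError):
    """Fixation target coincides with the camera origin or the baseline."""


class OutOfRangeError(GeometryError):
    """Angle or argument outside its admissible range."""


class SingularConfigurationError(GeometryError):
    """Gimbal/torsion formula hit a singular configuration."""


# ---------------------------------------------------------------------------
# elemental rotations and gimbals
# ---------------------------------------------------------------------------

def elemental_rotation(axis: str, angle_deg: float) -> np.ndarray:
    """Rotation about a coordinate axis.

    ``x`` is elevation (pitch), ``y`` azimuth (yaw), ``z`` torsion (roll);
    all follow the right-hand rule.
    """
    if not np.isfinite(angle_deg):
        raise OutOfRangeError(f"rotation angle must be finite, got {angle_deg!r}")
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    if axis == "x":
        return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])
    if axis == "y":
        return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])
    if axis == "z":
        return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    raise OutOfRangeError(f"axis must be one of 'x', 'y', 'z', got {axis!r}")


def head_rotation(alpha_deg: float, beta_deg: float) -> np.ndarray:
    """Fick-gimbal head rotation ``R_H = R_y(beta) @ R_x(alpha)``.

    The vertical (azimuth) axis is outermost, so the resulting pose has no
    torsional component in Fick coordinates.
    """
    return elemental_rotation("y", beta_deg) @ elemental_rotation("x", alpha_deg)


def eye_rotation(alpha_deg: float, beta_deg: float) -> np.ndarray:
    """Helmholtz-gimbal eye rotation ``R = R_x(alpha) @ R_y(beta)``.

    Note the composition order is reversed with respect to the head's Fick
    gimbal; the two agree only when one of the angles vanishes.
    """
    return elemental_rotation("x", alpha_deg) @ elemental_rotation("y", beta_deg)


def pose_matrix(rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    """4x4 homogeneous rigid transform from a 3x3 rotation and a translation (mm)."""
    P = np.eye(4)
    P[:3, :3] = rotation
    P[:3, 3] = np.asarray(translation, dtype=float)
    return P


def invert_pose(pose: np.ndarray) -> np.ndarray:
    R = pose[:3, :3]
    t = pose[:3, 3]
    return pose_matrix(R.T, -R.T @ t)


def apply_pose(pose: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Apply a 4x4 pose to one point or an (N, 3) array of points."""
    pts = np.asarray(points, dtype=float)
    return pts @ pose[:3, :3].T + pose[:3, 3]


def rotation_to_quaternion(rotation: np.ndarray) -> np.ndarray:
    """Unit quaternion in (w, x, y, z) order."""
    q = _ScipyRotation.from_matrix(rotation).as_quat()  # (x, y, z, w)
    q = np.roll(q, 1)
    if q[0] < 0:  # canonical sign
        q = -q
    return q


def quaternion_to_rotation(q_wxyz: np.ndarray) -> np.ndarray:
    q = np.asarray(q_wxyz, dtype=float)
    return _ScipyRotation.from_quat(np.roll(q, -1)).as_matrix()


def fick_angles(rotation: np.ndarray) -> tuple[float, float, float]:
    """Decompose ``R = R_y(beta) @ R_x(alpha) @ R_z(gamma)`` (Fick order).

    Returns ``(alpha, beta, gamma)`` in degrees.
    """
    g = rotation @ REFERENCE_AXIS
    alpha = np.arcsin(np.clip(g[1], -1.0, 1.0))
    beta = np.arctan2(-g[0], -g[2])
    residual = (
        elemental_rotation("x", -np.rad2deg(alpha))
        @ elemental_rotation("y", -np.rad2deg(beta))
        @ rotation
    )
    gamma = np.arctan2(residual[1, 0], residual[0, 0])
    return tuple(np.rad2deg([alpha, beta, gamma]))


def helmholtz_angles(rotation: np.ndarray) -> tuple[float, float, float]:
    """Decompose ``R = R_x(alpha) @ R_y(beta) @ R_z(gamma)`` (Helmholtz order)."""
    g = rotation @ REFERENCE_AXIS
    beta = np.arcsin(np.clip(-g[0], -1.0, 1.0))
    alpha = np.arctan2(g[1], -g[2])
    residual = (
        elemental_rotation("y", -np.rad2deg(beta))
        @ elemental_rotation("x", -np.rad2deg(alpha))
        @ rotation
    )
    gamma = np.arctan2(residual[1, 0], residual[0, 0])
    return tuple(np.rad2deg([alpha, beta, gamma]))


# ---------------------------------------------------------------------------
# head
# ---------------------------------------------------------------------------

@dataclass
class HeadState:
    """Head placed in the world on a Fick gimbal (no torsion).

    Parameters
    ----------
    position : (3,) array, mm, world frame.
    elevation : Fick elevation (pitch) of the nose direction, degrees;
        positive looks up.
    azimuth : Fick azimuth (yaw), degrees; positive looks left.
    fixation : optional fixation target in world coordinates, mm.
    """

    position: np.ndarray
    elevation: float = 0.0
    azimuth: float = 0.0
    fixation: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if self.fixation is not None:
            self.fixation = np.asarray(self.fixation, dtype=float).reshape(3)

    @property
    def rotation(self) -> np.ndarray:
        return head_rotation(self.elevation, self.azimuth)

    @property
    def nose_direction(self) -> np.ndarray:
        """Unit nose direction in the world frame (rotated reference axis)."""
        return self.rotation @ REFERENCE_AXIS

    @property
    def pose(self) -> np.ndarray:
        return pose_matrix(self.rotation, self.position)


def head_pose(head: HeadState) -> np.ndarray:
    """4x4 world-frame pose matrix of the head."""
    return head.pose


# ---------------------------------------------------------------------------
# eyes
# ---------------------------------------------------------------------------

def helmholtz_angles_to_target(
    origin: np.ndarray, target: np.ndarray
) -> tuple[float, float]:
    """Helmholtz (elevation, azimuth) aiming the optical axis at ``target``.

    Both points are head-frame millimetres.  The returned angles satisfy
    ``eye_rotation(alpha, beta) @ REFERENCE_AXIS == unit(target - origin)``.
    Targets must lie in the frontal hemifield (negative head-frame ``z``
    relative to the origin); the angles then fall in (-90, 90) degrees.
    """
    origin = np.asarray(origin, dtype=float).reshape(3)
    target = np.asarray(target, dtype=float).reshape(3)
    d = target - origin
    norm = np.linalg.norm(d)
    if norm < 1e-12:
        raise DegenerateTargetError("fixation target coincides with the camera origin")
    g = d / norm
    if g[2] >= 0.0:
        raise OutOfRangeError(
            "target lies behind the frontal hemifield (non-negative head-frame z)"
        )
    beta = np.arcsin(np.clip(-g[0], -1.0, 1.0))
    alpha = np.arctan2(g[1], -g[2])
    return float(np.rad2deg(alpha)), float(np.rad2deg(beta))


def listing_plane_tilt(
    vergence_deg: float, version_deg: float, delta: float = DEFAULT_DELTA
) -> tuple[float, float]:
    """Temporal tilt of the two Listing planes under vergence (L2).

    ``phi_L = -phi_R = (delta/2) * arcsin(sin(nu) / (2 cos(xi/2)))`` with
    vergence ``nu`` and version (binocular azimuth) ``xi``; antisymmetric in
    the two eyes.  ``delta`` in [0, 1] balances the monocular motor
    advantage (Listing) against the binocular perceptual optimisation (L2).
    """
    if not (np.isfinite(vergence_deg) and np.isfinite(version_deg)):
        raise OutOfRangeError("vergence and version must be finite")
    if abs(vergence_deg) >= 180.0:
        raise OutOfRangeError("vergence must satisfy |nu| < 180 degrees")
    nu = np.deg2rad(vergence_deg)
    xi = np.deg2rad(version_deg)
    arg = np.sin(nu) / (2.0 * np.cos(xi / 2.0))
    if abs(arg) > 1.0:
        raise OutOfRangeError(f"arcsin argument {arg:.6f} outside [-1, 1]")
    phi_l = np.rad2deg(delta / 2.0 * np.arcsin(arg))
    return float(phi_l), float(-phi_l)


def l2_torsion(alpha_deg: float, beta_deg: float, phi_deg: float) -> float:
    """Cyclotorsion (degrees) of one eye for a given gaze and Listing tilt.

    ``tan(gamma/2) = -tan(alpha/2) * (tan(phi) + tan(beta)) /
    (1 + tan(phi) tan(beta))``.  With ``phi = 0`` this reduces to
    ``-tan(alpha/2) tan(beta)``, the false torsion a Helmholtz gimbal needs
    to comply with monocular Listing's law.
    """
    alpha = np.deg2rad(alpha_deg)
    beta = np.deg2rad(beta_deg)
    phi = np.deg2rad(phi_deg)
    denom = 1.0 + np.tan(phi) * np.tan(beta)
    if abs(denom) < 1e-12:
        raise SingularConfigurationError(
            "torsion denominator vanished (phi + beta at 90 degrees)"
        )
    half_tan = -np.tan(alpha / 2.0) * (np.tan(phi) + np.tan(beta)) / denom
    return float(np.rad2deg(2.0 * np.arctan(half_tan)))


@dataclass
class EyeState:
    """Static pose of one camera (left/right/cyclopic) of the binocular head.

    Angles are Helmholtz gaze angles in degrees; ``gamma`` is the
    cyclotorsion about the line of sight and ``phi`` the Listing-plane
    tilt that produced it.  ``origin`` is the head-frame position (mm).
    """

    side: str
    origin: np.ndarray
    alpha: float
    beta: float
    gamma: float = 0.0
    phi: float = 0.0
    pose_head: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    pose_world: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    @property
    def rotation(self) -> np.ndarray:
        """Torsion-compliant rotation ``R_L2 = R_helmholtz @ R_z(gamma)``."""
        return eye_rotation(self.alpha, self.beta) @ elemental_rotation("z", self.gamma)

    @property
    def optical_axis_world(self) -> np.ndarray:
        return self.pose_world[:3, :3] @ REFERENCE_AXIS

    @property
    def position_world(self) -> np.ndarray:
        return self.pose_world[:3, 3]


@dataclass
class BinocularState:
    """Complete static pose of the binocular head fixating one 3-D point."""

    head: HeadState
    left: EyeState
    right: EyeState
    cyclopic: EyeState
    baseline: float
    vergence: float
    version: float
    delta: float
    fixation: np.ndarray | None
    listing_mode: str = "l2"

    @property
    def eyes(self) -> tuple[EyeState, EyeState, EyeState]:
        return self.left, self.right, self.cyclopic

    def eye(self, side: str) -> EyeState:
        return {"left": self.left, "right": self.right, "cyclopic": self.cyclopic}[side]


def _build_eye(
    side: str,
    origin: np.ndarray,
    alpha: float,
    beta: float,
    gamma: float,
    phi: float,
    head_pose_mat: np.ndarray,
) -> EyeState:
    eye = EyeState(side=side, origin=np.asarray(origin, float), alpha=alpha, beta=beta,
                   gamma=gamma, phi=phi)
    eye.pose_head = pose_matrix(eye.rotation, eye.origin)
    eye.pose_world = head_pose_mat @ eye.pose_head
    return eye


def fixate(
    head: HeadState,
    fixation_world: np.ndarray,
    baseline: float = DEFAULT_BASELINE_MM,
    delta: float = DEFAULT_DELTA,
    listing_mode: str = "l2",
) -> BinocularState:
    """Pose the three cameras so both optical axes pass through a 3-D target.

    The target is transformed into the head frame, per-camera Helmholtz
    angles are computed with the toe-in construction, vergence and version
    follow, and cyclotorsion is applied according to ``listing_mode``:

    * ``"l2"``   — Listing plane tilts with vergence (gain ``delta``);
    * ``"ll"``   — monocular Listing's law (tilt forced to zero);
    * ``"none"`` — no torsion at all (pure Helmholtz).

    The cyclopic camera never carries torsion.
    """
    if listing_mode not in ("l2", "ll", "none"):
        raise OutOfRangeError(f"unknown listing_mode {listing_mode!r}")
    if not 0.0 <= delta <= 1.0:
        raise OutOfRangeError("delta must be in [0, 1]")
    F_world = np.asarray(fixation_world, dtype=float).reshape(3)
    P_WH = head.pose
    F_head = invert_pose(P_WH)[:3, :3] @ F_world + invert_pose(P_WH)[:3, 3]

    # Degenerate if F lies on the baseline (the head-frame x axis).
    if np.hypot(F_head[1], F_head[2]) < 1e-9:
        raise DegenerateTargetError("fixation point lies on the baseline line")

    origins = {
        "left": np.array([-baseline / 2.0, 0.0, 0.0]),
        "right": np.array([baseline / 2.0, 0.0, 0.0]),
        "cyclopic": np.zeros(3),
    }
    angles = {
        side: helmholtz_angles_to_target(origin, F_head)
        for side, origin in origins.items()
    }
    beta_l = angles["left"][1]
    beta_r = angles["right"][1]
    vergence = beta_r - beta_l
    version = 0.5 * (beta_l + beta_r)

    if listing_mode == "l2":
        phi_l, phi_r = listing_plane_tilt(vergence, version, delta)
    else:
        phi_l = phi_r = 0.0
    if listing_mode == "none":
        gamma_l = gamma_r = 0.0
    else:
        gamma_l = l2_torsion(angles["left"][0], beta_l, phi_l)
        gamma_r = l2_torsion(angles["right"][0], beta_r, phi_r)

    left = _build_eye("left", origins["left"], angles["left"][0], beta_l,
                      gamma_l, phi_l, P_WH)
    right = _build_eye("right", origins["right"], angles["right"][0], beta_r,
                       gamma_r, phi_r, P_WH)
    cyclopic = _build_eye("cyclopic", origins["cyclopic"], angles["cyclopic"][0],
                          angles["cyclopic"][1], 0.0, 0.0, P_WH)

    head = HeadState(head.position, head.elevation, head.azimuth, fixation=F_world)
    return BinocularState(
        head=head, left=left, right=right, cyclopic=cyclopic,
        baseline=float(baseline), vergence=float(vergence), version=float(version),
        delta=float(delta), fixation=F_world, listing_mode=listing_mode,
    )


def parallel_axes_state(
    head: HeadState,
    baseline: float = DEFAULT_BASELINE_MM,
    elevation: float = 0.0,
) -> BinocularState:
    """Off-axis (machine-vision) configuration: parallel optical axes.

    Both cameras share identical Helmholtz angles with zero azimuth, so the
    axes are parallel and perpendicular to the baseline; vergence and
    torsion are zero and the vertical disparity vanishes identically.
    """
    P_WH = head.pose
    eyes = {
        side: _build_eye(side, origin, elevation, 0.0, 0.0, 0.0, P_WH)
        for side, origin in {
            "left": np.array([-baseline / 2.0, 0.0, 0.0]),
            "right": np.array([baseline / 2.0, 0.0, 0.0]),
            "cyclopic": np.zeros(3),
        }.items()
    }
    return BinocularState(
        head=head, left=eyes["left"], right=eyes["right"], cyclopic=eyes["cyclopic"],
        baseline=float(baseline), vergence=0.0, version=0.0, delta=0.0,
        fixation=None, listing_mode="none",
    )
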
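"""4-DOF articulated-arm kinematics (DOBOT MG400 topology).

The arm is a base yaw joint (theta1) carrying a parallelogram-constrained
shoulder/elbow pair (theta2, theta3) and a tool yaw joint (theta4).  The
parallelogram linkage keeps the tool axis vertical for every configuration
— the posture required to hold an extrusion nozzle perpendicular to the
build plate — so the end-effector pose reduces to a 3D position plus a tool
yaw angle:

    r   = L2 sin(theta2) + L3 cos(theta3) + L4
    x   = r cos(theta1),   y = r sin(theta1)
    z   = L1 + L2 cos(theta2) - L3 sin(theta3)
    yaw = theta1 + theta4

theta2 is measured from vertical and theta3 from horizontal, matching the
device's zero posture (upper arm upright, forearm horizontal).  Inverse
kinematics is the analytic two-link solution in the vertical plane through
the base axis; the elbow-up branch matches the device's working posture.

Ideal actuation is assumed throughout: no backlash, compliance or
time-dependent disturbance.  Joint limits are reported (logged) but not
enforced, mirroring how such desktop arms are driven inside a verified
central workspace.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Default joint limits (rad): base yaw, shoulder, elbow, tool yaw.
DEFAULT_JOINT_LIMITS = (
    (-math.radians(160), math.radians(160)),
    (-math.radians(25), math.radians(85)),
    (-math.radians(25), math.radians(105)),
    (-math.pi, math.pi),
)


class ReachabilityError(ValueError):
    """Target outside the arm's reachable annulus."""


@dataclass(frozen=True)
class ArmModel:
    """Link lengths (mm), joint limits (rad) and positional repeatability.

    Defaults are desktop-arm scale configuration values (upper arm and
    forearm 175 mm, base column 138 mm, tool offset 66 mm); every public
    result that matters to path validation is either link-invariant or
    reported together with the links used.
    """

    L1: float = 138.0
    L2: float = 175.0
    L3: float = 175.0
    L4: float = 66.0
    joint_limits: tuple = DEFAULT_JOINT_LIMITS
    repeatability_eps: float = 0.05

    def __post_init__(self) -> None:
        for name in ("L1", "L2", "L3", "L4"):
            if getattr(self, name) <= 0:
                raise ValueError(f"link length {name} must be positive")
        for lo, hi in self.joint_limits:
            if not lo < hi:
                raise ValueError("joint limits must satisfy min < max")


@dataclass(frozen=True)
class JointState:
    """Joint angles in radians."""

    theta1: float
    theta2: float
    theta3: float
    theta4: float

    def as_array(self) -> np.ndarray:
        return np.array([self.theta1, self.theta2, self.theta3, self.theta4])


@dataclass(frozen=True)
class EEPose:
    """End-effector position (mm) and tool yaw (rad)."""

    position: np.ndarray
    yaw: float = 0.0

    def __post_init__(self) -> None:
        p = np.asarray(self.position, dtype=np.float64).reshape(3)
        if not np.isfinite(p).all() or not math.isfinite(self.yaw):
            raise ValueError("non-finite pose")
        object.__setattr__(self, "position", p)


def forward_kinematics(arm: ArmModel, joints: JointState) -> EEPose:
    """Map joint angles to the end-effector pose (tool always vertical)."""
    t1, t2, t3, t4 = joints.theta1, joints.theta2, joints.theta3, joints.theta4
    r = arm.L2 * math.sin(t2) + arm.L3 * math.cos(t3) + arm.L4
    x = r * math.cos(t1)
    y = r * math.sin(t1)
    z = arm.L1 + arm.L2 * math.cos(t2) - arm.L3 * math.sin(t3)
    return EEPose(position=np.array([x, y, z]), yaw=t1 + t4)


def _check_limits(arm: ArmModel, joints: JointState) -> None:
    for i, (angle, (lo, hi)) in enumerate(
        zip(joints.as_array(), arm.joint_limits), start=1
    ):
        if not (lo - 1e-12 <= angle <= hi + 1e-12):
            logger.warning(
                "joint %d angle %.4f rad outside limits [%.4f, %.4f] (not enforced)",
                i, angle, lo, hi,
            )


def inverse_kinematics(arm: ArmModel, pose: EEPose, elbow: str = "up") -> JointState:
    """Analytic inverse kinematics, elbow-up branch by default.

    Raises :class:`ReachabilityError` when the target lies outside the
    annulus |L2 - L3| <= sqrt(r^2 + h^2) <= L2 + L3, where r is the
    horizontal distance from the base axis minus the tool offset L4 and
    h the height above the shoulder (z - L1).
    """
    x, y, z = pose.position
    t1 = math.atan2(y, x)
    r = math.hypot(x, y) - arm.L4
    h = z - arm.L1
    rho = math.hypot(r, h)
    outer, inner = arm.L2 + arm.L3, abs(arm.L2 - arm.L3)
    if rho > outer + 1e-9:
        raise ReachabilityError(
            f"target at planar distance {rho:.6g} mm exceeds full reach "
            f"L2 + L3 = {outer:.6g} mm"
        )
    if rho < inner - 1e-9:
        raise ReachabilityError(
            f"target at planar distance {rho:.6g} mm is inside the inner "
            f"bound |L2 - L3| = {inner:.6g} mm"
        )
    cos_g = (rho * rho - arm.L2**2 - arm.L3**2) / (2 * arm.L2 * arm.L3)
    cos_g = min(1.0, max(-1.0, cos_g))
    gamma = math.acos(cos_g)
    if elbow == "up":
        gamma = -gamma
    elif elbow != "down":
        raise ValueError(f"elbow must be 'up' or 'down', got {elbow!r}")
    # planar 2R in (r, h): absolute link angles a (upper arm from the r-axis)
    # and b = a + gamma (forearm); mapped back to device angles below.
    a = math.atan2(h, r) - math.atan2(
        arm.L3 * math.sin(gamma), arm.L2 + arm.L3 * math.cos(gamma)
    )
    b = a + gamma
    t2 = math.pi / 2 - a  # shoulder measured from vertical
    t3 = -b               # elbow measured from horizontal
    t4 = pose.yaw - t1
    joints = JointState(t1, t2, t3, t4)
    _check_limits(arm, joints)
    return joints


def execute_path(
    arm: ArmModel,
    waypoints: Sequence[np.ndarray],
    mode: str = "cartesian_chord",
    samples_per_segment: int = 200,
) -> np.ndarray:
    """Execute a waypoint path and return the Cartesian samples visited.

    ``cartesian_chord``: each straight chord between consecutive waypoints
    is sampled at ``samples_per_segment`` + 1 evenly spaced points (shared
    endpoints counted once) — the reference interpolation, independent of
    the arm geometry.

    ``joint_linear``: inverse kinematics at each waypoint, linear
    interpolation of the four joint angles in ``samples_per_segment`` steps,
    forward kinematics back to Cartesian space — how a joint-interpolating
    controller would actually move between waypoints.

    Every waypoint must be reachable; an unreachable one raises
    :class:`ReachabilityError` naming its index.
    """
    if samples_per_segment < 1:
        raise ValueError("samples_per_segment must be >= 1")
    if mode not in ("cartesian_chord", "joint_linear"):
        raise ValueError(f"unknown execution mode {mode!r}")
    wp = [np.asarray(w, dtype=np.float64).reshape(3) for w in waypoints]
    if len(wp) < 2:
        raise ValueError("need at least two waypoints")

    joint_states = []
    for i, w in enumerate(wp):
        try:
            joint_states.append(inverse_kinematics(arm, EEPose(w)))
        except ReachabilityError as exc:
            raise ReachabilityError(f"waypoint {i} unreachable: {exc}") from exc

    M = samples_per_segment
    samples: list[np.ndarray] = []
    if mode == "cartesian_chord":
        for i in range(len(wp) - 1):
            t = np.linspace(0.0, 1.0, M + 1)[:, None]
            seg = wp[i] + t * (wp[i + 1] - wp[i])
            samples.append(seg if i == len(wp) - 2 else seg[:-1])
    else:
        for i in range(len(wp) - 1):
            qa = joint_states[i].as_array()
            qb = joint_states[i + 1].as_array()
            t = np.linspace(0.0, 1.0, M + 1)[:, None]
            qs = qa + t * (qb - qa)
            if i < len(wp) - 2:
                qs = qs[:-1]
            for q in qs:
                samples.append(
                    forward_kinematics(arm, JointState(*q)).position[None, :]
                )
    return np.vstack(samples)
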
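"""Spherical-treadmill kinematics: ball rotation, planar velocity, trajectory.

An animal tethered over an air-supported sphere drives the sphere instead of
translating; two optical-flow sensors mounted 90 degrees apart around the
equator (each tilted 45 degrees) read surface displacement, from which the
sphere's yaw/roll/pitch angular velocities, the animal's planar walking
velocity and its dead-reckoned trajectory are reconstructed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circular import wrap_to_pi

__all__ = [
    "CalibrationParams",
    "BallState",
    "PlanarVelocity",
    "Trajectory",
    "PoseAngles",
    "ClockMap",
    "angular_velocities",
    "planar_velocity",
    "integrate_trajectory",
    "synchronize_clocks",
    "pose_angles",
    "normalize_body_length",
]

_COS45 = np.cos(np.pi / 4.0)
_SIN45 = np.sin(np.pi / 4.0)


@dataclass(frozen=True)
class CalibrationParams:
    """Optical-flow sensor calibration.

    sigma_* convert sensor counts (per second) to sphere surface angular
    rate in rad/s; ``sphere_radius_mm`` is the treadmill sphere radius
    (50 mm for a 100 mm styrofoam ball); ``log_rate_hz`` is the sensor
    logging rate used to convert per-sample counts to per-second counts.
    """

    sigma_x1: float = 1.0
    sigma_y1: float = 1.0
    sigma_x2: float = 1.0
    sigma_y2: float = 1.0
    sphere_radius_mm: float = 50.0
    log_rate_hz: float = 50.0

    def __post_init__(self):
        if 0.0 in (self.sigma_x1, self.sigma_y1, self.sigma_x2, self.sigma_y2):
            raise ValueError("calibration scale parameters must be nonzero")
        if self.sphere_radius_mm <= 0:
            raise ValueError("sphere radius must be positive")
        if self.log_rate_hz <= 0:
            raise ValueError("log rate must be positive")


@dataclass
class BallState:
    """Sphere angular velocities (rad/s), vectorised over time."""

    omega_yaw: np.ndarray
    omega_roll: np.ndarray
    omega_pitch: np.ndarray
    t: np.ndarray | None = None


@dataclass
class PlanarVelocity:
    """Camera-frame planar walking velocity (mm/s unless BL-normalised)."""

    xdot_cam: np.ndarray
    ydot_cam: np.ndarray
    v_cam: np.ndarray
    t: np.ndarray | None = None


@dataclass
class Trajectory:
    """Integrated body-frame path, starting at the origin."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    dt: float


@dataclass
class PoseAngles:
    """Body orientation in camera frame and head angle relative to the body."""

    t: np.ndarray
    theta_body_cam: np.ndarray
    theta_head_cricket: np.ndarray


@dataclass
class ClockMap:
    """Affine map from logger time to camera time: t_cam = slope*t_log + offset."""

    slope: float
    offset: float
    residual_rms: float

    def __call__(self, t_logger):
        return self.slope * np.asarray(t_logger, dtype=float) + self.offset


def angular_velocities(frames: pd.DataFrame, calib: CalibrationParams) -> BallState:
    """Sphere yaw/roll/pitch angular velocities from dual optical-flow counts.

    ``frames`` has columns t, dx1, dy1, dx2, dy2 with counts per sample;
    counts are converted to counts/s with the log rate, then:

        omega_yaw   = -(sx1*dx1 + sx2*dx2) * cos 45
        omega_roll  = (1/2) * (-sy1*dy1 + sy2*dy2)
        omega_pitch =  (sx1*dx1 - sx2*dx2) * sin 45
    """
    rate = calib.log_rate_hz
    dx1 = np.asarray(frames["dx1"], dtype=float) * rate
    dy1 = np.asarray(frames["dy1"], dtype=float) * rate
    dx2 = np.asarray(frames["dx2"], dtype=float) * rate
    dy2 = np.asarray(frames["dy2"], dtype=float) * rate
    sx1, sy1 = calib.sigma_x1, calib.sigma_y1
    sx2, sy2 = calib.sigma_x2, calib.sigma_y2
    omega_yaw = -(sx1 * dx1 + sx2 * dx2) * _COS45
    omega_roll = 0.5 * (-sy1 * dy1 + sy2 * dy2)
    omega_pitch = (sx1 * dx1 - sx2 * dx2) * _SIN45
    t = np.asarray(frames["t"], dtype=float) if "t" in frames else None
    return BallState(omega_yaw, omega_roll, omega_pitch, t=t)


def planar_velocity(state: BallState, calib: CalibrationParams) -> PlanarVelocity:
    """Planar walking velocity on the camera frame from ball rotation.

    xdot = l_s * omega_roll, ydot = l_s * omega_pitch; yaw does not enter
    (spinning in place produces no translation).
    """
    ls = calib.sphere_radius_mm
    xdot = ls * np.asarray(state.omega_roll, dtype=float)
    ydot = ls * np.asarray(state.omega_pitch, dtype=float)
    return PlanarVelocity(xdot, ydot, np.hypot(xdot, ydot), t=state.t)


def integrate_trajectory(
    vel: PlanarVelocity, angles: PoseAngles, dt: float | None = None
) -> Trajectory:
    """Dead-reckon the body-frame path with an explicit Euler update.

    Velocity and body-angle series must share a time grid (resample first).
    The update uses the rotated-frame arrangement

        dx = dt * (xdot*sin(theta) - ydot*cos(theta))
        dy = dt * (xdot*cos(theta) + ydot*sin(theta))

    with the origin as initial position.
    """
    t = np.asarray(angles.t, dtype=float)
    if vel.t is not None:
        tv = np.asarray(vel.t, dtype=float)
        if tv.shape != t.shape or not np.allclose(tv, t):
            raise ValueError("velocity and angle series must share a time grid")
    xdot = np.asarray(vel.xdot_cam, dtype=float)
    ydot = np.asarray(vel.ydot_cam, dtype=float)
    theta = np.asarray(angles.theta_body_cam, dtype=float)
    if not (xdot.shape == theta.shape == t.shape):
        raise ValueError("velocity and angle series must share a time grid")
    if dt is None:
        dt = float(np.mean(np.diff(t)))
    dx = dt * (xdot * np.sin(theta) - ydot * np.cos(theta))
    dy = dt * (xdot * np.cos(theta) + ydot * np.sin(theta))
    x = np.concatenate([[0.0], np.cumsum(dx[:-1])])
    y = np.concatenate([[0.0], np.cumsum(dy[:-1])])
    return Trajectory(t=t, x=x, y=y, dt=dt)


def synchronize_clocks(camera_events, logger_events) -> ClockMap:
    """Fit the affine map logger-clock -> camera-clock from paired LED events.

    With exactly two events only an offset and slope through the two points
    is determined; with three or more, ordinary least squares.  With two
    matched blink events the slope is fixed to 1 and only the offset fitted.
    """
    cam = np.asarray(camera_events, dtype=float).ravel()
    log = np.asarray(logger_events, dtype=float).ravel()
    if cam.size != log.size:
        raise ValueError("event lists must be matched pairs")
    if cam.size < 2:
        raise ValueError("need at least two matched events")
    if cam.size == 2:
        slope = 1.0
        offset = float(np.mean(cam - log))
    else:
        slope, offset = np.polyfit(log, cam, 1)
    resid = cam - (slope * log + offset)
    return ClockMap(
        slope=float(slope),
        offset=float(offset),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def pose_angles(pose: pd.DataFrame) -> PoseAngles:
    """Body and head angles from the tracked body-axis markers.

    The body axis is defined posterior->anterior (Meta -> Pro);
    ``theta_body_cam`` is its orientation in the camera frame and
    ``theta_head_cricket`` the orientation of Pro -> Head relative to that
    axis, both wrapped to (-pi, pi].

    ``pose`` is a marker table with column MultiIndex (bodypart, coord)
    as returned by :func:`cricketgait.io.read_pose_table`.
    """
    for marker in ("Head", "Pro", "Meta"):
        if marker not in pose.columns.get_level_values(0):
            raise ValueError(f"pose table is missing required marker '{marker}'")
    axis_x = pose[("Pro", "x")].to_numpy(float) - pose[("Meta", "x")].to_numpy(float)
    axis_y = pose[("Pro", "y")].to_numpy(float) - pose[("Meta", "y")].to_numpy(float)
    head_x = pose[("Head", "x")].to_numpy(float) - pose[("Pro", "x")].to_numpy(float)
    head_y = pose[("Head", "y")].to_numpy(float) - pose[("Pro", "y")].to_numpy(float)
    theta_body = np.arctan2(axis_y, axis_x)
    theta_head = wrap_to_pi(np.arctan2(head_y, head_x) - theta_body)
    if "t" in pose.index.names and pose.index.nlevels == 1:
        t = pose.index.to_numpy(float)
    else:
        t = np.arange(len(pose), dtype=float)
    return PoseAngles(t=t, theta_body_cam=wrap_to_pi(theta_body), theta_head_cricket=theta_head)


def normalize_body_length(values, body_length_mm: float):
    """Convert mm (or mm/s) quantities to body lengths (or BL/s)."""
    if body_length_mm <= 0:
        raise ValueError("body length must be positive")
    return np.asarray(values, dtype=float) / body_length_mm
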
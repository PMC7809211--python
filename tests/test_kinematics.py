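"""Ball angular velocities, planar velocity, trajectory, clocks, pose angles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cricketgait.kinematics import (
    CalibrationParams,
    BallState,
    PlanarVelocity,
    PoseAngles,
    angular_velocities,
    integrate_trajectory,
    normalize_body_length,
    planar_velocity,
    pose_angles,
    synchronize_clocks,
)
from cricketgait.synth import BallMotionProfile, generate_ball_sensor_log, generate_sync_events

UNIT_CALIB = CalibrationParams()


def _frame(dx1=0.0, dy1=0.0, dx2=0.0, dy2=0.0, rate=50.0):
    # per-second counts -> per-sample counts at the log rate
    return pd.DataFrame(
        {"t": [0.0], "dx1": [dx1 / rate], "dy1": [dy1 / rate],
         "dx2": [dx2 / rate], "dy2": [dy2 / rate]}
    )


class TestAngularVelocities:
    def test_zero_frame(self):
        st_ = angular_velocities(_frame(), UNIT_CALIB)
        assert st_.omega_yaw[0] == st_.omega_roll[0] == st_.omega_pitch[0] == 0.0

    def test_pure_yaw_hand_solved(self):
        # dx1 = dx2 = -1/(2 cos45) per second solves yaw=1, pitch=0
        d = -1.0 / (2.0 * np.cos(np.pi / 4))
        st_ = angular_velocities(_frame(dx1=d, dx2=d), UNIT_CALIB)
        assert st_.omega_yaw[0] == pytest.approx(1.0)
        assert st_.omega_pitch[0] == pytest.approx(0.0, abs=1e-12)
        assert st_.omega_roll[0] == pytest.approx(0.0, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        counts=st.tuples(*[st.floats(-5, 5) for _ in range(4)]),
        factor=st.floats(0.1, 10),
    )
    def test_linearity(self, counts, factor):
        dx1, dy1, dx2, dy2 = counts
        a = angular_velocities(_frame(dx1, dy1, dx2, dy2), UNIT_CALIB)
        b = angular_velocities(
            _frame(dx1 * factor, dy1 * factor, dx2 * factor, dy2 * factor), UNIT_CALIB
        )
        for name in ("omega_yaw", "omega_roll", "omega_pitch"):
            assert getattr(b, name)[0] == pytest.approx(
                factor * getattr(a, name)[0], abs=1e-9
            )

    def test_round_trip_from_generator(self):
        t = np.arange(0, 5, 0.02)
        prof = BallMotionProfile(
            t=t, omega_yaw=0.5 * np.sin(t), omega_roll=1 + np.cos(t),
            omega_pitch=0.3 * t,
        )
        calib = CalibrationParams(sigma_x1=0.7, sigma_y1=1.3, sigma_x2=0.9, sigma_y2=1.1)
        log = generate_ball_sensor_log(prof, calib, noise_sd=0.0)
        st_ = angular_velocities(log, calib)
        assert np.allclose(st_.omega_yaw, np.interp(st_.t, t, prof.omega_yaw), atol=1e-12)
        assert np.allclose(st_.omega_roll, np.interp(st_.t, t, prof.omega_roll), atol=1e-12)
        assert np.allclose(st_.omega_pitch, np.interp(st_.t, t, prof.omega_pitch), atol=1e-12)

    def test_singular_calibration_rejected(self):
        with pytest.raises(ValueError):
            CalibrationParams(sigma_x1=0.0)


class TestPlanarVelocity:
    @pytest.mark.parametrize(
        "roll,pitch,yaw,ls,expect_v",
        [
            (1.0, 0.0, 0.0, 50.0, 50.0),
            (0.0, 0.0, 10.0, 50.0, 0.0),  # yaw does not translate
            (3.0, 4.0, 0.0, 1.0, 5.0),
        ],
    )
    def test_speed(self, roll, pitch, yaw, ls, expect_v):
        calib = CalibrationParams(sphere_radius_mm=ls)
        state = BallState(np.array([yaw]), np.array([roll]), np.array([pitch]))
        vel = planar_velocity(state, calib)
        assert vel.v_cam[0] == pytest.approx(expect_v)
        assert vel.xdot_cam[0] == pytest.approx(ls * roll)
        assert vel.ydot_cam[0] == pytest.approx(ls * pitch)


class TestTrajectory:
    @staticmethod
    def _angles(t, theta):
        return PoseAngles(t=t, theta_body_cam=theta, theta_head_cricket=np.zeros_like(t))

    def test_zero_velocity_stays_at_origin(self):
        t = np.arange(0, 1, 0.02)
        vel = PlanarVelocity(np.zeros_like(t), np.zeros_like(t), np.zeros_like(t), t=t)
        traj = integrate_trajectory(vel, self._angles(t, np.zeros_like(t)))
        assert np.all(traj.x == 0) and np.all(traj.y == 0)

    def test_constant_velocity_heading_zero(self):
        # xdot = v, theta = 0 -> motion along +y: endpoint (0, 2v) after 2 s
        v, dt = 7.0, 0.02
        t = np.arange(0, 2 + dt / 2, dt)
        vel = PlanarVelocity(np.full_like(t, v), np.zeros_like(t), np.full_like(t, v), t=t)
        traj = integrate_trajectory(vel, self._angles(t, np.zeros_like(t)))
        assert traj.x[-1] == pytest.approx(0.0, abs=1e-12)
        assert traj.y[-1] == pytest.approx(2 * v)

    def test_uniform_rotation_closes_circle(self):
        # constant speed with heading sweeping 2*pi returns to the origin
        # within O(dt) of the Euler scheme (analytic path is a circle)
        v, T, dt = 5.0, 2.0, 0.001
        t = np.arange(0, T + dt / 2, dt)
        theta = 2 * np.pi * t / T
        vel = PlanarVelocity(np.full_like(t, v), np.zeros_like(t), np.full_like(t, v), t=t)
        traj = integrate_trajectory(vel, self._angles(t, theta))
        radius = v * T / (2 * np.pi)
        closure = np.hypot(traj.x[-1], traj.y[-1])
        assert closure < 20 * dt * v  # O(dt) closure error

    def test_grid_mismatch_rejected(self):
        t = np.arange(0, 1, 0.02)
        vel = PlanarVelocity(np.zeros(10), np.zeros(10), np.zeros(10), t=t[:10])
        with pytest.raises(ValueError):
            integrate_trajectory(vel, self._angles(t, np.zeros_like(t)))

    def test_straight_walk_is_straight(self):
        # zero yaw, constant heading: lateral RMS < 1% of path length
        t = np.arange(0, 10, 0.02)
        speed = 30.0 + 10.0 * np.sin(t)  # varying speed, fixed direction
        vel = PlanarVelocity(speed, np.zeros_like(t), speed, t=t)
        theta = np.full_like(t, 0.7)
        traj = integrate_trajectory(vel, self._angles(t, theta))
        path_len = np.sum(np.hypot(np.diff(traj.x), np.diff(traj.y)))
        heading = np.array([np.sin(0.7), np.cos(0.7)])
        lateral = traj.x * heading[1] - traj.y * heading[0]
        assert np.sqrt(np.mean(lateral**2)) < 0.01 * path_len


class TestClockSync:
    def test_identity(self):
        ev = np.array([0.0, 1.0, 2.0])
        m = synchronize_clocks(ev, ev)
        assert m.slope == pytest.approx(1.0)
        assert m.offset == pytest.approx(0.0, abs=1e-12)

    def test_constant_shift(self):
        cam = np.array([0.0, 1.0, 2.0])
        m = synchronize_clocks(cam, cam + 1.5)
        assert m.slope == pytest.approx(1.0)
        assert m.offset == pytest.approx(-1.5)
        assert m(cam + 1.5) == pytest.approx(cam)

    def test_recovers_offset_and_drift(self):
        cam, log = generate_sync_events(1.5, 1e-3, 10, seed=3)
        m = synchronize_clocks(cam, log)
        # logger = cam*(1+drift)+offset -> inverse slope/offset
        assert m.slope == pytest.approx(1.0 / (1 + 1e-3), abs=1e-6)
        assert m(log) == pytest.approx(cam, abs=1e-6)
        assert m.residual_rms < 1e-9

    def test_too_few_events(self):
        with pytest.raises(ValueError):
            synchronize_clocks([0.0], [1.0])


class TestPoseAngles:
    @staticmethod
    def _pose(meta, pro, head):
        cols = {}
        for name, (x, y) in (("Meta", meta), ("Pro", pro), ("Head", head)):
            cols[(name, "x")] = [x]
            cols[(name, "y")] = [y]
            cols[(name, "likelihood")] = [1.0]
        df = pd.DataFrame(cols)
        df.columns = pd.MultiIndex.from_tuples(df.columns)
        return df

    def test_straight_body(self):
        a = pose_angles(self._pose((0, 0), (0, 1), (0, 2)))
        assert a.theta_head_cricket[0] == pytest.approx(0.0, abs=1e-12)
        assert a.theta_body_cam[0] == pytest.approx(np.pi / 2)

    def test_head_30_degrees_off_axis(self):
        head = (np.cos(np.pi / 2 + np.pi / 6), 1 + np.sin(np.pi / 2 + np.pi / 6))
        a = pose_angles(self._pose((0, 0), (0, 1), head))
        assert a.theta_head_cricket[0] == pytest.approx(np.pi / 6)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(rot=st.floats(-3, 3))
    def test_rigid_rotation_equivariance(self, rot):
        pts = {"Meta": (0.0, 0.0), "Pro": (1.0, 0.5), "Head": (2.0, 0.4)}
        base = pose_angles(self._pose(pts["Meta"], pts["Pro"], pts["Head"]))
        c, s = np.cos(rot), np.sin(rot)
        rpts = {k: (c * x - s * y, s * x + c * y) for k, (x, y) in pts.items()}
        rotated = pose_angles(self._pose(rpts["Meta"], rpts["Pro"], rpts["Head"]))
        dbody = rotated.theta_body_cam[0] - base.theta_body_cam[0]
        assert np.cos(dbody - rot) == pytest.approx(1.0, abs=1e-9)
        assert rotated.theta_head_cricket[0] == pytest.approx(
            base.theta_head_cricket[0], abs=1e-9
        )

    def test_missing_marker(self):
        df = self._pose((0, 0), (0, 1), (0, 2)).drop(columns=[("Head", "x")], level=None)
        df = df.drop(columns="Head", level=0)
        with pytest.raises(ValueError, match="Head"):
            pose_angles(df)


class TestBodyLengthNormalization:
    def test_scaling_and_round_trip(self):
        assert normalize_body_length(50.0, 25.0) == pytest.approx(2.0)
        assert normalize_body_length(0.0, 25.0) == 0.0
        v = np.array([10.0, 20.0])
        assert np.allclose(normalize_body_length(v, 4.0) * 4.0, v)

    def test_invalid_bl(self):
        with pytest.raises(ValueError):
            normalize_body_length(1.0, 0.0)
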
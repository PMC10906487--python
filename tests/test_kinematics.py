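"""Burst-escape kinematics against closed-form motion."""

import math

import numpy as np
import pytest

from thermoperf.kinematics import (
    AttemptKinematics,
    KinematicsError,
    TrackTrajectory,
    analyze_cstart,
    calibrate,
    score_responsiveness,
    select_best,
    summarize_fish,
)
from thermoperf.synthetic import simulate_cstart_trajectory


def attempt(u, a, attempt_id="a"):
    return AttemptKinematics(
        fish_id="f", attempt_id=attempt_id, u_max_cms=u,
        u_max_bls=u / 10.0, a_max_ms2=a,
    )


class TestCalibration:
    def test_ratio(self):
        assert calibrate(30.0, 3.0) == 10.0
        assert calibrate(3.0, 3.0) == 1.0

    def test_nonpositive_rejected(self):
        with pytest.raises(KinematicsError):
            calibrate(0.0, 3.0)

    def test_calibration_scales_speeds_inversely(self):
        traj, _ = simulate_cstart_trajectory(
            v0_cms=40.0, accel_ms2=0.0, pixels_per_cm=10.0
        )
        halved = TrackTrajectory(
            fish_id=traj.fish_id,
            attempt_id=traj.attempt_id,
            stimulus_type=traj.stimulus_type,
            pre_contact_response=True,
            time_s=traj.time_s,
            x_px=traj.x_px,
            y_px=traj.y_px,
            fps=traj.fps,
            pixels_per_cm=5.0,
            cstart_onset=0.0,
        )
        u_full = analyze_cstart(traj, body_length=10.0).u_max_cms
        u_half = analyze_cstart(halved, body_length=10.0).u_max_cms
        assert u_half == pytest.approx(2 * u_full, rel=1e-9)


class TestAnalyzeCStart:
    def test_constant_velocity(self):
        traj, _ = simulate_cstart_trajectory(v0_cms=50.0, accel_ms2=0.0)
        k = analyze_cstart(traj, body_length=10.0)
        assert k.u_max_cms == pytest.approx(50.0, rel=1e-9)
        assert k.a_max_ms2 == pytest.approx(0.0, abs=1e-6)

    def test_constant_acceleration_closed_form(self):
        traj, truth = simulate_cstart_trajectory(
            v0_cms=0.0, accel_ms2=10.0, duration_s=0.075
        )
        k = analyze_cstart(traj, body_length=10.0)
        assert k.u_max_cms == pytest.approx(truth["u_max_cms"], rel=0.02)
        assert k.a_max_ms2 == pytest.approx(truth["a_max_ms2"], rel=0.02)

    def test_body_length_normalisation(self):
        traj, _ = simulate_cstart_trajectory(v0_cms=50.0, accel_ms2=0.0)
        k = analyze_cstart(traj, body_length=10.0)
        assert k.u_max_bls == pytest.approx(k.u_max_cms / 10.0, rel=1e-12)

    def test_missing_onset_excluded(self):
        traj, _ = simulate_cstart_trajectory(v0_cms=50.0, accel_ms2=0.0)
        traj.cstart_onset = None
        with pytest.raises(KinematicsError):
            analyze_cstart(traj, body_length=10.0)

    @pytest.mark.parametrize("angle_deg", [0.0, 37.0, 90.0, 211.5])
    def test_rigid_motion_invariance(self, angle_deg):
        traj, _ = simulate_cstart_trajectory(
            v0_cms=20.0, accel_ms2=8.0, heading_deg=10.0
        )
        base = analyze_cstart(traj, body_length=10.0)
        th = math.radians(angle_deg)
        x = traj.x_px * math.cos(th) - traj.y_px * math.sin(th) + 123.0
        y = traj.x_px * math.sin(th) + traj.y_px * math.cos(th) - 77.0
        moved = TrackTrajectory(
            fish_id="f", attempt_id="a", stimulus_type="tube_drop",
            pre_contact_response=True, time_s=traj.time_s, x_px=x, y_px=y,
            fps=traj.fps, pixels_per_cm=traj.pixels_per_cm, cstart_onset=0.0,
        )
        rot = analyze_cstart(moved, body_length=10.0)
        assert rot.u_max_cms == pytest.approx(base.u_max_cms, rel=1e-9)
        assert rot.a_max_ms2 == pytest.approx(base.a_max_ms2, abs=1e-9)


class TestBestAttemptSelection:
    def test_amax_taken_from_umax_attempt(self):
        # the faster attempt's (lower) acceleration is the one reported
        best = select_best([attempt(40.0, 8.0, "a1"), attempt(50.0, 6.0, "a2")])
        assert (best.u_max_cms, best.a_max_ms2) == (50.0, 6.0)

    def test_single_attempt(self):
        a = attempt(30.0, 5.0)
        assert select_best([a]) is a

    def test_tie_goes_to_earliest(self):
        first = attempt(40.0, 2.0, "a1")
        assert select_best([first, attempt(40.0, 9.0, "a2")]) is first


class TestResponsiveness:
    @pytest.mark.parametrize(
        "flags,expected",
        [
            ([True, True, False, False, False], 40.0),
            ([True] * 5, 100.0),
            ([False] * 5, 0.0),
        ],
    )
    def test_fraction_of_attempts(self, flags, expected):
        assert score_responsiveness(flags) == expected

    def test_zero_attempts_undefined(self):
        with pytest.raises(KinematicsError):
            score_responsiveness([])


class TestSummarizeFish:
    def test_unannotated_attempts_count_for_responsiveness_only(self):
        good, _ = simulate_cstart_trajectory(
            v0_cms=50.0, accel_ms2=0.0, attempt_id="a1"
        )
        contact, _ = simulate_cstart_trajectory(
            v0_cms=60.0,
            accel_ms2=0.0,
            attempt_id="a2",
            pre_contact_response=False,
        )
        contact.cstart_onset = None  # no usable kinematics
        result = summarize_fish([good, contact], body_length=10.0)
        assert result.responsiveness == 50.0
        assert result.best_attempt_id == "a1"

    def test_no_analyzable_attempts_returns_none(self):
        traj, _ = simulate_cstart_trajectory(v0_cms=50.0, accel_ms2=0.0)
        traj.cstart_onset = None
        assert summarize_fish([traj], body_length=10.0) is None

    def test_noiseless_roundtrip_recovers_acceleration(self):
        # generator -> kinematics closes to <2% (finite differencing)
        traj, truth = simulate_cstart_trajectory(
            v0_cms=12.0, accel_ms2=7.5, duration_s=0.09, noise_px=0.0
        )
        k = analyze_cstart(traj, body_length=8.8)
        assert k.a_max_ms2 == pytest.approx(truth["a_max_ms2"], rel=0.02)
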
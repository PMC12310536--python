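"""Gait and flight statistics against generator ground truth."""

import numpy as np
import pytest

from flysim.analysis import (
    ContractError,
    GaitRecord,
    circular_median,
    classify_wingbeats,
    mean_legs_in_stance,
    saccade_profile,
    swing_onset_phases,
    tracking_errors,
    turn_asymmetry,
)
from flysim.synth import (
    SynthFlightParams,
    SynthWalkParams,
    synth_flight_traj,
    synth_walk_track,
)
from flysim.walking import egocentric_tips, label_swing_stance
from flysim.rotations import quat_from_axis_angle


class TestTrackingErrors:
    def test_identical_trajectories_zero(self):
        pos = np.random.default_rng(0).normal(size=(20, 3))
        quat = np.tile([1.0, 0, 0, 0], (20, 1))
        s = tracking_errors(pos, quat, pos, quat)
        assert s["position"]["median"] == 0.0
        assert s["orientation_deg"]["median"] == 0.0

    def test_pure_yaw_offset(self):
        n = 10
        pos = np.zeros((n, 3))
        q1 = np.tile([1.0, 0, 0, 0], (n, 1))
        q2 = np.tile(quat_from_axis_angle([0, 0, 1.0], np.deg2rad(10.0)),
                     (n, 1))
        s = tracking_errors(pos, q1, pos, q2)
        assert s["orientation_deg"]["median"] == pytest.approx(10.0)
        assert s["position"]["median"] == 0.0

    def test_translation_offset(self):
        n = 8
        pos = np.zeros((n, 3))
        quat = np.tile([1.0, 0, 0, 0], (n, 1))
        s = tracking_errors(pos + [0.3, 0.4, 0.0], quat, pos, quat)
        assert np.allclose(s["position"]["per_frame"], 0.5)

    def test_symmetric_in_arguments(self, rng):
        pos1 = rng.normal(size=(15, 3))
        pos2 = rng.normal(size=(15, 3))
        quat1 = np.array(
            [quat_from_axis_angle(rng.normal(size=3), rng.uniform(0, 2))
             for _ in range(15)]
        )
        quat2 = np.array(
            [quat_from_axis_angle(rng.normal(size=3), rng.uniform(0, 2))
             for _ in range(15)]
        )
        a = tracking_errors(pos1, quat1, pos2, quat2)
        b = tracking_errors(pos2, quat2, pos1, quat1)
        assert a["position"]["median"] == b["position"]["median"]
        assert a["orientation_deg"]["median"] == pytest.approx(
            b["orientation_deg"]["median"]
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ContractError):
            tracking_errors(np.zeros((3, 3)), np.tile([1, 0, 0, 0.0], (3, 1)),
                            np.zeros((4, 3)), np.tile([1, 0, 0, 0.0], (4, 1)))


class TestStanceCounts:
    def test_all_stance_gives_six(self):
        rec = GaitRecord(np.ones((100, 6), bool), np.full(100, 1.0), 1 / 150)
        df = mean_legs_in_stance([rec])
        assert df.mean_legs_in_stance.iloc[0] == pytest.approx(6.0)

    @pytest.mark.parametrize("duty,expected", [(0.5, 3.0), (0.65, 3.9)])
    def test_tripod_generator_anchors(self, duty, expected):
        r = synth_walk_track(
            SynthWalkParams(speed=1.0, duty_factor=duty, duration=2.0, seed=2)
        )
        rec = GaitRecord(~r.swing, r.com_speed, r.track.dt)
        assert rec.stance.sum(axis=1).mean() == pytest.approx(
            expected, abs=1 / 60
        )

    def test_binning_by_speed(self):
        recs = []
        for speed in (0.6, 1.1, 2.6):
            r = synth_walk_track(
                SynthWalkParams(speed=speed, duration=1.0, seed=4)
            )
            recs.append(GaitRecord(~r.swing, r.com_speed, r.track.dt))
        df = mean_legs_in_stance(recs)
        assert len(df) == 3
        assert df.n_snippets.sum() == 3


class TestCircularStatistics:
    def test_median_of_tight_cluster(self):
        a = np.deg2rad([10.0, 12.0, 14.0])
        assert circular_median(a) == pytest.approx(np.deg2rad(12.0))

    def test_median_handles_wraparound(self):
        a = np.deg2rad([350.0, 355.0, 5.0])
        med = circular_median(a)
        assert med == pytest.approx(np.deg2rad(355.0))

    def test_rotation_of_origin_rotates_median(self, rng):
        a = rng.uniform(0, 1.0, 21)
        shift = 2.0
        m0 = circular_median(a)
        m1 = circular_median((a + shift) % (2 * np.pi))
        assert (m1 - m0) % (2 * np.pi) == pytest.approx(shift, abs=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ContractError):
            circular_median([])


@pytest.fixture(scope="module")
def tripod():
    return synth_walk_track(SynthWalkParams(speed=2.0, duration=3.0, seed=5))


class TestSwingOnsetPhases:
    def test_reference_leg_phase_is_zero(self, tripod):
        phases = swing_onset_phases(tripod.swing)
        assert np.allclose(phases[0], 0.0)

    def test_tripod_groups_at_zero_and_pi(self, tripod):
        phases = swing_onset_phases(tripod.swing)
        # L1 (ref), R2, L3 share the tripod; R1, L2, R3 are antiphase
        for leg in (3, 4):  # R2=3, L3=4
            assert circular_median(phases[leg]) == pytest.approx(0.0,
                                                                 abs=0.1)
        for leg in (1, 2, 5):
            assert circular_median(phases[leg]) == pytest.approx(np.pi,
                                                                 abs=0.1)

    def test_time_origin_invariance(self, tripod):
        p0 = swing_onset_phases(tripod.swing)
        p1 = swing_onset_phases(tripod.swing[37:])
        for leg in range(6):
            if p0[leg].size and p1[leg].size:
                assert circular_median(p0[leg]) == pytest.approx(
                    circular_median(p1[leg]), abs=0.15
                )

    def test_never_swinging_reference_rejected(self):
        swing = np.zeros((100, 6), bool)
        swing[10:20, 1] = True
        with pytest.raises(ContractError):
            swing_onset_phases(swing, reference_leg=0)


class TestTurnAsymmetry:
    def test_straight_walking_is_symmetric(self):
        r = synth_walk_track(SynthWalkParams(speed=2.0, duration=3.0, seed=6))
        tips = egocentric_tips(r.track.keypoints)
        assert abs(turn_asymmetry(tips, r.swing)) < 0.01

    def test_imposed_stride_scaling_recovered(self):
        # left turn with radius chosen so inside (left) strides shrink ~20%
        radius = 0.55  # cm: home y ~0.11 -> 1 - y/R = 0.8
        r = synth_walk_track(
            SynthWalkParams(speed=2.0, turn_radius=radius, duration=3.0,
                            seed=8)
        )
        tips = egocentric_tips(r.track.keypoints)
        delta = turn_asymmetry(tips, r.swing)
        stride = 2.0 / 7.5
        duty = 0.5
        # the egocentric swing displacement of a leg is duty x its stride
        # (the stance sweep it must recover); per-side strides scale by
        # (1 -+ y_home / R), so left - right = -2 duty stride y_mean / R
        y_mean = np.mean([0.10, 0.13, 0.11])
        expected = -2 * duty * stride * y_mean / radius
        assert delta == pytest.approx(expected, rel=0.2)
        assert delta < 0

    def test_sign_flips_with_turn_direction(self):
        left = synth_walk_track(
            SynthWalkParams(speed=2.0, turn_radius=1.0, duration=3.0, seed=9)
        )
        right = synth_walk_track(
            SynthWalkParams(speed=2.0, turn_radius=-1.0, duration=3.0, seed=9)
        )
        d_left = turn_asymmetry(
            egocentric_tips(left.track.keypoints), left.swing
        )
        d_right = turn_asymmetry(
            egocentric_tips(right.track.keypoints), right.swing
        )
        assert d_left < 0 < d_right
        assert d_left == pytest.approx(-d_right, rel=0.2)


class TestSaccadeProfile:
    def test_identical_copies_give_that_trajectory(self):
        traj = synth_flight_traj(SynthFlightParams(template="saccade"))
        prof = saccade_profile([traj, traj, traj], window=40)
        assert np.allclose(prof["speed"]["median"], prof["speed"]["p25"])

    def test_yaw_rate_peak_recovered(self):
        p = SynthFlightParams(template="saccade", saccade_yaw_deg=90.0,
                              saccade_duration=0.05)
        traj = synth_flight_traj(p)
        prof = saccade_profile([traj], window=60)
        # peak yaw rate of the tanh heading profile: total/(2 tau)
        expected_peak = np.deg2rad(90.0) / (2 * p.saccade_duration / 6.0)
        peak = np.max(np.abs(prof["omega_z"]["median"]))
        assert peak == pytest.approx(expected_peak, rel=0.05)

    def test_alignment_at_peak_acceleration(self):
        traj = synth_flight_traj(SynthFlightParams(template="saccade"))
        from flysim.analysis import _kinematics

        _, a, _, _ = _kinematics(traj)
        peak = int(np.argmax(np.linalg.norm(a, axis=1)))
        assert 0 < peak < traj.n_frames - 1

    def test_hover_excluded_with_warning(self, caplog):
        hover = synth_flight_traj(SynthFlightParams(template="hover"))
        with pytest.raises(ContractError):
            with caplog.at_level("WARNING"):
                saccade_profile([hover], window=10)
        assert any("flat-acceleration" in r.message for r in caplog.records)


class TestWingbeatClassification:
    def _traces(self, n_beats=10, accel=None):
        f = 218.0
        dt = 2e-4
        t = np.arange(int(n_beats / f / dt)) * dt
        stroke = 1.2 * np.cos(2 * np.pi * f * t)
        if accel is None:
            accel = np.zeros_like(t)
        return t, stroke, accel

    def test_zero_acceleration_hover_all_steady(self):
        t, stroke, accel = self._traces()
        out = classify_wingbeats(t, stroke, accel)
        assert out["unsteady_beats"].size == 0

    def test_threshold_zero_all_unsteady(self):
        t, stroke, _ = self._traces()
        accel = np.full_like(t, 0.5)
        out = classify_wingbeats(t, stroke, accel, threshold=0.0)
        assert out["steady_beats"].size == 0

    def test_bimodal_acceleration_split_matches_construction(self):
        t, stroke, _ = self._traces(n_beats=12)
        f = 218.0
        beat_of = (t * f).astype(int)
        accel = np.where(beat_of % 2 == 0, 0.1, 5.0)
        out = classify_wingbeats(t, stroke, accel)
        # alternating construction: half the beats on each side
        assert abs(out["steady_beats"].size - out["unsteady_beats"].size) <= 1
        assert out["steady_median_cycle"] is not None
        assert out["unsteady_median_cycle"] is not None
        assert out["steady_median_cycle"].shape == out["phase"].shape
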
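import numpy as np
import pytest

import stsbiomech as sb
from stsbiomech.body import forward_kinematics
from stsbiomech.errors import InvalidDataError, NumericalFailureError
from stsbiomech.kinematics import (KinematicSeries, UKFConfig,
                                   filter_and_differentiate,
                                   segment_and_kinematics)
from stsbiomech.synthetic import JointTrajectory


class TestUKFInverseKinematics:
    def test_noiseless_round_trip_recovers_generating_angles(
            self, noiseless_trial, linkage):
        traj, truth = noiseless_trial
        kin = sb.ukf_inverse_kinematics(traj, linkage,
                                        UKFConfig(measurement_noise_sd=0.0))
        rmse = np.sqrt(np.mean((kin.joint_angles - truth["joint_angles"]) ** 2))
        assert rmse < 0.01

    def test_static_pose_matches_closed_form_geometry(self, linkage):
        phi = np.array([0.05, -1.2, 0.1, 0.3])
        n = 90
        pos = np.tile(forward_kinematics(linkage, phi), (n, 1, 1))
        traj = JointTrajectory("s", "t", np.arange(n) / 30.0, pos, 30.0)
        kin = sb.ukf_inverse_kinematics(traj, linkage,
                                        UKFConfig(measurement_noise_sd=0.0))
        expected = np.concatenate([[phi[0]], np.diff(phi)])
        assert np.allclose(kin.joint_angles[10:], expected, atol=1e-3)

    def test_smoothing_reduces_landmark_error_below_raw(self, noisy_trial, linkage):
        traj, truth = noisy_trial
        kin = sb.ukf_inverse_kinematics(traj, linkage)
        raw = np.sqrt(np.mean((traj.positions - truth["positions"]) ** 2))
        reprojected = np.sqrt(np.mean((kin.reprojected - truth["positions"]) ** 2))
        assert reprojected < raw

    def test_estimate_improves_as_noise_shrinks(self, profile, linkage):
        strategy = sb.default_strategy_for_group("control")
        errs = []
        for noise in (0.03, 0.01, 0.0):
            traj, truth = sb.simulate_sts_trial(profile, linkage, strategy,
                                                noise_sd=noise, seed=3,
                                                return_truth=True)
            kin = sb.ukf_inverse_kinematics(
                traj, linkage, UKFConfig(measurement_noise_sd=noise))
            errs.append(np.sqrt(np.mean(
                (kin.joint_angles - truth["joint_angles"]) ** 2)))
        assert errs[0] > errs[1] > errs[2]

    def test_reprojection_obeys_link_length_constancy(self, noisy_trial, linkage):
        traj, _ = noisy_trial
        kin = sb.ukf_inverse_kinematics(traj, linkage)
        dists = np.linalg.norm(np.diff(kin.reprojected, axis=1), axis=2)
        assert np.all(np.abs(dists - linkage.lengths) < 1e-6)

    def test_nonfinite_input_rejected(self, noisy_trial, linkage):
        traj, _ = noisy_trial
        bad = JointTrajectory(traj.subject_id, traj.trial_id, traj.t,
                              traj.positions.copy(), traj.sample_rate)
        bad.positions[5, 2, 0] = np.nan
        with pytest.raises(InvalidDataError):
            sb.ukf_inverse_kinematics(bad, linkage)

    def test_divergent_measurements_raise_with_frame_index(self, noiseless_trial,
                                                           linkage):
        traj, _ = noiseless_trial
        pos = traj.positions.copy()
        pos[30:] += 5.0  # teleporting landmarks the chain cannot reach
        jump = JointTrajectory(traj.subject_id, traj.trial_id, traj.t, pos,
                               traj.sample_rate)
        with pytest.raises(NumericalFailureError, match="frame"):
            sb.ukf_inverse_kinematics(jump, linkage)


class TestFilterAndDifferentiate:
    @staticmethod
    def _series(signal, fs=30.0):
        n = len(signal)
        q = np.tile(np.asarray(signal, float)[:, None], (1, 4))
        return KinematicSeries(t=np.arange(n) / fs, joint_angles=q,
                               world_angles=np.cumsum(q, axis=1), sample_rate=fs)

    def test_ramp_angle_gives_constant_velocity(self):
        t = np.arange(0, 10, 1 / 30)
        out = filter_and_differentiate(self._series(0.5 * t))
        interior = out.joint_velocities[len(t) // 4: 3 * len(t) // 4, 0]
        assert np.allclose(interior, 0.5, rtol=0.01)

    def test_constant_angle_gives_zero_derivatives(self):
        out = filter_and_differentiate(self._series(np.full(300, 0.7)))
        assert np.allclose(out.joint_velocities, 0.0, atol=1e-10)
        assert np.allclose(out.joint_accelerations, 0.0, atol=1e-8)

    @pytest.mark.parametrize("freq,bound,mode", [
        (1.0, 0.05, "pass"),    # < 5% attenuation in the passband
        (10.0, 0.90, "stop"),   # > 90% attenuation past cutoff
    ])
    def test_butterworth_magnitude_response(self, freq, bound, mode):
        t = np.arange(0, 10, 1 / 30)
        out = filter_and_differentiate(self._series(np.sin(2 * np.pi * freq * t)))
        n = len(t)
        amp = np.abs(out.joint_angles[n // 4: 3 * n // 4, 0]).max()
        if mode == "pass":
            assert amp > 1.0 - bound
        else:
            assert amp < 1.0 - bound

    def test_shift_equivariance_away_from_edges(self):
        t = np.arange(0, 12, 1 / 30)
        sig = np.sin(2 * np.pi * 0.8 * t) + 0.3 * np.sin(2 * np.pi * 1.7 * t)
        shift = 30
        a = filter_and_differentiate(self._series(sig))
        b = filter_and_differentiate(self._series(np.roll(sig, shift)))
        inner = slice(3 * shift, len(t) - 3 * shift)
        assert np.allclose(a.joint_velocities[inner, 0],
                           b.joint_velocities[inner.start + shift:
                                              inner.stop + shift, 0], atol=1e-6)

    def test_short_series_rejected(self):
        with pytest.raises(InvalidDataError):
            filter_and_differentiate(self._series(np.zeros(5)))


class TestSegmentKinematics:
    def test_upright_static_stance_is_quiet(self, static_series, linkage):
        kin = static_series(np.zeros(4), linkage)
        for frame in ("world", "body", "joint"):
            assert np.allclose(kin.com_vel[frame], 0.0)
        assert np.allclose(kin.sva, 0.0, atol=1e-12)

    def test_torso_world_angle_is_sum_of_joint_angles(self, processed_trial):
        kin, _, _, _ = processed_trial
        assert np.allclose(kin.world_angles[:, 3], kin.joint_angles.sum(axis=1),
                           atol=1e-12)

    def test_com_velocity_is_derivative_of_com_position(self, linkage):
        """Chain-rule velocities agree with finite differences of position.

        Checked at dense sampling so the central-difference truncation
        error (O(dt^2) on a dynamic rise) sits well below the tolerance.
        """
        from stsbiomech.synthetic import strategy_world_angles
        fs = 240.0
        dt = 1 / fs
        strat = sb.default_strategy_for_group("control")
        t = np.arange(0, 3.5, dt)
        phi = strategy_world_angles(strat, t)
        q = np.column_stack([phi[:, 0], np.diff(phi, axis=1)])
        qd = np.gradient(q, dt, axis=0)
        qdd = np.gradient(qd, dt, axis=0)
        kin = sb.KinematicSeries(
            t=t, joint_angles=q, world_angles=phi,
            joint_velocities=qd, joint_accelerations=qdd,
            world_velocities=np.cumsum(qd, axis=1),
            world_accelerations=np.cumsum(qdd, axis=1), sample_rate=fs)
        kin = segment_and_kinematics(kin, linkage)
        fd = np.gradient(kin.com_pos, dt, axis=0)
        inner = slice(int(0.5 * fs), len(t) - int(0.5 * fs))
        assert np.allclose(kin.com_vel["world"][inner], fd[inner], atol=1e-3)

    def test_body_frame_is_rotation_of_world_frame(self, processed_trial):
        kin, _, _, _ = processed_trial
        norms_w = np.linalg.norm(kin.com_vel["world"], axis=2)
        norms_b = np.linalg.norm(kin.com_vel["body"], axis=2)
        assert np.allclose(norms_w, norms_b, atol=1e-10)

    def test_requires_derivatives(self, linkage, noiseless_trial):
        traj, _ = noiseless_trial
        kin = sb.ukf_inverse_kinematics(traj, linkage,
                                        UKFConfig(measurement_noise_sd=0.0))
        with pytest.raises(InvalidDataError):
            segment_and_kinematics(kin, linkage)


class TestEventDetection:
    def test_events_are_ordered_and_bracket_the_rise(self, processed_trial):
        kin, _, _, events = processed_trial
        assert 0 <= events.start <= events.seatoff < events.end < kin.n_frames
        # movement onset after the seated lead-in begins, before 1 s
        assert kin.t[events.start] < 1.0
        # standing is reached before the trace ends
        assert kin.t[events.end] > kin.t[events.seatoff] + 0.5

    def test_quiet_series_has_no_onset(self, static_series, linkage):
        kin = static_series([0.0, -1.5, 0.1, 0.2], linkage, n=90)
        with pytest.raises(InvalidDataError):
            sb.detect_events(kin, linkage)
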
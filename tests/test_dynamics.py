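import numpy as np
import pytest
from dataclasses import replace

import stsbiomech as sb
from stsbiomech.dynamics import (DynamicsSeries, chain_energy,
                                 forward_simulate_tracking,
                                 generalized_inverse_dynamics, work_integrals)
from stsbiomech.errors import InvalidArgumentError, InvalidDataError
from stsbiomech.kinematics import (KinematicSeries, filter_and_differentiate,
                                   segment_and_kinematics)
from stsbiomech.synthetic import strategy_world_angles


class TestStaticsLimit:
    def test_upright_stack_carries_weight_with_zero_torque(self, static_series,
                                                           linkage):
        kin = static_series(np.zeros(4), linkage)
        dyn = sb.inverse_dynamics(kin, linkage)
        assert np.allclose(dyn.torque, 0.0, atol=1e-9)
        assert np.allclose(dyn.reaction[:, 0, 1],
                           linkage.segment_mass_total * linkage.gravity)
        assert np.allclose(dyn.reaction[:, 0, 0], 0.0, atol=1e-9)

    def test_leaned_torso_matches_hand_statics(self, static_series, linkage):
        angle = np.pi / 6
        kin = static_series([0.0, 0.0, 0.0, angle], linkage)
        dyn = sb.inverse_dynamics(kin, linkage)
        torso = linkage.segments["torso"]
        expected = torso.mass * linkage.gravity * torso.com_offset * np.sin(angle)
        assert np.allclose(dyn.torque[:, 3], expected, atol=1e-6)

    def test_gravity_enters_linearly(self, static_series, linkage):
        from stsbiomech.body import LinkageModel
        kin = static_series([0.1, -0.4, 0.2, 0.5], linkage)
        double_g = LinkageModel(segments=linkage.segments,
                                gravity=2 * linkage.gravity,
                                height=linkage.height,
                                total_mass=linkage.total_mass)
        tau_g = sb.inverse_dynamics(kin, linkage).torque
        tau_2g = sb.inverse_dynamics(kin, double_g).torque
        assert np.allclose(tau_2g, 2 * tau_g, atol=1e-9)

    def test_missing_accelerations_rejected(self, linkage):
        kin = KinematicSeries(t=np.arange(30) / 30.0,
                              joint_angles=np.zeros((30, 4)),
                              world_angles=np.zeros((30, 4)))
        with pytest.raises(InvalidDataError):
            sb.inverse_dynamics(kin, linkage)


class TestDynamicConsistency:
    def test_newton_euler_agrees_with_lagrangian_route(self, linkage):
        """Two independent derivations of the same joint torques."""
        fs = 240.0
        strat = sb.default_strategy_for_group("control")
        t = np.arange(0, 3.0, 1 / fs)
        phi = strategy_world_angles(strat, t)
        q = np.column_stack([phi[:, 0], np.diff(phi, axis=1)])
        kin = KinematicSeries(t=t, joint_angles=q, world_angles=phi, sample_rate=fs)
        kin = segment_and_kinematics(
            filter_and_differentiate(kin, cutoff=10.0), linkage)
        tau_ne = sb.inverse_dynamics(kin, linkage).torque
        tau_lag = generalized_inverse_dynamics(
            linkage, kin.world_angles, kin.world_velocities,
            kin.world_accelerations)
        inner = slice(int(0.4 * fs), len(t) - int(0.4 * fs))
        assert np.allclose(tau_ne[inner], tau_lag[inner], atol=1e-6)

    def test_energy_balance_on_simulated_rise(self, linkage):
        fs = 240.0
        strat = sb.default_strategy_for_group("control")
        t = np.arange(0, 0.5 + strat.duration / strat.momentum_scale + 1.0, 1 / fs)
        phi = strategy_world_angles(strat, t)
        q = np.column_stack([phi[:, 0], np.diff(phi, axis=1)])
        kin = KinematicSeries(t=t, joint_angles=q, world_angles=phi, sample_rate=fs)
        kin = segment_and_kinematics(
            filter_and_differentiate(kin, cutoff=8.0), linkage)
        dyn = sb.joint_powers(sb.inverse_dynamics(kin, linkage), kin)
        E = chain_energy(linkage, kin.world_angles, kin.world_velocities)
        inner = slice(int(0.4 * fs), len(t) - int(0.4 * fs))
        net_work = np.trapezoid(dyn.power[inner].sum(axis=1), t[inner])
        dE = E[inner][-1] - E[inner][0]
        assert abs(net_work - dE) < 0.05 * abs(dE)

    def test_forward_simulation_then_inverse_dynamics_recovers_torques(
            self, linkage):
        """Known-torque round trip through the full estimation pipeline."""
        from stsbiomech.body import forward_kinematics
        from stsbiomech.kinematics import UKFConfig
        from stsbiomech.synthetic import JointTrajectory, StrategyParams
        from stsbiomech.dynamics import torque_recovery_errors

        strat = StrategyParams(peak_torso_lean=0.4, momentum_scale=1.0,
                               duration=3.0)
        fs = 30.0
        t = np.arange(0, 4.5, 1 / fs)
        phi_ref = strategy_world_angles(strat, t)

        def estimate(phi, tt):
            pos = forward_kinematics(linkage, phi)
            traj = JointTrajectory("sim", "T1", tt, pos, fs)
            kin = sb.ukf_inverse_kinematics(
                traj, linkage,
                UKFConfig(measurement_noise_sd=0.0, process_noise=200.0))
            kin = segment_and_kinematics(filter_and_differentiate(kin), linkage)
            return sb.inverse_dynamics(kin, linkage).torque

        rmse, peak = torque_recovery_errors(linkage, phi_ref, t, estimate)
        assert np.all(rmse < 0.02 * peak)

    def test_tracking_simulation_follows_the_reference(self, linkage):
        strat = sb.default_strategy_for_group("control")
        t = np.arange(0, 3.5, 1 / 30.0)
        phi_ref = strategy_world_angles(strat, t)
        phi, _, _ = forward_simulate_tracking(linkage, t, phi_ref)
        assert np.abs(phi - phi_ref).max() < 0.05


class TestJointPowers:
    def test_zero_velocity_means_zero_power(self, static_series, linkage):
        kin = static_series([0.0, -0.5, 0.2, 0.4], linkage)
        dyn = sb.joint_powers(sb.inverse_dynamics(kin, linkage), kin)
        assert np.allclose(dyn.power, 0.0)

    def test_extension_torque_with_extension_motion_is_concentric(self, linkage):
        n = 30
        kin = KinematicSeries(
            t=np.arange(n) / 30.0, joint_angles=np.full((n, 4), 0.3),
            world_angles=np.cumsum(np.full((n, 4), 0.3), axis=1),
            joint_velocities=np.full((n, 4), -0.5),   # flexion angle decreasing
            joint_accelerations=np.zeros((n, 4)),
            world_velocities=np.full((n, 4), -0.5).cumsum(axis=1),
            world_accelerations=np.zeros((n, 4)))
        dyn = DynamicsSeries(t=kin.t, torque=np.full((n, 4), 10.0),
                             reaction=np.zeros((n, 4, 2)))
        out = sb.joint_powers(dyn, kin)
        assert np.all(out.power > 0)


class TestWorkIntegrals:
    def test_constant_power_rectangle(self):
        n = 31
        t = np.linspace(0.0, 1.0, n)
        dyn = DynamicsSeries(t=t, torque=np.zeros((n, 4)),
                             reaction=np.zeros((n, 4, 2)),
                             power=np.full((n, 4), 10.0))
        ws = work_integrals(dyn)
        assert np.allclose(ws.concentric, 10.0)
        assert np.allclose(ws.eccentric, 0.0)

    def test_sinusoidal_power_cancels_over_a_period(self):
        t = np.linspace(0.0, 1.0, 2001)
        p = np.tile(np.sin(2 * np.pi * t)[:, None], (1, 4))
        dyn = DynamicsSeries(t=t, torque=np.zeros((2001, 4)),
                             reaction=np.zeros((2001, 4, 2)), power=p)
        ws = work_integrals(dyn)
        assert np.allclose(ws.concentric, -ws.eccentric, atol=1e-6)
        assert np.allclose(ws.net, 0.0, atol=1e-6)

    def test_split_parts_sum_to_net_on_random_series(self):
        rng = np.random.default_rng(3)
        t = np.arange(100) / 30.0
        p = rng.normal(size=(100, 4))
        dyn = DynamicsSeries(t=t, torque=np.zeros((100, 4)),
                             reaction=np.zeros((100, 4, 2)), power=p)
        ws = work_integrals(dyn, window=(5, 90))
        direct = np.trapezoid(p[5:91], t[5:91], axis=0)
        assert np.allclose(ws.net, direct, atol=1e-9)

    def test_empty_window_rejected(self):
        dyn = DynamicsSeries(t=np.arange(10) / 30.0, torque=np.zeros((10, 4)),
                             reaction=np.zeros((10, 4, 2)),
                             power=np.zeros((10, 4)))
        with pytest.raises(InvalidArgumentError):
            work_integrals(dyn, window=(4, 4))


class TestNormalization:
    def test_known_value(self, processed_trial, profile):
        _, dyn, _, _ = processed_trial
        scaled = replace(dyn, torque=np.full_like(dyn.torque, 100.0))
        out = sb.normalize_dynamics(scaled, profile)
        assert np.allclose(out.torque_norm, 100.0 / (70.0 * 9.81 * 1.75))

    def test_round_trip_is_identity(self, processed_trial, profile):
        _, dyn, _, _ = processed_trial
        back = sb.denormalize_dynamics(sb.normalize_dynamics(dyn, profile),
                                       profile)
        assert np.allclose(back.torque, dyn.torque, atol=1e-12)
        assert np.allclose(back.power, dyn.power, atol=1e-12)

    def test_normalized_torque_is_size_invariant(self, static_series):
        angle = [0.0, 0.0, 0.0, 0.4]
        results = []
        for mass in (60.0, 120.0):
            link = sb.scale_segments(1, 1.75, mass)
            prof = sb.SubjectProfile("s", "control", 1, 30.0, 1.75, mass,
                                     mass / 1.75**2)
            kin = static_series(angle, link)
            dyn = sb.normalize_dynamics(sb.inverse_dynamics(kin, link), prof)
            results.append(dyn.torque_norm[0])
        assert np.allclose(results[0], results[1], atol=1e-12)

    def test_nonpositive_mass_rejected(self, processed_trial):
        _, dyn, _, _ = processed_trial
        with pytest.raises(Exception):
            sb.SubjectProfile("bad", "control", 1, 30.0, 1.75, -5.0, 20.0)
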
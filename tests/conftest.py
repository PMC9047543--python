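"""Shared fixtures: one scaled linkage, one subject, and processed trials."""

from __future__ import annotations

import numpy as np
import pytest

import stsbiomech as sb
from stsbiomech.kinematics import (UKFConfig, filter_and_differentiate,
                                   segment_and_kinematics)


@pytest.fixture(scope="session")
def linkage():
    return sb.scale_segments(sex=1, height=1.75, mass=70.0)


@pytest.fixture(scope="session")
def profile():
    return sb.SubjectProfile("S001", "control", 1, 30.0, 1.75, 70.0,
                             70.0 / 1.75**2)


@pytest.fixture(scope="session")
def patient_profile():
    return sb.SubjectProfile("P001", "sdlbp", 0, 62.0, 1.62, 68.0,
                             68.0 / 1.62**2, vas=7.0, odi=50.0)


@pytest.fixture(scope="session")
def noiseless_trial(profile, linkage):
    """One clean control trial plus its generating angles."""
    strategy = sb.default_strategy_for_group("control")
    return sb.simulate_sts_trial(profile, linkage, strategy, noise_sd=0.0,
                                 seed=7, return_truth=True)


@pytest.fixture(scope="session")
def noisy_trial(profile, linkage):
    strategy = sb.default_strategy_for_group("control")
    return sb.simulate_sts_trial(profile, linkage, strategy, noise_sd=0.018,
                                 seed=7, return_truth=True)


def full_kinematics(traj, linkage, measurement_noise_sd):
    kin = sb.ukf_inverse_kinematics(
        traj, linkage, UKFConfig(measurement_noise_sd=measurement_noise_sd))
    kin = filter_and_differentiate(kin)
    return segment_and_kinematics(kin, linkage)


@pytest.fixture(scope="session")
def processed_trial(noiseless_trial, linkage, profile):
    """Kinematics, dynamics and spine loads of the clean control trial."""
    traj, truth = noiseless_trial
    kin = full_kinematics(traj, linkage, measurement_noise_sd=0.0)
    dyn = sb.inverse_dynamics(kin, linkage)
    dyn = sb.joint_powers(dyn, kin)
    dyn = sb.normalize_dynamics(dyn, profile)
    loads = sb.l5s1_loads(dyn, kin)
    loads = sb.normalize_spine_loads(loads, profile)
    events = sb.detect_events(kin, linkage)
    return kin, dyn, loads, events


@pytest.fixture(scope="session")
def static_series():
    """Factory for constant-pose kinematic series with zero derivatives."""

    def make(joint_angles, linkage, n=20, fs=30.0):
        q = np.tile(np.asarray(joint_angles, float), (n, 1))
        kin = sb.KinematicSeries(
            t=np.arange(n) / fs, joint_angles=q, world_angles=np.cumsum(q, axis=1),
            joint_velocities=np.zeros((n, 4)), joint_accelerations=np.zeros((n, 4)),
            world_velocities=np.zeros((n, 4)), world_accelerations=np.zeros((n, 4)),
            sample_rate=fs)
        return segment_and_kinematics(kin, linkage)

    return make
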
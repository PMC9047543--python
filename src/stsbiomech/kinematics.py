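"""Inverse kinematics and kinematic post-processing of the four-link chain.

Stage 1 (:func:`ukf_inverse_kinematics`) estimates joint angles from noisy
landmark positions with an unscented Kalman filter whose measurement model
is the forward kinematics of the scaled linkage; the state is the four
joint angles plus their rates under a constant-velocity process model.

Stage 2 (:func:`filter_and_differentiate`) produces angular velocities and
accelerations by sequential zero-phase second-order Butterworth low-pass
filtering (5 Hz default) and central-difference differentiation: the
signal is filtered before each differentiation stage so that noise
amplification is suppressed per stage.

Stage 3 (:func:`segment_and_kinematics`) propagates segment
center-of-mass positions, velocities and accelerations in a forward
recursion from the joint-angle derivatives, expresses them in world, body
and joint reference frames, and computes the planar sagittal-vertical-axis
(SVA) surrogate: the anterior offset of the torso-end landmark from the
ankle.

Sign conventions (fixed throughout the package): the anterior direction is
+x, vertical is +y; world segment angles are measured from the upward
vertical, positive tilting anterior; joint angles are differences of
adjacent world angles, so flexion (forward bending) is positive at the
hip and L5S1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .body import JOINTS, LANDMARKS, SEGMENTS, LinkageModel, forward_kinematics
from .errors import InvalidArgumentError, InvalidDataError, NumericalFailureError
from .synthetic import JointTrajectory

FRAMES = ("world", "body", "joint")


@dataclass
class KinematicSeries:
    """Per-frame joint and segment kinematics for one trial.

    Arrays indexed ``(frame, joint-or-segment[, component])``; joint order
    ankle/knee/hip/L5S1, segment order shank/thigh/pelvis/torso.  ``com_vel``
    and ``com_acc`` map each reference frame ("world", "body", "joint") to an
    (n, 4, 2) array with (anterior, vertical) components; ``com_pos`` is
    world-frame only.
    """

    t: np.ndarray
    joint_angles: np.ndarray                    # (n, 4), rad
    world_angles: np.ndarray                    # (n, 4), rad
    reprojected: np.ndarray | None = None       # (n, 5, 2), m
    joint_velocities: np.ndarray | None = None  # (n, 4), rad/s
    joint_accelerations: np.ndarray | None = None
    world_velocities: np.ndarray | None = None
    world_accelerations: np.ndarray | None = None
    com_pos: np.ndarray | None = None           # (n, 4, 2), m (world)
    com_vel: dict[str, np.ndarray] = field(default_factory=dict)
    com_acc: dict[str, np.ndarray] = field(default_factory=dict)
    sva: np.ndarray | None = None               # (n,), m
    sample_rate: float = 30.0
    innovation_rms: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class UKFConfig:
    """Unscented-filter settings.

    ``process_noise`` is the continuous white-angular-acceleration spectral
    density (rad^2/s^3) of the constant-velocity process model;
    ``measurement_noise_sd`` should match the landmark noise scale (m) and
    is floored at ``min_measurement_sd`` so noiseless data stay well
    conditioned.
    """

    process_noise: float = 50.0
    measurement_noise_sd: float = 0.018
    min_measurement_sd: float = 1e-3
    alpha: float = 1e-3
    beta: float = 2.0
    kappa: float = 0.0
    divergence_innovation: float = 0.25   # m, RMS innovation threshold
    divergence_frames: int = 10


def _geometric_angles(positions: np.ndarray) -> np.ndarray:
    """Closed-form world angles from one frame of landmark positions."""
    seg = np.diff(positions, axis=0)          # (4, 2)
    return np.arctan2(seg[:, 0], seg[:, 1])   # angle from vertical, anterior positive


def ukf_inverse_kinematics(
    traj: JointTrajectory,
    linkage: LinkageModel,
    config: UKFConfig | None = None,
) -> KinematicSeries:
    """Smoothed joint-angle estimates from noisy landmark positions.

    Returns a :class:`KinematicSeries` with angles and re-projected
    landmark positions only; derivatives are added by
    :func:`filter_and_differentiate`.

    Raises
    ------
    InvalidDataError
        If the trajectory contains non-finite coordinates.
    NumericalFailureError
        If the RMS innovation stays above the divergence threshold for
        more than ``config.divergence_frames`` consecutive frames.
    """
    config = config or UKFConfig()
    if not np.all(np.isfinite(traj.positions)):
        raise InvalidDataError("trajectory contains non-finite coordinates")
    n = traj.n_frames
    dt = 1.0 / traj.sample_rate
    dim_x, dim_z = 8, 2 * len(LANDMARKS)

    # Sigma-point weights (scaled unscented transform).
    lam = config.alpha**2 * (dim_x + config.kappa) - dim_x
    wm = np.full(2 * dim_x + 1, 0.5 / (dim_x + lam))
    wc = wm.copy()
    wm[0] = lam / (dim_x + lam)
    wc[0] = wm[0] + (1.0 - config.alpha**2 + config.beta)

    F = np.eye(dim_x)
    F[:4, 4:] = np.eye(4) * dt
    qc = config.process_noise
    Q = np.zeros((dim_x, dim_x))
    Q[:4, :4] = np.eye(4) * qc * dt**3 / 3.0
    Q[:4, 4:] = Q[4:, :4] = np.eye(4) * qc * dt**2 / 2.0
    Q[4:, 4:] = np.eye(4) * qc * dt
    meas_sd = max(config.measurement_noise_sd, config.min_measurement_sd)
    R = np.eye(dim_z) * meas_sd**2

    def measure(states: np.ndarray) -> np.ndarray:
        world = np.cumsum(states[:, :4], axis=1)
        return forward_kinematics(linkage, world).reshape(states.shape[0], dim_z)

    phi0 = _geometric_angles(traj.positions[0])
    x = np.concatenate([np.concatenate([[phi0[0]], np.diff(phi0)]), np.zeros(4)])
    P = np.diag([0.05**2] * 4 + [0.5**2] * 4)

    joint = np.empty((n, 4))
    innov = np.empty(n)
    diverged_run = 0
    for k in range(n):
        # Predict
        x = F @ x
        P = F @ P @ F.T + Q
        # Sigma points around the predicted state
        P = 0.5 * (P + P.T)
        try:
            sqrtP = np.linalg.cholesky((dim_x + lam) * P)
        except np.linalg.LinAlgError:
            P += np.eye(dim_x) * 1e-10
            sqrtP = np.linalg.cholesky((dim_x + lam) * P)
        sigmas = np.vstack([x, x + sqrtP.T, x - sqrtP.T])
        Z = measure(sigmas)
        z_mean = wm @ Z
        dZ = Z - z_mean
        dX = sigmas - x
        S = dZ.T @ (dZ * wc[:, None]) + R
        Pxz = dX.T @ (dZ * wc[:, None])
        K = Pxz @ np.linalg.inv(S)
        y = traj.positions[k].reshape(dim_z) - z_mean
        x = x + K @ y
        P = P - K @ S @ K.T
        joint[k] = x[:4]
        innov[k] = float(np.sqrt(np.mean(y**2)))
        diverged_run = diverged_run + 1 if innov[k] > config.divergence_innovation else 0
        if diverged_run > config.divergence_frames:
            raise NumericalFailureError(
                f"UKF diverged at frame {k}: RMS innovation {innov[k]:.3f} m "
                f"exceeded {config.divergence_innovation} m for "
                f"{config.divergence_frames} consecutive frames"
            )

    world = np.cumsum(joint, axis=1)
    reproj = forward_kinematics(linkage, world)
    return KinematicSeries(
        t=traj.t.copy(), joint_angles=joint, world_angles=world,
        reprojected=reproj, sample_rate=traj.sample_rate, innovation_rms=innov,
    )


def filter_and_differentiate(
    series: KinematicSeries,
    sample_rate: float | None = None,
    cutoff: float = 5.0,
    order: int = 2,
) -> KinematicSeries:
    """Low-pass filter the angles and differentiate twice.

    Zero-phase (forward-backward) Butterworth filtering is applied before
    each differentiation stage: angles -> filter -> d/dt -> filter -> d/dt
    -> filter.  Differentiation uses central differences in the interior
    and one-sided differences at the endpoints.
    """
    fs = sample_rate or series.sample_rate
    if cutoff >= fs / 2:
        raise InvalidArgumentError(f"cutoff {cutoff} Hz must be below Nyquist {fs / 2} Hz")
    n = series.n_frames
    if n < max(15, 3 * order):
        raise InvalidDataError(f"series too short to filter ({n} frames)")
    sos = butter(order, cutoff, btype="low", fs=fs, output="sos")
    dt = 1.0 / fs

    q = sosfiltfilt(sos, series.joint_angles, axis=0)
    qd = sosfiltfilt(sos, np.gradient(q, dt, axis=0), axis=0)
    qdd = sosfiltfilt(sos, np.gradient(qd, dt, axis=0), axis=0)

    return replace(
        series,
        joint_angles=q,
        world_angles=np.cumsum(q, axis=1),
        joint_velocities=qd,
        joint_accelerations=qdd,
        world_velocities=np.cumsum(qd, axis=1),
        world_accelerations=np.cumsum(qdd, axis=1),
    )


def _rotate_into(v: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Express world vectors ``v`` (n, 2) in a frame tilted by ``phi``.

    The rotated frame's "vertical" axis is the segment long axis
    (sin phi, cos phi) and its "anterior" axis the forward normal
    (cos phi, -sin phi).
    """
    c, s = np.cos(phi), np.sin(phi)
    anterior = v[..., 0] * c - v[..., 1] * s
    vertical = v[..., 0] * s + v[..., 1] * c
    return np.stack([anterior, vertical], axis=-1)


def segment_and_kinematics(series: KinematicSeries, linkage: LinkageModel) -> KinematicSeries:
    """Add segment CoM kinematics (world/body/joint frames) and the SVA.

    World-frame CoM positions, velocities, and accelerations follow from a
    forward recursion over the chain using the joint angle derivatives;
    body-frame components are the world vectors expressed along/normal to
    the segment's own axis, joint-frame components along/normal to the
    parent segment's axis (ground for the shank).
    """
    if series.joint_velocities is None or series.joint_accelerations is None:
        raise InvalidDataError("run filter_and_differentiate before segment kinematics")
    phi = series.world_angles                   # (n, 4)
    phid = series.world_velocities
    phidd = series.world_accelerations
    L = linkage.lengths
    c = linkage.com_offsets
    n = series.n_frames

    u = np.stack([np.sin(phi), np.cos(phi)], axis=-1)        # (n, 4, 2)
    du = np.stack([np.cos(phi), -np.sin(phi)], axis=-1)      # d u / d phi

    # a[k, j] = lever of world angle j on CoM k: L_j below the segment, c_k on it.
    lever = np.zeros((4, 4))
    for k in range(4):
        lever[k, :k] = L[:k]
        lever[k, k] = c[k]

    pos = np.einsum("kj,njc->nkc", lever, u)
    vel = np.einsum("kj,njc,nj->nkc", lever, du, phid)
    acc = np.einsum("kj,njc,nj->nkc", lever, du, phidd) - \
        np.einsum("kj,njc,nj->nkc", lever, u, phid**2)

    com_vel = {"world": vel}
    com_acc = {"world": acc}
    for frame in ("body", "joint"):
        v_out = np.empty_like(vel)
        a_out = np.empty_like(acc)
        for k in range(4):
            ref = phi[:, k] if frame == "body" else (phi[:, k - 1] if k > 0 else np.zeros(n))
            v_out[:, k] = _rotate_into(vel[:, k], ref)
            a_out[:, k] = _rotate_into(acc[:, k], ref)
        com_vel[frame] = v_out
        com_acc[frame] = a_out

    landmarks = forward_kinematics(linkage, phi)
    sva = landmarks[:, -1, 0] - landmarks[:, 0, 0]

    return replace(series, com_pos=pos, com_vel=com_vel, com_acc=com_acc, sva=sva)


# --------------------------------------------------------------------------
# Event segmentation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EventConfig:
    """Thresholds for sit-to-stand event detection (all overridable)."""

    velocity_threshold_deg: float = 5.0   # deg/s, movement start/end threshold
    start_sustain: float = 0.2            # s the torso velocity must stay above threshold
    end_sustain: float = 0.5              # s all joint velocities must stay below threshold
    seatoff_hip_velocity: float = 0.05    # m/s upward hip velocity marking seat-off


@dataclass(frozen=True)
class Events:
    """Frame indices of movement start, seat-off, and movement end."""

    start: int
    seatoff: int
    end: int


def _first_sustained(mask: np.ndarray, run: int) -> int | None:
    if run <= 1:
        idx = np.flatnonzero(mask)
        return int(idx[0]) if len(idx) else None
    conv = np.convolve(mask.astype(int), np.ones(run, dtype=int), mode="valid")
    idx = np.flatnonzero(conv == run)
    return int(idx[0]) if len(idx) else None


def detect_events(series: KinematicSeries, linkage: LinkageModel,
                  config: EventConfig | None = None) -> Events:
    """Segment one trial into start / seat-off / end.

    Start: first frame where the torso world angular speed exceeds the
    threshold sustained for ``start_sustain``.  Seat-off: first frame at or
    after start where the hip landmark rises faster than
    ``seatoff_hip_velocity``.  End: first frame after the peak hip height
    where every joint angular speed stays below threshold for
    ``end_sustain`` (falls back to the last frame).
    """
    if series.world_velocities is None:
        raise InvalidDataError("run filter_and_differentiate before event detection")
    config = config or EventConfig()
    fs = series.sample_rate
    thr = np.deg2rad(config.velocity_threshold_deg)

    torso_speed = np.abs(series.world_velocities[:, 3])
    start = _first_sustained(torso_speed > thr, max(1, int(round(config.start_sustain * fs))))
    if start is None:
        raise InvalidDataError("no movement onset found (torso velocity never exceeds threshold)")

    hip_y = forward_kinematics(linkage, series.world_angles)[:, 2, 1]
    hip_vy = np.gradient(hip_y, 1.0 / fs)
    after = np.flatnonzero(hip_vy[start:] > config.seatoff_hip_velocity)
    seatoff = start + int(after[0]) if len(after) else start

    peak = int(np.argmax(hip_y))
    quiet = np.all(np.abs(series.joint_velocities) < thr, axis=1)
    run = max(1, int(round(config.end_sustain * fs)))
    rel = _first_sustained(quiet[peak:], run)
    end = peak + rel + run - 1 if rel is not None else series.n_frames - 1
    end = min(end, series.n_frames - 1)
    return Events(start=start, seatoff=seatoff, end=int(end))


# --------------------------------------------------------------------------
# Serialization
# --------------------------------------------------------------------------

def kinematics_to_frame(series: KinematicSeries) -> pd.DataFrame:
    """Wide-format table, one row per frame, one column per channel."""
    cols: dict[str, np.ndarray] = {"t": series.t}
    for j, joint in enumerate(JOINTS):
        cols[f"{joint}_angle_joint"] = series.joint_angles[:, j]
        cols[f"{joint}_angle_world"] = series.world_angles[:, j]
        if series.joint_velocities is not None:
            cols[f"{joint}_velocity_joint"] = series.joint_velocities[:, j]
            cols[f"{joint}_acceleration_joint"] = series.joint_accelerations[:, j]
    for frame in FRAMES:
        if frame in series.com_vel:
            for k, seg in enumerate(SEGMENTS):
                for d, comp in enumerate(("anterior", "vertical")):
                    cols[f"{seg}_velocity_{comp}_{frame}"] = series.com_vel[frame][:, k, d]
                    cols[f"{seg}_acceleration_{comp}_{frame}"] = series.com_acc[frame][:, k, d]
    if series.sva is not None:
        cols["sva"] = series.sva
    return pd.DataFrame(cols)


def write_kinematics_csv(series: KinematicSeries, path: str | Path) -> None:
    kinematics_to_frame(series).to_csv(path, index=False)
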
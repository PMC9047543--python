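"""Joint kinetics of the four-link chain.

:func:`inverse_dynamics` implements the classical Newton-Euler backward
recursion: starting from the free torso end, each segment's Newton
(F = m a_com + m g) and Euler (torque balance about the CoM) equations
yield the reaction force and net torque at its lower joint.  Joint powers
are the product of the net joint torque and the relative joint angular
velocity, and concentric/eccentric work are the time integrals of the
positive/negative parts of power.

Torques are reported extension-positive at every joint and stored as
scalars; eccentric work is stored as a negative quantity.  Forces, torques
and powers can be rendered dimensionless with the body-size normalization
force / (M g), torque / (M g H), power / (M g^{3/2} H^{1/2}).

The module also ships the *independent* dynamics route used for
verification: the Lagrangian mass-matrix form of the same chain in
absolute segment angles (:func:`generalized_inverse_dynamics`,
:func:`forward_dynamics`).  Torques recovered by the Newton-Euler
recursion from a motion that was forward-integrated under known torque
profiles must agree with those profiles; the two derivations share no
code path.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.interpolate import interp1d

from .body import JOINTS, LinkageModel
from .errors import InvalidArgumentError, InvalidDataError
from .kinematics import KinematicSeries
from .synthetic import SubjectProfile


@dataclass
class DynamicsSeries:
    """Per-frame joint kinetics.

    ``torque`` (n, 4): net joint torques, extension positive, N m.
    ``reaction`` (n, 4, 2): force transmitted to the segment above each
    joint from below, (anterior, vertical) components, N.
    ``power`` (n, 4): joint powers, W (positive = concentric).
    ``*_norm``: dimensionless body-size-normalized variants.
    """

    t: np.ndarray
    torque: np.ndarray
    reaction: np.ndarray
    power: np.ndarray | None = None
    torque_norm: np.ndarray | None = None
    reaction_norm: np.ndarray | None = None
    power_norm: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return len(self.t)


@dataclass(frozen=True)
class WorkSummary:
    """Concentric (>= 0) and eccentric (<= 0) work per joint, J."""

    concentric: np.ndarray   # (4,)
    eccentric: np.ndarray    # (4,)

    @property
    def net(self) -> np.ndarray:
        return self.concentric + self.eccentric


def _cross_z(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """z-component of the planar cross product a x b."""
    return a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]


def inverse_dynamics(kin: KinematicSeries, linkage: LinkageModel) -> DynamicsSeries:
    """Newton-Euler backward recursion over the chain.

    Requires complete kinematics (CoM accelerations and angular
    accelerations from :func:`stsbiomech.kinematics.segment_and_kinematics`).
    The recursion runs from the torso (free end) down to the ankle; the
    returned torque scalars are extension-positive.
    """
    if "world" not in kin.com_acc or kin.world_accelerations is None:
        raise InvalidDataError("kinematics must include world CoM and angular accelerations")
    n = kin.n_frames
    g = linkage.gravity
    m = linkage.masses
    L = linkage.lengths
    c = linkage.com_offsets
    inertia = linkage.inertias
    phi = kin.world_angles
    phidd = kin.world_accelerations
    acc = kin.com_acc["world"]                 # (n, 4, 2)
    u = np.stack([np.sin(phi), np.cos(phi)], axis=-1)   # segment axis, (n, 4, 2)

    reaction = np.zeros((n, 4, 2))
    torque = np.zeros((n, 4))
    f_above = np.zeros((n, 2))                 # force from the segment above (zero at torso top)
    tau_above = np.zeros(n)
    for i in range(3, -1, -1):
        f = m[i] * acc[:, i] + np.array([0.0, m[i] * g]) + f_above
        r_low = -c[i] * u[:, i]                # CoM -> lower joint
        r_up = (L[i] - c[i]) * u[:, i]         # CoM -> upper joint
        # Euler about the CoM; planar angular acceleration about z is -phidd
        # because world angles are positive clockwise (anterior tilt).
        tau = inertia[i] * (-phidd[:, i]) + tau_above \
            - _cross_z(r_low, f) + _cross_z(r_up, f_above)
        reaction[:, i] = f
        torque[:, i] = tau
        f_above = f
        tau_above = tau
    return DynamicsSeries(t=kin.t.copy(), torque=torque, reaction=reaction)


def joint_powers(dyn: DynamicsSeries, kin: KinematicSeries) -> DynamicsSeries:
    """Add joint powers: torque times joint angular velocity.

    With extension-positive torques and flexion-positive joint angle rates,
    the extension angular velocity is the negated joint rate, so
    ``power = torque * (-d(joint angle)/dt)``: an extension torque acting
    through an extension motion produces positive (concentric) power.
    """
    if kin.joint_velocities is None:
        raise InvalidDataError("kinematics must include joint velocities")
    power = dyn.torque * (-kin.joint_velocities)
    return replace(dyn, power=power)


def work_integrals(dyn: DynamicsSeries, window: tuple[int, int] | None = None) -> WorkSummary:
    """Trapezoidal concentric/eccentric work per joint over ``window``.

    ``window`` is an inclusive frame range ``(first, last)``; the whole
    series is used when omitted.
    """
    if dyn.power is None:
        raise InvalidDataError("run joint_powers before work integration")
    lo, hi = (0, dyn.n_frames - 1) if window is None else window
    if hi <= lo or lo < 0 or hi >= dyn.n_frames:
        raise InvalidArgumentError(f"empty or out-of-range window ({lo}, {hi})")
    t = dyn.t[lo:hi + 1]
    p = dyn.power[lo:hi + 1]
    con = np.trapezoid(np.maximum(p, 0.0), t, axis=0)
    ecc = np.trapezoid(np.minimum(p, 0.0), t, axis=0)
    return WorkSummary(concentric=con, eccentric=ecc)


def _norm_factors(profile: SubjectProfile, gravity: float) -> tuple[float, float, float]:
    if profile.mass <= 0 or profile.height <= 0:
        raise InvalidArgumentError("mass and height must be positive")
    mg = profile.mass * gravity
    return mg * profile.height, mg, mg * np.sqrt(gravity * profile.height)


def normalize_dynamics(dyn: DynamicsSeries, profile: SubjectProfile,
                       gravity: float = 9.81) -> DynamicsSeries:
    """Fill the dimensionless channels using body-size normalization."""
    tq, f, p = _norm_factors(profile, gravity)
    return replace(
        dyn,
        torque_norm=dyn.torque / tq,
        reaction_norm=dyn.reaction / f,
        power_norm=None if dyn.power is None else dyn.power / p,
    )


def denormalize_dynamics(dyn: DynamicsSeries, profile: SubjectProfile,
                         gravity: float = 9.81) -> DynamicsSeries:
    """Inverse of :func:`normalize_dynamics` (restores the raw channels)."""
    if dyn.torque_norm is None:
        raise InvalidDataError("series has no normalized channels")
    tq, f, p = _norm_factors(profile, gravity)
    return replace(
        dyn,
        torque=dyn.torque_norm * tq,
        reaction=dyn.reaction_norm * f,
        power=None if dyn.power_norm is None else dyn.power_norm * p,
    )


# --------------------------------------------------------------------------
# Lagrangian route (verification oracle + forward simulation)
# --------------------------------------------------------------------------

def _chain_coefficients(linkage: LinkageModel) -> tuple[np.ndarray, np.ndarray]:
    """Lever matrix b_ij = sum_k m_k a_ki a_kj and gravity levers g_i."""
    L = linkage.lengths
    c = linkage.com_offsets
    m = linkage.masses
    a = np.zeros((4, 4))
    for k in range(4):
        a[k, :k] = L[:k]
        a[k, k] = c[k]
    b = np.einsum("k,ki,kj->ij", m, a, a)
    glev = linkage.gravity * m @ a           # g_i = g * sum_k m_k a_ki
    return b, glev


def mass_matrix(linkage: LinkageModel, phi: np.ndarray) -> np.ndarray:
    """Chain mass matrix in absolute segment angles."""
    b, _ = _chain_coefficients(linkage)
    M = b * np.cos(phi[:, None] - phi[None, :])
    return M + np.diag(linkage.inertias)


def generalized_inverse_dynamics(
    linkage: LinkageModel,
    phi: np.ndarray, phid: np.ndarray, phidd: np.ndarray,
) -> np.ndarray:
    """Joint torques (extension positive) from the Lagrangian equations.

    Accepts per-frame arrays of shape (n, 4); returns torques (n, 4).
    This route is derived from the chain's energy (mass matrix, Coriolis
    and gravity vectors in absolute angles) and is fully independent of
    the Newton-Euler recursion in :func:`inverse_dynamics`.
    """
    phi, phid, phidd = (np.atleast_2d(np.asarray(x, float)) for x in (phi, phid, phidd))
    b, glev = _chain_coefficients(linkage)
    n = phi.shape[0]
    Q = np.empty((n, 4))
    for k in range(n):
        dphi = phi[k][:, None] - phi[k][None, :]
        M = b * np.cos(dphi) + np.diag(linkage.inertias)
        C = (b * np.sin(dphi)) @ (phid[k] ** 2)
        G = -glev * np.sin(phi[k])
        Q[k] = M @ phidd[k] + C + G
    # Generalized forces in absolute angles relate to extension-positive
    # joint torques by Q_i = tau_{i+1} - tau_i  =>  tau_i = -sum_{j>=i} Q_j.
    return -np.cumsum(Q[:, ::-1], axis=1)[:, ::-1]


def forward_dynamics(
    linkage: LinkageModel,
    torque_t: np.ndarray,
    torque_profiles: np.ndarray,
    phi0: np.ndarray,
    phid0: np.ndarray,
    t_eval: np.ndarray,
    rtol: float = 1e-9,
    atol: float = 1e-11,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the chain's equations of motion under known joint torques.

    ``torque_profiles`` (len(torque_t), 4) holds extension-positive joint
    torques sampled at ``torque_t`` (interpolated cubically in between).
    Returns world angles and angular velocities at ``t_eval``.
    """
    b, glev = _chain_coefficients(linkage)
    inertias = np.diag(linkage.inertias)
    tau_fn = interp1d(torque_t, torque_profiles, axis=0, kind="cubic",
                      bounds_error=False, fill_value=(torque_profiles[0], torque_profiles[-1]))

    def rhs(t: float, y: np.ndarray) -> np.ndarray:
        phi, phid = y[:4], y[4:]
        dphi = phi[:, None] - phi[None, :]
        M = b * np.cos(dphi) + inertias
        C = (b * np.sin(dphi)) @ (phid ** 2)
        G = -glev * np.sin(phi)
        tau = tau_fn(t)
        Q = np.append(np.diff(-tau[::-1])[::-1], -tau[3])  # Q_i = tau_{i+1} - tau_i
        phidd = np.linalg.solve(M, Q - C - G)
        return np.concatenate([phid, phidd])

    sol = solve_ivp(rhs, (t_eval[0], t_eval[-1]), np.concatenate([phi0, phid0]),
                    t_eval=t_eval, rtol=rtol, atol=atol, method="RK45")
    if not sol.success:
        raise InvalidDataError(f"forward integration failed: {sol.message}")
    return sol.y[:4].T, sol.y[4:].T


def forward_simulate_tracking(
    linkage: LinkageModel,
    t: np.ndarray,
    phi_ref: np.ndarray,
    tau_ff: np.ndarray | None = None,
    kp: float = 800.0,
    kd: float = 120.0,
    rtol: float = 1e-7,
    atol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forward-integrate the chain under exactly known joint torques.

    The upright chain is an unstable inverted pendulum, so pure open-loop
    torque playback amplifies integration error exponentially.  Instead
    the applied joint torque is a feedforward profile (Lagrangian inverse
    dynamics of ``phi_ref`` unless ``tau_ff`` is given) plus a small PD
    tracking term; the *total* applied torque is known in closed form from
    the simulated state at every instant and is returned sampled at ``t``.
    Inverse-dynamics implementations can therefore be validated against
    the exact torques that actually generated the motion.

    Returns ``(phi, phid, tau_applied)`` with shapes (n, 4).
    """
    t = np.asarray(t, float)
    phi_ref = np.asarray(phi_ref, float)
    dt = np.median(np.diff(t))
    phid_ref = np.gradient(phi_ref, dt, axis=0)
    phidd_ref = np.gradient(phid_ref, dt, axis=0)
    if tau_ff is None:
        tau_ff = generalized_inverse_dynamics(linkage, phi_ref, phid_ref, phidd_ref)

    q_ref = np.column_stack([phi_ref[:, :1], np.diff(phi_ref, axis=1)])
    qd_ref = np.column_stack([phid_ref[:, :1], np.diff(phid_ref, axis=1)])
    # Piecewise-linear interpolants keep the right-hand side cheap; the
    # applied torque stays exact because it is re-evaluated from the same
    # interpolants and the simulated state.
    tau_i = interp1d(t, tau_ff, axis=0, kind="linear")
    qref_i = interp1d(t, q_ref, axis=0, kind="linear")
    qdref_i = interp1d(t, qd_ref, axis=0, kind="linear")

    b, glev = _chain_coefficients(linkage)
    inertias = np.diag(linkage.inertias)

    def applied_tau(tt: float, phi: np.ndarray, phid: np.ndarray) -> np.ndarray:
        q = np.append(phi[0], np.diff(phi))
        qd = np.append(phid[0], np.diff(phid))
        # Extension-positive torque decreases the (flexion-positive) joint
        # angle, hence the feedback sign.
        return tau_i(tt) + kp * (q - qref_i(tt)) + kd * (qd - qdref_i(tt))

    def rhs(tt: float, y: np.ndarray) -> np.ndarray:
        phi, phid = y[:4], y[4:]
        dphi = phi[:, None] - phi[None, :]
        M = b * np.cos(dphi) + inertias
        C = (b * np.sin(dphi)) @ (phid ** 2)
        G = -glev * np.sin(phi)
        tau = applied_tau(tt, phi, phid)
        Q = np.append(np.diff(-tau[::-1])[::-1], -tau[3])
        return np.concatenate([phid, np.linalg.solve(M, Q - C - G)])

    y0 = np.concatenate([phi_ref[0], phid_ref[0]])
    sol = solve_ivp(rhs, (t[0], t[-1]), y0, t_eval=t, rtol=rtol, atol=atol,
                    method="LSODA")
    if not sol.success:
        raise InvalidDataError(f"forward integration failed: {sol.message}")
    phi, phid = sol.y[:4].T, sol.y[4:].T
    tau_applied = np.vstack([applied_tau(tt, p, pd)
                             for tt, p, pd in zip(t, phi, phid)])
    return phi, phid, tau_applied


def torque_recovery_errors(
    linkage: LinkageModel,
    phi_ref: np.ndarray,
    t: np.ndarray,
    estimate_torques,
    edge_margin: float = 0.3,
    kp: float = 800.0,
    kd: float = 120.0,
) -> tuple[np.ndarray, np.ndarray]:
    """End-to-end inverse-dynamics verification on a known-torque motion.

    Forward-simulates ``linkage`` tracking ``phi_ref`` (so the applied
    torques are known exactly), hands the resulting motion to
    ``estimate_torques(phi, t) -> torques`` — typically the full landmark ->
    UKF -> filtering -> Newton-Euler pipeline — and returns ``(rmse, peak)``
    per joint, with RMSE evaluated away from the first/last ``edge_margin``
    seconds where zero-phase filtering has edge effects.

    The feedforward is computed on a dense (1 kHz) grid so the PD
    correction stays small and smooth.
    """
    dtd = 1e-3
    dt = np.median(np.diff(t))
    td = np.arange(0, t[-1] + dtd, dtd)
    idx = np.clip(np.round(t / dtd).astype(int), 0, len(td) - 1)
    # Dense reference by cubic interpolation of the sampled reference.
    ref_i = interp1d(t, phi_ref, axis=0, kind="cubic")
    phi_d = ref_i(np.clip(td, t[0], t[-1]))
    vel_d = np.gradient(phi_d, dtd, axis=0)
    acc_d = np.gradient(vel_d, dtd, axis=0)
    tau_ff = generalized_inverse_dynamics(linkage, phi_d, vel_d, acc_d)[idx]
    phi, _, tau_true = forward_simulate_tracking(linkage, t, phi_ref,
                                                 tau_ff=tau_ff, kp=kp, kd=kd)
    estimated = estimate_torques(phi, t)
    mask = (t > t[0] + edge_margin) & (t < t[-1] - edge_margin)
    rmse = np.sqrt(np.mean((estimated[mask] - tau_true[mask]) ** 2, axis=0))
    peak = np.abs(tau_true).max(axis=0)
    return rmse, peak


def chain_energy(linkage: LinkageModel, phi: np.ndarray, phid: np.ndarray) -> np.ndarray:
    """Total mechanical energy (kinetic + gravitational) per frame."""
    b, glev = _chain_coefficients(linkage)
    n = phi.shape[0]
    E = np.empty(n)
    for k in range(n):
        M = b * np.cos(phi[k][:, None] - phi[k][None, :]) + np.diag(linkage.inertias)
        E[k] = 0.5 * phid[k] @ M @ phid[k] + glev @ np.cos(phi[k])
    return E


# --------------------------------------------------------------------------
# Serialization
# --------------------------------------------------------------------------

def dynamics_to_frame(dyn: DynamicsSeries) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {"t": dyn.t}
    for j, joint in enumerate(JOINTS):
        cols[f"{joint}_torque"] = dyn.torque[:, j]
        cols[f"{joint}_reaction_anterior"] = dyn.reaction[:, j, 0]
        cols[f"{joint}_reaction_vertical"] = dyn.reaction[:, j, 1]
        if dyn.power is not None:
            cols[f"{joint}_power"] = dyn.power[:, j]
        if dyn.torque_norm is not None:
            cols[f"{joint}_torque_norm"] = dyn.torque_norm[:, j]
        if dyn.power_norm is not None:
            cols[f"{joint}_power_norm"] = dyn.power_norm[:, j]
    return pd.DataFrame(cols)


def write_dynamics_csv(dyn: DynamicsSeries, path: str | Path) -> None:
    dynamics_to_frame(dyn).to_csv(path, index=False)
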
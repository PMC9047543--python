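"""Planar single-equivalent-muscle model of L5S1 loading.

The net extension torque demand at L5S1 is balanced by a single equivalent
erector-spinae force ``F_m`` acting parallel to the torso long axis at a
posterior moment arm ``d_m`` (default 5 cm), assisted by an abdominal
pressure force ``F_a`` acting anterior to the joint at moment arm ``d_a``:

    F_m = max(0, (tau_L5S1 - F_a * d_a) / d_m)

The abdominal relieving force follows a Chaffin-style closed form: it grows
with the extension-torque demand and saturates,

    F_a = min(c_a * max(0, tau_L5S1), F_a_max),

with the pressure coefficient ``c_a`` (1/m) and cap ``F_a_max`` both
configurable; setting either to zero reduces the model exactly to the pure
torque-balance solution tau / d_m.

The total load transmitted across the lumbosacral disc is the inverse-
dynamics joint reaction plus the muscle force (compressive, along the
torso axis) minus the abdominal relief.  Compression and anterior shear
resolve this load onto the torso long axis and its forward normal at the
lumbar cut; sacral compression resolves it onto the sacral-endplate
direction, taken as the pelvis long axis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import DynamicsSeries
from .errors import InvalidConfigError, InvalidDataError
from .kinematics import KinematicSeries
from .synthetic import SubjectProfile

L5S1 = 3  # joint index of L5S1 in the chain


@dataclass(frozen=True)
class SpineModelParams:
    """Geometry, abdominal-pressure and co-activation coefficients.

    ``co_contraction`` is the antagonist co-activation fraction: the
    antagonist equivalent muscle carries that fraction of the agonist
    force, as trunk muscle pairs are never fully silent.  With
    ``co_contraction = 0`` the extension branch reduces to the classical
    single-muscle balance ``F_m = max(0, (tau - F_a d_a) / d_m)``.
    """

    extensor_moment_arm: float = 0.05    # d_m, m, posterior to the joint
    abdominal_moment_arm: float = 0.08   # d_a, m, anterior to the joint
    abdominal_coefficient: float = 1.8   # c_a, 1/m: relieving force per unit torque demand
    abdominal_max_force: float = 400.0   # N, saturation of the abdominal relief
    co_contraction: float = 0.1          # antagonist/agonist force fraction

    def __post_init__(self) -> None:
        if self.extensor_moment_arm <= 0 or self.abdominal_moment_arm <= 0:
            raise InvalidConfigError("moment arms must be positive")
        if self.abdominal_coefficient < 0 or self.abdominal_max_force < 0:
            raise InvalidConfigError("abdominal coefficients must be non-negative")
        # Keep the effective torque share of the abdominal term below unity so
        # muscle force stays monotone in torque demand.
        if self.abdominal_coefficient * self.abdominal_moment_arm >= 1.0:
            raise InvalidConfigError(
                "abdominal_coefficient * abdominal_moment_arm must be < 1"
            )
        if not 0.0 <= self.co_contraction < 1.0:
            raise InvalidConfigError("co_contraction must lie in [0, 1)")
        if self.co_contraction > 0 and (
                self.abdominal_moment_arm <= self.co_contraction * self.extensor_moment_arm
                or self.extensor_moment_arm <= self.co_contraction * self.abdominal_moment_arm):
            raise InvalidConfigError(
                "co-contraction too strong for the moment-arm geometry")


@dataclass
class SpineLoadSeries:
    """Per-frame L5S1 loads (N) and their body-weight-normalized variants."""

    t: np.ndarray
    extensor_muscle_force: np.ndarray
    abdominal_pressure_force: np.ndarray
    lumbar_compression: np.ndarray
    lumbar_anterior_shear: np.ndarray
    sacral_compression: np.ndarray
    extensor_muscle_force_norm: np.ndarray | None = None
    lumbar_compression_norm: np.ndarray | None = None
    lumbar_anterior_shear_norm: np.ndarray | None = None
    sacral_compression_norm: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return len(self.t)


def l5s1_loads(
    dyn: DynamicsSeries,
    kin: KinematicSeries,
    params: SpineModelParams | None = None,
) -> SpineLoadSeries:
    """Muscle, abdominal, compressive and shear forces at L5S1.

    Uses the raw (unnormalized) L5S1 torque and joint reaction from
    ``dyn`` and the torso/pelvis world angles from ``kin``.
    """
    params = params or SpineModelParams()
    if dyn.n_frames != kin.n_frames:
        raise InvalidDataError("dynamics and kinematics must be frame-aligned")

    tau = dyn.torque[:, L5S1]
    d_m, d_a = params.extensor_moment_arm, params.abdominal_moment_arm
    cc = params.co_contraction
    demand = np.maximum(tau, 0.0)
    f_abd = np.minimum(params.abdominal_coefficient * demand, params.abdominal_max_force)
    # Extension demand: extensor agonist (with abdominal-pressure relief and
    # antagonist flexor at cc times the agonist force in the moment balance).
    f_ext_agonist = np.maximum(0.0, (tau - f_abd * d_a) / (d_m - cc * d_a))
    # Flexion demand: abdominal flexor agonist, extensor co-contracting.
    f_flex_agonist = np.maximum(0.0, -tau) / (d_a - cc * d_m)
    flexion = tau < 0
    f_muscle = np.where(flexion, cc * f_flex_agonist, f_ext_agonist)
    f_flexor = np.where(flexion, f_flex_agonist, cc * f_ext_agonist)

    phi_torso = kin.world_angles[:, 3]
    phi_pelvis = kin.world_angles[:, 2]
    axis_t = np.stack([np.sin(phi_torso), np.cos(phi_torso)], axis=-1)
    normal_t = np.stack([np.cos(phi_torso), -np.sin(phi_torso)], axis=-1)
    axis_p = np.stack([np.sin(phi_pelvis), np.cos(phi_pelvis)], axis=-1)

    reaction = dyn.reaction[:, L5S1]            # force supporting the torso from below
    # Muscle tensions compress the disc; abdominal pressure unloads it.
    axial_musc = f_muscle + f_flexor - f_abd
    compression = np.einsum("nc,nc->n", reaction, axis_t) + axial_musc
    shear = -np.einsum("nc,nc->n", reaction, normal_t)
    cos_tp = np.einsum("nc,nc->n", axis_t, axis_p)
    sacral = np.einsum("nc,nc->n", reaction, axis_p) + axial_musc * cos_tp

    return SpineLoadSeries(
        t=dyn.t.copy(),
        extensor_muscle_force=f_muscle,
        abdominal_pressure_force=f_abd,
        lumbar_compression=compression,
        lumbar_anterior_shear=shear,
        sacral_compression=sacral,
    )


def normalize_spine_loads(series: SpineLoadSeries, profile: SubjectProfile,
                          gravity: float = 9.81) -> SpineLoadSeries:
    """Fill body-weight (M g) normalized channels."""
    bw = profile.mass * gravity
    return replace(
        series,
        extensor_muscle_force_norm=series.extensor_muscle_force / bw,
        lumbar_compression_norm=series.lumbar_compression / bw,
        lumbar_anterior_shear_norm=series.lumbar_anterior_shear / bw,
        sacral_compression_norm=series.sacral_compression / bw,
    )


def spine_to_frame(series: SpineLoadSeries) -> pd.DataFrame:
    cols = {
        "t": series.t,
        "l5s1_muscle_force": series.extensor_muscle_force,
        "l5s1_abdominal_force": series.abdominal_pressure_force,
        "l5s1_lumbar_compression": series.lumbar_compression,
        "l5s1_lumbar_shear": series.lumbar_anterior_shear,
        "l5s1_sacral_compression": series.sacral_compression,
    }
    if series.lumbar_compression_norm is not None:
        cols.update({
            "l5s1_muscle_force_norm": series.extensor_muscle_force_norm,
            "l5s1_lumbar_compression_norm": series.lumbar_compression_norm,
            "l5s1_lumbar_shear_norm": series.lumbar_anterior_shear_norm,
            "l5s1_sacral_compression_norm": series.sacral_compression_norm,
        })
    return pd.DataFrame(cols)


def write_spine_csv(series: SpineLoadSeries, path: str | Path) -> None:
    spine_to_frame(series).to_csv(path, index=False)
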
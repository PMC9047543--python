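"""Synthetic cohorts and sit-to-stand trials.

No public motion-capture dataset accompanies this analysis, so the package
ships a generator that emulates the study conditions end to end: three
cohorts (healthy controls, non-specific low-back-pain patients, and
spinal-deformity patients), each subject rising from a chair three times
while a depth-camera-like observer records five planar landmarks (ankle,
knee, hip, L5S1, torso end) at 30 Hz with ~1.8 cm joint-position noise.

Trial generation is purely kinematic: joint-angle keyframes (seated,
peak-lean/seat-off, rise, swing-back, standing) are interpolated with
minimum-jerk quintics and pushed through the forward kinematics of the
scaled four-link chain, with the ankle fixed at the world origin.  Torques
are *not* simulated here; they are recovered downstream by inverse
dynamics, mirroring the purely inverse measurement pipeline.

Movement strategy is controlled by a small parameter set
(:class:`StrategyParams`): controls rise nearly vertically with high
momentum, patients lean forward further, move slower, swing back after
seat-off, and finish in a residually flexed posture.  World segment angles
are measured from the upward vertical, positive tilting anterior (+x).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .body import LANDMARKS, LinkageModel, forward_kinematics
from .errors import InvalidArgumentError, InvalidConfigError

GROUPS = ("control", "nslbp", "sdlbp")

DEFAULT_SAMPLE_RATE = 30.0   # Hz, depth-camera stream rate
DEFAULT_NOISE_SD = 0.018     # m, per-coordinate landmark noise (1.80 cm validation error)

# Seated reference pose (world angles, rad): shank vertical, thigh horizontal
# pointing posterior (hip behind the knee), mild trunk flexion.
_SEATED_SHANK = 0.0
_SEATED_THIGH = -np.pi / 2
_SEATED_PELVIS_FRACTION = 0.55   # pelvis lean as a fraction of seated torso lean

# Stature distributions used to sample height (m) conditional on sex.
_HEIGHT_BY_SEX = {1: (1.754, 0.069), 0: (1.618, 0.065)}


@dataclass(frozen=True)
class SubjectProfile:
    """Demographics, anthropometrics and patient-reported outcomes."""

    subject_id: str
    group: str                  # control | nslbp | sdlbp
    sex: int                    # 0 = female, 1 = male
    age: float                  # years
    height: float               # m
    mass: float                 # kg
    bmi: float                  # kg/m^2
    vas: float | None = None    # pain, 0-10 (missing for controls)
    odi: float | None = None    # disability, 0-100 (missing for controls)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise InvalidArgumentError(f"unknown group {self.group!r}")
        if self.height <= 0 or self.mass <= 0:
            raise InvalidArgumentError("height and mass must be positive")
        implied = self.mass / self.height**2
        if abs(implied - self.bmi) > 0.15 * self.bmi:
            raise InvalidArgumentError(
                f"bmi {self.bmi:.1f} inconsistent with mass/height^2 = {implied:.1f}"
            )


@dataclass(frozen=True)
class StrategyParams:
    """Shape parameters of one sit-to-stand movement strategy.

    peak_torso_lean:
        Maximum world torso flexion during the rise (rad).
    momentum_scale:
        Multiplier on peak angular velocities; >1 compresses the rise in
        time (momentum-transfer strategy), <1 slows it down.
    end_posture_flexion:
        Residual L5S1+hip flexion retained at quiet standing (rad).
    swingback_amplitude:
        Posterior trunk overshoot after seat-off (rad).
    duration:
        Nominal self-paced sit-to-stand duration (s) at momentum_scale 1.
    """

    peak_torso_lean: float
    momentum_scale: float = 1.0
    end_posture_flexion: float = 0.0
    swingback_amplitude: float = 0.0
    duration: float = 2.0
    n_repetitions: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.peak_torso_lean < np.pi / 2:
            raise InvalidArgumentError(
                f"peak_torso_lean must lie in [0, pi/2), got {self.peak_torso_lean}"
            )
        if self.duration <= 0:
            raise InvalidArgumentError("duration must be > 0")
        if self.momentum_scale <= 0:
            raise InvalidArgumentError("momentum_scale must be > 0")
        if self.n_repetitions < 1:
            raise InvalidArgumentError("n_repetitions must be >= 1")


@dataclass(frozen=True)
class JointTrajectory:
    """Timestamped planar landmark positions for one trial.

    ``positions`` has shape (n_frames, 5, 2): landmarks in the order of
    :data:`stsbiomech.body.LANDMARKS`, components (anterior x, vertical y)
    in meters.
    """

    subject_id: str
    trial_id: str
    t: np.ndarray
    positions: np.ndarray
    sample_rate: float = DEFAULT_SAMPLE_RATE

    def __post_init__(self) -> None:
        t = np.asarray(self.t, float)
        if t.ndim != 1 or len(t) < 2:
            raise InvalidArgumentError("trajectory needs at least two frames")
        dt = np.diff(t)
        if not np.allclose(dt, 1.0 / self.sample_rate, atol=1e-9):
            raise InvalidArgumentError("frame times must be uniform at 1/sample_rate")
        if t[-1] - t[0] < 2.0 - 1e-9:
            raise InvalidArgumentError("trajectory must span at least 2 s")
        if not np.all(np.isfinite(self.positions)):
            raise InvalidArgumentError("landmark positions must be finite")
        if self.positions.shape != (len(t), len(LANDMARKS), 2):
            raise InvalidArgumentError(
                f"positions must have shape (n, {len(LANDMARKS)}, 2)"
            )

    @property
    def n_frames(self) -> int:
        return len(self.t)


# --------------------------------------------------------------------------
# Cohort generation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupDemographics:
    """Per-group sampling moments (defaults mirror the study's cohort table)."""

    age_mean: float
    age_sd: float
    bmi_mean: float
    bmi_sd: float
    male_fraction: float
    vas_mean: float | None = None
    vas_sd: float | None = None
    odi_mean: float | None = None
    odi_sd: float | None = None


@dataclass(frozen=True)
class DemographicsConfig:
    groups: dict[str, GroupDemographics] = field(default_factory=lambda: {
        "control": GroupDemographics(27.5, 8.85, 23.8, 3.85, 0.500),
        "nslbp": GroupDemographics(53.9, 17.4, 26.7, 4.18, 0.558,
                                   vas_mean=4.67, vas_sd=2.38,
                                   odi_mean=50.2, odi_sd=16.3),
        "sdlbp": GroupDemographics(62.7, 11.9, 26.4, 4.86, 0.310,
                                   vas_mean=6.83, vas_sd=2.93,
                                   odi_mean=48.9, odi_sd=16.2),
    })

    def __post_init__(self) -> None:
        for name, g in self.groups.items():
            for attr in ("age_sd", "bmi_sd", "vas_sd", "odi_sd"):
                val = getattr(g, attr)
                if val is not None and val <= 0:
                    raise InvalidConfigError(f"group {name!r}: {attr} must be > 0")
            if not 0.0 <= g.male_fraction <= 1.0:
                raise InvalidConfigError(f"group {name!r}: male_fraction must be in [0, 1]")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      low: float, high: float, size: int) -> np.ndarray:
    """Resampling-based truncated normal (simple and exactly reproducible)."""
    out = rng.normal(mean, sd, size)
    for _ in range(100):
        bad = (out < low) | (out > high)
        if not bad.any():
            break
        out[bad] = rng.normal(mean, sd, bad.sum())
    return np.clip(out, low, high)


def generate_cohort(
    n_control: int,
    n_nslbp: int,
    n_sdlbp: int,
    demographics: DemographicsConfig | None = None,
    seed: int = 0,
) -> list[SubjectProfile]:
    """Sample a cohort of subject profiles, deterministic given ``seed``.

    Ages are truncated at 18 years, BMI at 15 kg/m^2; VAS/ODI are clipped
    to their scales and set missing for every control subject.
    """
    for n in (n_control, n_nslbp, n_sdlbp):
        if n < 0:
            raise InvalidArgumentError("group sizes must be non-negative")
    demographics = demographics or DemographicsConfig()
    rng = np.random.default_rng(seed)
    prefixes = {"control": "C", "nslbp": "N", "sdlbp": "S"}
    counts = {"control": n_control, "nslbp": n_nslbp, "sdlbp": n_sdlbp}

    profiles: list[SubjectProfile] = []
    for group in GROUPS:
        n = counts[group]
        if n == 0:
            continue
        g = demographics.groups[group]
        ages = _truncated_normal(rng, g.age_mean, g.age_sd, 18.0, 95.0, n)
        bmis = _truncated_normal(rng, g.bmi_mean, g.bmi_sd, 15.0, 55.0, n)
        sexes = (rng.random(n) < g.male_fraction).astype(int)
        if group == "control":
            vas = np.full(n, np.nan)
            odi = np.full(n, np.nan)
        else:
            vas = np.clip(rng.normal(g.vas_mean, g.vas_sd, n), 0.0, 10.0)
            odi = np.clip(rng.normal(g.odi_mean, g.odi_sd, n), 0.0, 100.0)
        for i in range(n):
            hm, hs = _HEIGHT_BY_SEX[int(sexes[i])]
            height = float(np.clip(rng.normal(hm, hs), 1.40, 2.05))
            mass = float(bmis[i] * height**2)
            profiles.append(SubjectProfile(
                subject_id=f"{prefixes[group]}{i + 1:03d}",
                group=group,
                sex=int(sexes[i]),
                age=float(ages[i]),
                height=height,
                mass=mass,
                bmi=float(bmis[i]),
                vas=None if np.isnan(vas[i]) else float(vas[i]),
                odi=None if np.isnan(odi[i]) else float(odi[i]),
            ))
    return profiles


# --------------------------------------------------------------------------
# Strategies
# --------------------------------------------------------------------------

_DEFAULT_STRATEGIES = {
    # Controls: near-vertical rise driven by momentum transfer; upright finish.
    "control": StrategyParams(peak_torso_lean=0.35, momentum_scale=1.15,
                              end_posture_flexion=0.02, swingback_amplitude=0.02,
                              duration=1.7),
    # Non-specific LBP: intermediate lean, slower, modest swing-back.
    "nslbp": StrategyParams(peak_torso_lean=0.62, momentum_scale=0.95,
                            end_posture_flexion=0.08, swingback_amplitude=0.10,
                            duration=2.0),
    # Spinal deformity: pronounced forward lean, slow rise, swing-back and a
    # residually flexed standing posture.
    "sdlbp": StrategyParams(peak_torso_lean=0.88, momentum_scale=0.75,
                            end_posture_flexion=0.20, swingback_amplitude=0.16,
                            duration=2.3),
}


def default_strategy_for_group(group: str) -> StrategyParams:
    """Default movement-strategy parameters for a cohort group."""
    if group not in _DEFAULT_STRATEGIES:
        raise InvalidArgumentError(f"unknown group {group!r}")
    return _DEFAULT_STRATEGIES[group]


@dataclass(frozen=True)
class StrategyVariability:
    """Between-subject spread of strategy parameters within a group.

    Real cohorts vary in how far they lean and how vigorously they rise
    largely independently of each other; sampling each parameter with its
    own SD around the group mean preserves the group ordering on average
    while letting lean-driven and momentum-driven feature variation span
    separate directions, as they do in recorded cohorts.
    """

    lean_sd: float = 0.10          # rad
    momentum_sd: float = 0.12      # dimensionless
    end_flexion_sd: float = 0.05   # rad
    swingback_sd: float = 0.04     # rad
    duration_sd: float = 0.25      # s


def sample_subject_strategy(
    base: StrategyParams,
    variability: StrategyVariability | None = None,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> StrategyParams:
    """Draw one subject's habitual strategy around the group means."""
    variability = variability or StrategyVariability()
    if rng is None:
        rng = np.random.default_rng(seed)
    return StrategyParams(
        peak_torso_lean=float(np.clip(
            rng.normal(base.peak_torso_lean, variability.lean_sd), 0.05, np.pi / 2 - 1e-3)),
        momentum_scale=float(np.clip(
            rng.normal(base.momentum_scale, variability.momentum_sd), 0.4, 2.0)),
        end_posture_flexion=float(np.clip(
            rng.normal(base.end_posture_flexion, variability.end_flexion_sd), 0.0, 0.6)),
        swingback_amplitude=float(np.clip(
            rng.normal(base.swingback_amplitude, variability.swingback_sd), 0.0, 0.5)),
        duration=float(np.clip(
            rng.normal(base.duration, variability.duration_sd), 1.0, 4.0)),
        n_repetitions=base.n_repetitions,
    )


# --------------------------------------------------------------------------
# Trial simulation
# --------------------------------------------------------------------------

def _min_jerk(u: np.ndarray) -> np.ndarray:
    """Minimum-jerk blend: s(0)=0, s(1)=1, zero velocity/acceleration at ends."""
    return u**3 * (10.0 - 15.0 * u + 6.0 * u**2)


def _strategy_keyframes(strategy: StrategyParams) -> tuple[np.ndarray, np.ndarray]:
    """Keyframe times (fractions of the rise phase) and world angles (4,)."""
    lean = strategy.peak_torso_lean
    end = strategy.end_posture_flexion
    swing = strategy.swingback_amplitude
    seated_torso = min(0.18, max(0.02, 0.8 * lean))
    seated_pelvis = _SEATED_PELVIS_FRACTION * seated_torso
    mid_torso = end + 0.25 * (lean - end)
    frames = np.array([
        # shank,        thigh,                pelvis,                        torso
        [_SEATED_SHANK, _SEATED_THIGH,        seated_pelvis,                 seated_torso],
        [0.06,          _SEATED_THIGH + 0.12, 0.55 * lean,                   lean],
        [0.03,          -0.18,                0.50 * mid_torso,              mid_torso],
        [0.01,          -0.05,                0.45 * end - 0.5 * swing,      end - swing],
        [0.00,          0.00,                 0.45 * end,                    end],
    ])
    s = np.array([0.0, 0.35, 0.70, 0.85, 1.0])
    return s, frames


def strategy_world_angles(strategy: StrategyParams, t: np.ndarray,
                          lead_in: float = 0.5) -> np.ndarray:
    """Ground-truth world segment angles (n, 4) for one repetition.

    The movement occupies ``[lead_in, lead_in + rise_time]`` where
    ``rise_time = duration / momentum_scale``; the pose is held seated
    before and standing after.
    """
    t = np.asarray(t, float)
    rise_time = strategy.duration / strategy.momentum_scale
    s_knots, frames = _strategy_keyframes(strategy)
    s = np.clip((t - lead_in) / rise_time, 0.0, 1.0)
    angles = np.empty((len(t), 4))
    for i in range(len(s_knots) - 1):
        lo, hi = s_knots[i], s_knots[i + 1]
        mask = (s >= lo) & (s <= hi) if i == len(s_knots) - 2 else (s >= lo) & (s < hi)
        u = (s[mask] - lo) / (hi - lo)
        blend = _min_jerk(u)[:, None]
        angles[mask] = frames[i] + blend * (frames[i + 1] - frames[i])
    return angles


def trial_duration(strategy: StrategyParams, lead_in: float = 0.5,
                   settle: float = 1.0) -> float:
    rise_time = strategy.duration / strategy.momentum_scale
    return max(2.0, lead_in + rise_time + settle)


def simulate_sts_trial(
    profile: SubjectProfile,
    linkage: LinkageModel,
    strategy: StrategyParams,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
    trial_id: str = "T1",
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    return_truth: bool = False,
) -> JointTrajectory | tuple[JointTrajectory, dict]:
    """Simulate one noisy sit-to-stand trial.

    Landmark positions come from the forward kinematics of ``linkage``
    driven by the minimum-jerk keyframe angles of ``strategy``; i.i.d.
    Gaussian noise of scale ``noise_sd`` is added per coordinate.  With
    ``return_truth=True`` also returns the generating world/joint angles
    and noiseless landmark positions for round-trip testing.
    """
    if noise_sd < 0:
        raise InvalidArgumentError("noise_sd must be >= 0")
    dt = 1.0 / sample_rate
    total = trial_duration(strategy)
    n = int(np.floor(total / dt)) + 1
    t = np.arange(n) * dt
    world = strategy_world_angles(strategy, t)
    clean = forward_kinematics(linkage, world)
    rng = np.random.default_rng(seed)
    noisy = clean + rng.normal(0.0, noise_sd, clean.shape) if noise_sd > 0 else clean.copy()
    traj = JointTrajectory(profile.subject_id, trial_id, t, noisy, sample_rate)
    if not return_truth:
        return traj
    joint = np.column_stack([world[:, 0], np.diff(world, axis=1)])
    truth = {"world_angles": world, "joint_angles": joint, "positions": clean}
    return traj, truth


def simulate_subject_trials(
    profile: SubjectProfile,
    linkage: LinkageModel,
    strategy: StrategyParams | None = None,
    noise_sd: float = DEFAULT_NOISE_SD,
    jitter: float = 0.05,
    seed: int = 0,
) -> list[JointTrajectory]:
    """Simulate ``strategy.n_repetitions`` trials with multiplicative
    per-repetition jitter (truncated normal, sd ``jitter``) on the strategy
    parameters, so trial averaging downstream is non-degenerate."""
    strategy = strategy or default_strategy_for_group(profile.group)
    # Decouple the jitter stream from the noise stream so noise_sd=0 runs
    # reproduce the same strategies.
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    trials = []
    for rep in range(strategy.n_repetitions):
        f = np.clip(rng.normal(1.0, jitter, 5), 0.75, 1.25)
        jittered = replace(
            strategy,
            peak_torso_lean=min(strategy.peak_torso_lean * f[0], np.pi / 2 - 1e-3),
            momentum_scale=strategy.momentum_scale * f[1],
            end_posture_flexion=strategy.end_posture_flexion * f[2],
            swingback_amplitude=strategy.swingback_amplitude * f[3],
            duration=strategy.duration * f[4],
        )
        trial_seed = int(np.random.SeedSequence([seed, 2, rep]).generate_state(1)[0] % (2**31))
        trials.append(simulate_sts_trial(
            profile, linkage, jittered, noise_sd=noise_sd,
            seed=trial_seed, trial_id=f"T{rep + 1}",
        ))
    return trials


# --------------------------------------------------------------------------
# Serialization
# --------------------------------------------------------------------------

def trajectory_to_frame(traj: JointTrajectory) -> pd.DataFrame:
    """Long-format table: (subject_id, trial_id, t, landmark, x, y)."""
    n, m = traj.positions.shape[:2]
    return pd.DataFrame({
        "subject_id": np.repeat(traj.subject_id, n * m),
        "trial_id": np.repeat(traj.trial_id, n * m),
        "t": np.repeat(traj.t, m),
        "landmark": np.tile(LANDMARKS, n),
        "x": traj.positions[:, :, 0].ravel(),
        "y": traj.positions[:, :, 1].ravel(),
    })


def write_trajectory_csv(traj: JointTrajectory, path: str | Path) -> None:
    trajectory_to_frame(traj).to_csv(path, index=False, float_format="%.17g")


def read_trajectory_csv(path: str | Path,
                        sample_rate: float = DEFAULT_SAMPLE_RATE) -> JointTrajectory:
    df = pd.read_csv(path, float_precision="round_trip")
    t = np.sort(df["t"].unique())
    pos = np.empty((len(t), len(LANDMARKS), 2))
    pivot_x = df.pivot_table(index="t", columns="landmark", values="x", sort=True)
    pivot_y = df.pivot_table(index="t", columns="landmark", values="y", sort=True)
    for j, lm in enumerate(LANDMARKS):
        pos[:, j, 0] = pivot_x[lm].to_numpy()
        pos[:, j, 1] = pivot_y[lm].to_numpy()
    return JointTrajectory(str(df["subject_id"].iloc[0]), str(df["trial_id"].iloc[0]),
                           t, pos, sample_rate)


def cohort_to_frame(profiles: list[SubjectProfile]) -> pd.DataFrame:
    return pd.DataFrame([{
        "subject_id": p.subject_id, "group": p.group, "sex": p.sex,
        "age": p.age, "height": p.height, "mass": p.mass, "bmi": p.bmi,
        "vas": np.nan if p.vas is None else p.vas,
        "odi": np.nan if p.odi is None else p.odi,
    } for p in profiles])


def write_cohort_csv(profiles: list[SubjectProfile], path: str | Path) -> None:
    cohort_to_frame(profiles).to_csv(path, index=False, float_format="%.17g")


def read_cohort_csv(path: str | Path) -> list[SubjectProfile]:
    df = pd.read_csv(path, float_precision="round_trip")
    return [SubjectProfile(
        subject_id=str(r.subject_id), group=str(r.group), sex=int(r.sex),
        age=float(r.age), height=float(r.height), mass=float(r.mass),
        bmi=float(r.bmi),
        vas=None if pd.isna(r.vas) else float(r.vas),
        odi=None if pd.isna(r.odi) else float(r.odi),
    ) for r in df.itertuples()]


def cohort_checksum(profiles: list[SubjectProfile]) -> str:
    """Stable content hash used by the pipeline manifest."""
    csv = cohort_to_frame(profiles).to_csv(index=False, float_format="%.12g")
    return hashlib.sha256(csv.encode()).hexdigest()
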
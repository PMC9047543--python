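"""Per-trial summary features and the subjects x 118 feature table.

Each trial's time series are reduced to the minimum and maximum of 59
channels: 8 joint-angle channels (four joints in joint and world frames),
the sagittal vertical axis, 4 normalized joint torques, 4 normalized joint
powers, 4 normalized L5S1 force channels (extensor muscle, lumbar
compression, lumbar anterior shear, sacral compression), and 38 segment
translational velocity/acceleration channels across world/body/joint
reference frames.  That yields 118 features per trial; a subject's trials
are averaged element-wise so each subject contributes one independent row.

Kinematic channels are summarized over the full movement window
(start..end); torque, power and force channels over the seat-off..end
window, where the chain is airborne from the chair and the no-external-
contact assumption of the inverse dynamics holds.

The default channel roster is checked in as ``data/channel_dictionary.json``
and validated (exactly 59 uniquely named channels) every time it is loaded;
alternative rosters can be supplied as JSON files of the same shape.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .body import JOINTS, SEGMENTS
from .dynamics import DynamicsSeries
from .errors import InvalidArgumentError, InvalidConfigError, InvalidDataError
from .kinematics import Events, KinematicSeries
from .spine import SpineLoadSeries

N_CHANNELS = 59
N_FEATURES = 2 * N_CHANNELS

_META_COLUMNS = ("group", "sex", "age", "height", "mass", "bmi", "vas", "odi")


@dataclass(frozen=True)
class ChannelDef:
    """One time-series channel resolvable against the pipeline outputs."""

    name: str
    source: str           # kinematics | dynamics | spine
    target: str           # joint or segment name, or "torso_end"/"l5s1"
    quantity: str         # angle | velocity | acceleration | torque | power | force | sva
    direction: str        # anterior | vertical | n/a
    frame: str            # joint | body | world | n/a
    units: str
    window: str           # movement | post_seatoff


@dataclass(frozen=True)
class DataDictionary:
    """Ordered roster of the channels feeding the feature table."""

    channels: tuple[ChannelDef, ...]
    version: str = "1"

    def __post_init__(self) -> None:
        names = [c.name for c in self.channels]
        if len(names) != len(set(names)):
            raise InvalidConfigError("channel names must be unique")
        if len(names) != N_CHANNELS:
            raise InvalidConfigError(
                f"dictionary must define exactly {N_CHANNELS} channels, got {len(names)}"
            )

    @property
    def feature_names(self) -> list[str]:
        out: list[str] = []
        for ch in self.channels:
            out.extend([f"{ch.name}_min", f"{ch.name}_max"])
        return out


def build_default_dictionary() -> DataDictionary:
    """Construct the default 59-channel roster in code."""
    chans: list[ChannelDef] = []
    for joint in JOINTS:
        for frame in ("joint", "world"):
            chans.append(ChannelDef(f"{joint}_angle_{frame}", "kinematics", joint,
                                    "angle", "n/a", frame, "rad", "movement"))
    chans.append(ChannelDef("sva", "kinematics", "torso_end", "sva", "anterior",
                            "world", "m", "movement"))
    for joint in JOINTS:
        chans.append(ChannelDef(f"{joint}_torque_norm", "dynamics", joint, "torque",
                                "n/a", "n/a", "dimensionless", "post_seatoff"))
    for joint in JOINTS:
        chans.append(ChannelDef(f"{joint}_power_norm", "dynamics", joint, "power",
                                "n/a", "n/a", "dimensionless", "post_seatoff"))
    for name in ("l5s1_muscle_force_norm", "l5s1_lumbar_compression_norm",
                 "l5s1_lumbar_shear_norm", "l5s1_sacral_compression_norm"):
        chans.append(ChannelDef(name, "spine", "l5s1", "force", "n/a", "n/a",
                                "body-weights", "post_seatoff"))
    # The shank pivots about the fixed ankle, so its CoM velocity is normal
    # to its own axis: the body-frame "vertical" velocity channel would be
    # identically zero and is excluded from the allocation.
    seg_frames = {"torso": ("world", "body", "joint"),
                  "pelvis": ("world", "body", "joint"),
                  "thigh": ("world", "body"), "shank": ("world",)}
    for seg in SEGMENTS[::-1]:   # torso first, mirroring the trunk-led enumeration
        for frame in seg_frames[seg]:
            for quantity, unit in (("velocity", "m/s"), ("acceleration", "m/s^2")):
                for direction in ("anterior", "vertical"):
                    chans.append(ChannelDef(f"{seg}_{quantity}_{direction}_{frame}",
                                            "kinematics", seg, quantity, direction,
                                            frame, unit, "movement"))
    for quantity, unit in (("velocity", "m/s"), ("acceleration", "m/s^2")):
        chans.append(ChannelDef(f"thigh_{quantity}_anterior_joint", "kinematics",
                                "thigh", quantity, "anterior", "joint", unit,
                                "movement"))
    return DataDictionary(channels=tuple(chans))


def load_dictionary(path: str | Path | None = None) -> DataDictionary:
    """Load a channel dictionary JSON (packaged default when ``path`` is None)."""
    if path is None:
        with resources.files("stsbiomech.data").joinpath("channel_dictionary.json").open() as fh:
            raw = json.load(fh)
    else:
        raw = json.loads(Path(path).read_text())
    return DataDictionary(
        channels=tuple(ChannelDef(**c) for c in raw["channels"]),
        version=str(raw.get("version", "1")),
    )


def write_dictionary(dictionary: DataDictionary, path: str | Path) -> None:
    payload = {"version": dictionary.version,
               "channels": [asdict(c) for c in dictionary.channels]}
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


# --------------------------------------------------------------------------
# Channel resolution and per-trial extraction
# --------------------------------------------------------------------------

def channel_series(ch: ChannelDef, kin: KinematicSeries, dyn: DynamicsSeries,
                   spine: SpineLoadSeries) -> np.ndarray:
    """Resolve one channel definition to its per-frame values."""
    if ch.quantity == "angle":
        j = JOINTS.index(ch.target)
        return (kin.joint_angles if ch.frame == "joint" else kin.world_angles)[:, j]
    if ch.quantity == "sva":
        if kin.sva is None:
            raise InvalidDataError("kinematics lack the SVA channel")
        return kin.sva
    if ch.quantity in ("velocity", "acceleration"):
        store = kin.com_vel if ch.quantity == "velocity" else kin.com_acc
        if ch.frame not in store:
            raise InvalidConfigError(f"channel {ch.name}: frame {ch.frame!r} not available")
        k = SEGMENTS.index(ch.target)
        d = ("anterior", "vertical").index(ch.direction)
        return store[ch.frame][:, k, d]
    if ch.quantity == "torque":
        if dyn.torque_norm is None:
            raise InvalidDataError("dynamics lack normalized torques")
        return dyn.torque_norm[:, JOINTS.index(ch.target)]
    if ch.quantity == "power":
        if dyn.power_norm is None:
            raise InvalidDataError("dynamics lack normalized powers")
        return dyn.power_norm[:, JOINTS.index(ch.target)]
    if ch.quantity == "force":
        attr = {
            "l5s1_muscle_force_norm": "extensor_muscle_force_norm",
            "l5s1_lumbar_compression_norm": "lumbar_compression_norm",
            "l5s1_lumbar_shear_norm": "lumbar_anterior_shear_norm",
            "l5s1_sacral_compression_norm": "sacral_compression_norm",
        }.get(ch.name)
        if attr is None or getattr(spine, attr) is None:
            raise InvalidConfigError(f"unresolvable spine channel {ch.name!r}")
        return getattr(spine, attr)
    raise InvalidConfigError(f"unresolvable channel {ch.name!r} (quantity {ch.quantity!r})")


def extract_trial_features(
    kin: KinematicSeries,
    dyn: DynamicsSeries,
    spine: SpineLoadSeries,
    dictionary: DataDictionary,
    events: Events,
) -> np.ndarray:
    """Min and max of every dictionary channel over its window; length 118."""
    out = np.empty(2 * len(dictionary.channels))
    for i, ch in enumerate(dictionary.channels):
        values = channel_series(ch, kin, dyn, spine)
        lo = events.start if ch.window == "movement" else events.seatoff
        segment = values[lo:events.end + 1]
        if len(segment) == 0:
            raise InvalidDataError(f"channel {ch.name}: empty feature window")
        out[2 * i] = segment.min()
        out[2 * i + 1] = segment.max()
    return out


def average_subject_features(trial_features: list[np.ndarray]) -> np.ndarray:
    """Element-wise mean of one subject's trial feature vectors."""
    if len(trial_features) == 0:
        raise InvalidArgumentError("at least one trial feature vector is required")
    lengths = {len(v) for v in trial_features}
    if len(lengths) != 1:
        raise InvalidDataError(f"trial feature vectors differ in length: {sorted(lengths)}")
    return np.mean(np.asarray(trial_features, dtype=float), axis=0)


# --------------------------------------------------------------------------
# Feature table
# --------------------------------------------------------------------------

@dataclass
class FeatureTable:
    """Subjects x 118 features with metadata and provenance."""

    data: pd.DataFrame            # index: subject_id; metadata + feature columns
    dictionary: DataDictionary
    config_hash: str = ""

    def __post_init__(self) -> None:
        feats = self.feature_names
        missing = [c for c in feats if c not in self.data.columns]
        if missing:
            raise InvalidDataError(f"feature table missing columns {missing[:5]}...")
        if len(feats) != N_FEATURES:
            raise InvalidDataError(f"expected {N_FEATURES} features, got {len(feats)}")
        if self.data.index.has_duplicates:
            raise InvalidDataError("each subject must appear exactly once")
        if len(self.data) and self.data[feats].isna().any().any():
            bad = self.data[feats].isna().any()
            raise InvalidDataError(
                f"missing feature values in columns {list(bad[bad].index[:5])}"
            )

    @property
    def feature_names(self) -> list[str]:
        return self.dictionary.feature_names

    @property
    def features(self) -> pd.DataFrame:
        return self.data[self.feature_names]

    @property
    def n_subjects(self) -> int:
        return len(self.data)


def build_feature_table(
    cohort: list,
    subject_features: dict[str, np.ndarray],
    dictionary: DataDictionary,
    config_hash: str = "",
) -> FeatureTable:
    """Join per-subject averaged features with subject metadata."""
    missing = [p.subject_id for p in cohort if p.subject_id not in subject_features]
    if missing:
        raise InvalidDataError(f"missing feature vectors for subjects {missing}")
    feat_names = dictionary.feature_names
    rows = []
    for p in cohort:
        vec = np.asarray(subject_features[p.subject_id], dtype=float)
        if len(vec) != len(feat_names):
            raise InvalidDataError(
                f"subject {p.subject_id}: feature vector length {len(vec)} != {len(feat_names)}"
            )
        row = {"group": p.group, "sex": p.sex, "age": p.age, "height": p.height,
               "mass": p.mass, "bmi": p.bmi,
               "vas": np.nan if p.vas is None else p.vas,
               "odi": np.nan if p.odi is None else p.odi}
        row.update(dict(zip(feat_names, vec)))
        rows.append(row)
    data = pd.DataFrame(rows, index=pd.Index([p.subject_id for p in cohort],
                                             name="subject_id"),
                        columns=list(_META_COLUMNS) + feat_names)
    return FeatureTable(data=data, dictionary=dictionary, config_hash=config_hash)


def write_feature_table(table: FeatureTable, csv_path: str | Path,
                        dictionary_path: str | Path | None = None) -> None:
    table.data.to_csv(csv_path, float_format="%.15g")
    if dictionary_path is not None:
        write_dictionary(table.dictionary, dictionary_path)


def read_feature_table(csv_path: str | Path,
                       dictionary: DataDictionary | None = None) -> FeatureTable:
    data = pd.read_csv(csv_path, index_col="subject_id", float_precision="round_trip")
    return FeatureTable(data=data, dictionary=dictionary or load_dictionary())
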
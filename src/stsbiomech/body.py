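"""Allometric scaling of the planar four-link sit-to-stand chain.

The body is modelled as a quadruple pendulum in the sagittal plane: four
rigid links (shank, thigh, pelvis, torso) articulated at the ankle, knee,
hip, and L5S1 joints, with the ankle fixed to the ground.  Because both
legs move together during a symmetric sit-to-stand, the "shank" and
"thigh" links lump the left and right limbs; the "torso" link lumps the
upper trunk with the head and the arms held at the sides, and is split
from the pelvis at the lumbosacral (L5S1) junction.

Segment geometry and inertia are obtained by allometric scaling from the
subject's sex, height ``H`` and body mass ``M``:

* length      = length_fraction   x H
* mass        = mass_fraction     x M
* inertia_com = mass x (gyration_fraction x length)^2

The default fraction table (``data/anthropometry.csv``) carries de
Leva-style sex-specific coefficients adapted to the four-link lumping
above; it is a plain CSV and fully injectable, so alternative
anthropometric tables can be swapped in without touching code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError

SEGMENTS = ("shank", "thigh", "pelvis", "torso")
JOINTS = ("ankle", "knee", "hip", "l5s1")

GRAVITY = 9.81  # m/s^2


@dataclass(frozen=True)
class SegmentParams:
    """Inertial and geometric parameters of one rigid link."""

    length: float          # m
    mass: float            # kg
    com_fraction: float    # distance of the CoM from the lower (distal) joint, as a fraction of length
    inertia_com: float     # kg m^2, about the out-of-plane axis through the CoM

    @property
    def com_offset(self) -> float:
        """Distance (m) of the CoM from the segment's lower joint."""
        return self.com_fraction * self.length


@dataclass(frozen=True)
class LinkageModel:
    """Planar four-link chain, ordered ankle -> knee -> hip -> L5S1.

    ``segments`` maps each of :data:`SEGMENTS` to its parameters; the
    segment above joint ``i`` is ``SEGMENTS[i]``.
    """

    segments: dict[str, SegmentParams]
    gravity: float = GRAVITY
    height: float = field(default=np.nan)
    total_mass: float = field(default=np.nan)

    def __post_init__(self) -> None:
        for name in SEGMENTS:
            if name not in self.segments:
                raise InvalidArgumentError(f"missing segment {name!r}")
            seg = self.segments[name]
            for attr in ("length", "mass", "inertia_com"):
                if getattr(seg, attr) <= 0:
                    raise InvalidArgumentError(
                        f"segment {name!r}: {attr} must be > 0, got {getattr(seg, attr)}"
                    )
            if not 0.0 < seg.com_fraction < 1.0:
                raise InvalidArgumentError(
                    f"segment {name!r}: com_fraction must lie in (0, 1), got {seg.com_fraction}"
                )
        if np.isfinite(self.total_mass) and self.segment_mass_total > self.total_mass + 1e-9:
            raise InvalidArgumentError(
                "sum of segment masses exceeds body mass "
                f"({self.segment_mass_total:.3f} > {self.total_mass:.3f} kg)"
            )
        if np.isfinite(self.height) and self.chain_length >= self.height:
            raise InvalidArgumentError(
                f"total chain length {self.chain_length:.3f} m is not below height {self.height:.3f} m"
            )

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.segments[s].length for s in SEGMENTS])

    @property
    def masses(self) -> np.ndarray:
        return np.array([self.segments[s].mass for s in SEGMENTS])

    @property
    def com_offsets(self) -> np.ndarray:
        return np.array([self.segments[s].com_offset for s in SEGMENTS])

    @property
    def inertias(self) -> np.ndarray:
        return np.array([self.segments[s].inertia_com for s in SEGMENTS])

    @property
    def segment_mass_total(self) -> float:
        return float(self.masses.sum())

    @property
    def chain_length(self) -> float:
        return float(self.lengths.sum())


LANDMARKS = ("ankle", "knee", "hip", "l5s1", "torso_end")


def forward_kinematics(linkage: LinkageModel, world_angles: np.ndarray) -> np.ndarray:
    """Landmark positions of the chain for given world segment angles.

    ``world_angles`` holds the orientation of each segment measured from the
    upward vertical, positive tilting anterior (+x); shape ``(..., 4)``.
    Returns positions of the five landmarks (ankle, knee, hip, L5S1,
    torso_end) with the ankle at the origin; shape ``(..., 5, 2)`` with
    components (anterior x, vertical y).
    """
    phi = np.asarray(world_angles, dtype=float)
    steps = np.stack([np.sin(phi), np.cos(phi)], axis=-1) * linkage.lengths[..., :, None]
    pts = np.zeros(phi.shape[:-1] + (5, 2))
    pts[..., 1:, :] = np.cumsum(steps, axis=-2)
    return pts


def load_anthropometry_table(path: str | Path | None = None) -> pd.DataFrame:
    """Load an anthropometry fraction table (the packaged default if ``path`` is None)."""
    if path is None:
        with resources.files("stsbiomech.data").joinpath("anthropometry.csv").open() as fh:
            table = pd.read_csv(fh)
    else:
        table = pd.read_csv(path)
    required = {"segment", "sex", "length_fraction", "mass_fraction",
                "com_fraction", "gyration_fraction"}
    missing = required - set(table.columns)
    if missing:
        raise InvalidArgumentError(f"anthropometry table missing columns {sorted(missing)}")
    return table


def scale_segments(
    sex: int | str,
    height: float,
    mass: float,
    table: pd.DataFrame | None = None,
    gravity: float = GRAVITY,
) -> LinkageModel:
    """Build a :class:`LinkageModel` for one subject.

    Parameters
    ----------
    sex:
        ``0``/``"female"`` or ``1``/``"male"`` (clinical coding: 0 = female,
        1 = male).
    height, mass:
        Stature in meters (1.2-2.2) and body mass in kilograms (30-200).
    table:
        Fraction table as returned by :func:`load_anthropometry_table`;
        the packaged default is used when omitted.
    """
    if isinstance(sex, str):
        sex_label = sex.lower()
        if sex_label not in ("male", "female"):
            raise InvalidArgumentError(f"sex must be 'male'/'female' or 0/1, got {sex!r}")
    else:
        if sex not in (0, 1):
            raise InvalidArgumentError(f"sex must be 'male'/'female' or 0/1, got {sex!r}")
        sex_label = "male" if sex == 1 else "female"
    if not 1.2 < height < 2.2:
        raise InvalidArgumentError(f"height {height} m outside the supported range (1.2, 2.2)")
    if not 30.0 < mass < 200.0:
        raise InvalidArgumentError(f"mass {mass} kg outside the supported range (30, 200)")

    if table is None:
        table = load_anthropometry_table()
    rows = table[table["sex"] == sex_label].set_index("segment")

    segments: dict[str, SegmentParams] = {}
    for name in SEGMENTS:
        if name not in rows.index:
            raise InvalidArgumentError(f"anthropometry table has no row for ({name}, {sex_label})")
        row = rows.loc[name]
        length = float(row["length_fraction"]) * height
        seg_mass = float(row["mass_fraction"]) * mass
        gyr = float(row["gyration_fraction"]) * length
        segments[name] = SegmentParams(
            length=length,
            mass=seg_mass,
            com_fraction=float(row["com_fraction"]),
            inertia_com=seg_mass * gyr * gyr,
        )
    return LinkageModel(segments=segments, gravity=gravity, height=height, total_mass=mass)
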
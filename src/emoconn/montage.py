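"""18-channel 10-20 montage on a spherical head and the three connectivity pair-groups.

Scalp connectivity between electrode pairs is grouped by anatomy and
inter-electrode distance into three families that behave differently during
emotion-eliciting stimulation:

* ``LD_OF``  -- long-distance occipital-to-frontal (visual cortex to the
  frontal/prefrontal executive areas),
* ``LD_PF``  -- long-distance prefrontal to temporal/central/parietal,
* ``SD``    -- short-distance (< 10 cm geodesic) pairs between adjacent
  regions (frontal-temporal, frontal-central, temporal-parietal,
  parietal-central).

Everything else is ``OTHER``.  The 18-electrode subset of the international
10-20 system used here (the 19-electrode set minus Fz) yields exactly
C(18, 2) = 153 unordered pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "Montage",
    "PairGroup",
    "REGION_PRECEDENCE",
    "build_montage",
    "pair_distance",
    "classify_pairs",
    "canonical_pair",
    "montage_to_frame",
    "montage_from_frame",
]

#: Region precedence fixing the canonical order of a pair (first channel =
#: higher-precedence region) and therefore the sign of every downstream
#: power-difference feature.
REGION_PRECEDENCE = {
    "occipital": 0,
    "prefrontal": 1,
    "frontal": 2,
    "temporal": 3,
    "central": 4,
    "parietal": 5,
}

_REGION_OF = {
    "Fp1": "prefrontal", "Fp2": "prefrontal",
    "F7": "frontal", "F3": "frontal", "F4": "frontal", "F8": "frontal",
    "T3": "temporal", "T4": "temporal", "T5": "temporal", "T6": "temporal",
    "C3": "central", "Cz": "central", "C4": "central",
    "P3": "parietal", "Pz": "parietal", "P4": "parietal",
    "O1": "occipital", "O2": "occipital",
}

_CHANNEL_ORDER = [
    "Fp1", "Fp2", "F7", "F3", "F4", "F8",
    "T3", "T4", "T5", "T6",
    "C3", "Cz", "C4",
    "P3", "Pz", "P4",
    "O1", "O2",
]

#: Region pairs eligible for the short-distance group.
_SD_REGION_PAIRS = {
    frozenset(("frontal", "temporal")),
    frozenset(("frontal", "central")),
    frozenset(("temporal", "parietal")),
    frozenset(("parietal", "central")),
}

DEFAULT_HEAD_RADIUS_CM = 9.2
SHORT_DISTANCE_CM = 10.0


class MontageError(ValueError):
    """Configuration or lookup problem with a montage."""


@dataclass(frozen=True)
class Montage:
    """Electrode layout on a sphere.

    positions map channel -> (azimuth, elevation) in radians. Azimuth is
    measured from the nasion (front of the head), positive toward the left
    ear; elevation from the equatorial ring toward the vertex.
    """

    channels: tuple[str, ...]
    positions: dict[str, tuple[float, float]]
    regions: dict[str, str]
    head_radius: float = DEFAULT_HEAD_RADIUS_CM

    def __post_init__(self) -> None:
        if len(self.channels) != len(set(self.channels)):
            raise MontageError("channel labels must be unique")
        for ch in self.channels:
            if ch not in self.positions:
                raise MontageError(f"missing position for channel {ch!r}")
            if ch not in self.regions:
                raise MontageError(f"missing region for channel {ch!r}")
            if self.regions[ch] not in REGION_PRECEDENCE:
                raise MontageError(f"unknown region {self.regions[ch]!r}")
        if self.head_radius <= 0:
            raise MontageError("head_radius must be positive")

    @property
    def n_pairs(self) -> int:
        n = len(self.channels)
        return n * (n - 1) // 2

    def unit_vector(self, channel: str) -> np.ndarray:
        """Cartesian unit vector (x=front, y=left, z=up) of an electrode."""
        if channel not in self.positions:
            raise MontageError(f"unknown channel {channel!r}")
        az, el = self.positions[channel]
        return np.array(
            [math.cos(el) * math.cos(az), math.cos(el) * math.sin(az), math.sin(el)]
        )


@dataclass(frozen=True)
class PairGroup:
    """One unordered electrode pair with its distance-group assignment."""

    pair: tuple[str, str]
    group: str  # LD_OF | LD_PF | SD | OTHER
    distance_cm: float


def _slerp_mid(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    m = u + v
    return m / np.linalg.norm(m)


def _ideal_1020_positions() -> dict[str, tuple[float, float]]:
    """Ideal spherical 10-20 angles for the 18-channel set.

    Ring electrodes sit on the equator at 18 degree steps from the nasion;
    C3/C4 and Pz sit 36 degrees from the vertex; F3/F4 (P3/P4) are the
    great-circle midpoints between F7/F8 (T5/T6) and the midline Fz (Pz)
    anchors, mirroring how a technician places them.
    """
    d = math.radians
    pos: dict[str, tuple[float, float]] = {
        "Fp1": (d(18), 0.0), "Fp2": (d(-18), 0.0),
        "F7": (d(54), 0.0), "F8": (d(-54), 0.0),
        "T3": (d(90), 0.0), "T4": (d(-90), 0.0),
        "T5": (d(126), 0.0), "T6": (d(-126), 0.0),
        "O1": (d(162), 0.0), "O2": (d(-162), 0.0),
        "C3": (d(90), d(54)), "C4": (d(-90), d(54)),
        "Cz": (0.0, d(90)),
        "Pz": (d(180), d(54)),
    }

    def vec(az: float, el: float) -> np.ndarray:
        return np.array(
            [math.cos(el) * math.cos(az), math.cos(el) * math.sin(az), math.sin(el)]
        )

    def ang(v: np.ndarray) -> tuple[float, float]:
        return math.atan2(v[1], v[0]), math.asin(np.clip(v[2], -1.0, 1.0))

    fz = vec(0.0, d(54))  # construction anchor only; Fz is not a channel here
    pos["F3"] = ang(_slerp_mid(vec(*pos["F7"]), fz))
    pos["F4"] = ang(_slerp_mid(vec(*pos["F8"]), fz))
    pos["P3"] = ang(_slerp_mid(vec(*pos["T5"]), vec(*pos["Pz"])))
    pos["P4"] = ang(_slerp_mid(vec(*pos["T6"]), vec(*pos["Pz"])))
    return pos


_COORDINATE_SETS = {"1020-18": _ideal_1020_positions}


def build_montage(coordinate_set_name: str = "1020-18") -> Montage:
    """Build a registered montage; the default is the 18-channel 10-20 set."""
    try:
        builder = _COORDINATE_SETS[coordinate_set_name]
    except KeyError:
        raise MontageError(
            f"unknown coordinate set {coordinate_set_name!r}; "
            f"registered: {sorted(_COORDINATE_SETS)}"
        ) from None
    return Montage(
        channels=tuple(_CHANNEL_ORDER),
        positions=builder(),
        regions=dict(_REGION_OF),
    )


def pair_distance(m: Montage, a: str, b: str) -> float:
    """Great-circle scalp distance in cm between two distinct electrodes."""
    if a == b:
        raise MontageError("pair_distance requires two distinct channels")
    ua, ub = m.unit_vector(a), m.unit_vector(b)
    # atan2 form is stable near parallel and antipodal electrode positions
    angle = math.atan2(float(np.linalg.norm(np.cross(ua, ub))),
                       float(np.dot(ua, ub)))
    return m.head_radius * angle


def canonical_pair(m: Montage, a: str, b: str) -> tuple[str, str]:
    """Order a pair by region precedence, then montage order within region."""
    def key(ch: str) -> tuple[int, int]:
        return (REGION_PRECEDENCE[m.regions[ch]], m.channels.index(ch))

    return (a, b) if key(a) < key(b) else (b, a)


def _group_of(m: Montage, a: str, b: str, dist: float) -> str:
    ra, rb = m.regions[a], m.regions[b]
    rs = {ra, rb}
    if "occipital" in rs and rs & {"frontal", "prefrontal"}:
        return "LD_OF"
    if "prefrontal" in rs and rs & {"temporal", "central", "parietal"}:
        return "LD_PF"
    if frozenset(rs) in _SD_REGION_PAIRS and dist < SHORT_DISTANCE_CM:
        return "SD"
    return "OTHER"


def classify_pairs(m: Montage) -> list[PairGroup]:
    """Assign each of the montage's unordered pairs to exactly one group.

    Returns one :class:`PairGroup` per pair (153 for the 18-channel set),
    with pairs in canonical order.
    """
    out: list[PairGroup] = []
    for a, b in combinations(m.channels, 2):
        first, second = canonical_pair(m, a, b)
        dist = pair_distance(m, first, second)
        out.append(PairGroup((first, second), _group_of(m, first, second, dist), dist))
    return out


def montage_to_frame(m: Montage) -> pd.DataFrame:
    """Serializable table: channel, azimuth_deg, elevation_deg, region."""
    rows = [
        {
            "channel": ch,
            "azimuth_deg": math.degrees(m.positions[ch][0]),
            "elevation_deg": math.degrees(m.positions[ch][1]),
            "region": m.regions[ch],
        }
        for ch in m.channels
    ]
    return pd.DataFrame(rows)


def montage_from_frame(df: pd.DataFrame, head_radius: float = DEFAULT_HEAD_RADIUS_CM) -> Montage:
    required = {"channel", "azimuth_deg", "elevation_deg", "region"}
    missing = required - set(df.columns)
    if missing:
        raise MontageError(f"montage table missing columns: {sorted(missing)}")
    channels = tuple(df["channel"])
    positions = {
        r.channel: (math.radians(r.azimuth_deg), math.radians(r.elevation_deg))
        for r in df.itertuples()
    }
    regions = {r.channel: r.region for r in df.itertuples()}
    return Montage(channels=channels, positions=positions, regions=regions,
                   head_radius=head_radius)
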
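"""Anatomical marker taxonomy and marker/trajectory containers.

The marker model is an 11-landmark set on one lower limb, placed on the
medial side of the foot (7 markers), the posterior hindfoot/shank (3), and
the lateral calf (1). Marker heights and ordering drive both automatic
labeling of detections and the rule-based gait-event logic.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

import numpy as np

from .geometry import Point3D


class AnatomicalLabel(str, enum.Enum):
    """The 11 anatomical landmarks, numbered as on the marker model."""

    DIP1 = "DIP1"          # 1: first distal interphalangeal joint
    HM = "HM"              # 2: head of first metatarsal
    MT1_MID = "MT1_MID"    # 3: midpoint of the first metatarsal shaft
    NV = "NV"              # 4: navicular tuberosity
    MM = "MM"              # 5: medial malleolus
    CALC = "CALC"          # 6: calcaneal tuberosity (posteromedial calcaneus)
    KNEE = "KNEE"          # 7: medial knee joint line
    ACH = "ACH"            # 8: Achilles tendon attachment (posterior calcaneus)
    PAJL = "PAJL"          # 9: posterior ankle joint line, level with MM
    GMTJ = "GMTJ"          # 10: gastrocnemius musculotendinous junction
    CALF = "CALF"          # 11: lateral half of the calf

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Markers visible from each camera view, in anatomical order.
MEDIAL_LABELS = (
    AnatomicalLabel.DIP1, AnatomicalLabel.HM, AnatomicalLabel.MT1_MID,
    AnatomicalLabel.NV, AnatomicalLabel.MM, AnatomicalLabel.CALC,
    AnatomicalLabel.KNEE,
)
POSTERIOR_LABELS = (AnatomicalLabel.ACH, AnatomicalLabel.PAJL, AnatomicalLabel.GMTJ)
LATERAL_LABELS = (AnatomicalLabel.CALF,)

SIDES = ("left", "right")


class MissingMarkerError(KeyError):
    """A required anatomical landmark is absent."""


@dataclass
class LabeledMarkerSet:
    """Positions of the 11 landmarks for one foot at one instant.

    Absent markers are represented explicitly as ``None`` (an occluded
    marker must surface as missing downstream, never as a silent guess).
    """

    side: str
    positions: Dict[AnatomicalLabel, Optional[Point3D]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.side not in SIDES:
            raise ValueError(f"side must be one of {SIDES}, got {self.side!r}")

    def get(self, label: AnatomicalLabel) -> Point3D:
        p = self.positions.get(label)
        if p is None:
            raise MissingMarkerError(f"marker {label.value} is missing ({self.side})")
        return p

    def has(self, label: AnatomicalLabel) -> bool:
        return self.positions.get(label) is not None


@dataclass
class TrajectorySet:
    """Per-frame 3D positions of the marker model, both sides, fixed rate.

    ``data[side][label]`` is an ``(n_frames, 3)`` float array in metres;
    missing samples are NaN rows.
    """

    fps: float
    n_frames: int
    data: Dict[str, Dict[AnatomicalLabel, np.ndarray]]
    treadmill_speed: float = 0.0

    def __post_init__(self) -> None:
        for side, markers in self.data.items():
            if side not in SIDES:
                raise ValueError(f"unknown side {side!r}")
            for label, arr in markers.items():
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (self.n_frames, 3):
                    raise ValueError(
                        f"{side}/{label}: expected shape ({self.n_frames}, 3), "
                        f"got {arr.shape}"
                    )
                markers[label] = arr

    def marker(self, side: str, label: AnatomicalLabel) -> np.ndarray:
        """(n, 3) trajectory of one marker; all-NaN if never observed."""
        try:
            return self.data[side][label]
        except KeyError:
            return np.full((self.n_frames, 3), np.nan)

    def coverage(self, side: str, label: AnatomicalLabel) -> float:
        """Fraction of frames where the marker is fully observed."""
        return float(np.mean(np.all(np.isfinite(self.marker(side, label)), axis=1)))

    def frame_markers(self, side: str, frame: int) -> LabeledMarkerSet:
        """Snapshot of one side at one frame as a :class:`LabeledMarkerSet`."""
        positions: Dict[AnatomicalLabel, Optional[Point3D]] = {}
        for label in AnatomicalLabel:
            xyz = self.marker(side, label)[frame]
            positions[label] = Point3D(*xyz) if np.all(np.isfinite(xyz)) else None
        return LabeledMarkerSet(side=side, positions=positions)

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps


def marker_set_from_mapping(side: str, mapping: Mapping) -> LabeledMarkerSet:
    """Build a :class:`LabeledMarkerSet` from ``{label: (x, y, z)}``."""
    positions: Dict[AnatomicalLabel, Optional[Point3D]] = {}
    for key, value in mapping.items():
        label = key if isinstance(key, AnatomicalLabel) else AnatomicalLabel(str(key))
        positions[label] = None if value is None else Point3D(*map(float, value))
    return LabeledMarkerSet(side=side, positions=positions)
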
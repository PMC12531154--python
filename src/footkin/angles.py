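"""The five clinical foot/ankle angles and their phase-anchored scalars.

Angle definitions (all vertices/endpoints are anatomical markers):

* **MLA** — medial longitudinal arch angle at the navicular tuberosity.
  Two variants exist: ``"equation"`` uses MM-NV-HM (medial malleolus /
  navicular / first metatarsal head) and is the default; ``"text"`` uses
  HM-NV-CALC (first metatarsal head / navicular / posteromedial calcaneus).
  A larger angle means a flatter arch.
* **CA** — subtalar (calcaneal) angle at the posterior ankle joint line
  between the posterior calcaneus (ACH) and the gastrocnemius
  musculotendinous junction (GMTJ); 180 deg is neutral hindfoot alignment.
  This output is tagged experimental: posterior-view subtalar estimates are
  known to be the least reliable of the five angles.
* **ANK** — ankle angle between the foot axis (CALC -> HM) and the shank
  axis (MM -> KNEE), evaluating the heel rocker.
* **AI** — signed tibia inclination: tilt of the MM -> KNEE segment from
  vertical, positive anterior, evaluating the ankle rocker.
* **MTP** — first metatarsophalangeal angle at the metatarsal head between
  the shaft midpoint (MT1_MID) and the hallux (DIP1); 180 deg is a neutral
  toe, extension = 180 - MTP, evaluating the forefoot rocker.

Phase anchoring samples each series at its clinically meaningful event
frames, yielding 19 scalars per cycle. The subtalar angle is by definition
not anchored at terminal stance (it cannot be read reliably from a
posterior view there), so ``CA_TSt`` is never produced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .anatomy import AnatomicalLabel as L
from .anatomy import LabeledMarkerSet, MissingMarkerError, TrajectorySet
from .geometry import (
    angle_at_vertex,
    angle_at_vertex_series,
    angle_between,
    signed_inclination,
    signed_inclination_series,
)
from .segmentation import CycleEvents

logger = logging.getLogger(__name__)

ANGLE_NAMES = ("MLA", "CA", "ANK", "AI", "MTP")

#: The 19 phase-anchored scalars: angle -> events it is read at.
ANCHOR_EVENTS: Dict[str, tuple] = {
    "MLA": ("IC", "LR", "MSt", "TSt", "PSw", "HE"),
    "CA": ("IC", "LR", "MSt", "PSw"),   # CA_TSt deliberately absent
    "ANK": ("IC", "LR"),
    "AI": ("LR", "MSt", "TSt"),
    "MTP": ("TSt", "PSw", "HE", "ISw"),
}

ANCHOR_NAMES = tuple(
    f"{angle}_{event}" for angle, events in ANCHOR_EVENTS.items() for event in events
)
assert len(ANCHOR_NAMES) == 19


# --------------------------------------------------------------------------
# Single-frame operators
# --------------------------------------------------------------------------

def mla_angle(markers: LabeledMarkerSet, variant: str = "equation") -> float:
    """Medial longitudinal arch angle (degrees) at the navicular."""
    if variant == "equation":
        return angle_at_vertex(markers.get(L.NV), markers.get(L.MM), markers.get(L.HM))
    if variant == "text":
        return angle_at_vertex(markers.get(L.NV), markers.get(L.HM), markers.get(L.CALC))
    raise ValueError(f"unknown MLA variant {variant!r} (use 'equation' or 'text')")


def subtalar_angle(markers: LabeledMarkerSet) -> float:
    """Subtalar (calcaneal) angle (degrees) at the posterior ankle joint line."""
    return angle_at_vertex(markers.get(L.PAJL), markers.get(L.ACH), markers.get(L.GMTJ))


def ankle_angle(markers: LabeledMarkerSet) -> float:
    """Ankle angle (degrees) between foot axis CALC->HM and shank axis MM->KNEE."""
    foot = np.subtract(markers.get(L.HM), markers.get(L.CALC))
    shank = np.subtract(markers.get(L.KNEE), markers.get(L.MM))
    return angle_between(foot, shank)


def tibia_inclination(markers: LabeledMarkerSet) -> float:
    """Signed tibia inclination (degrees); positive = anterior tilt."""
    return signed_inclination(markers.get(L.MM), markers.get(L.KNEE))


def mtp_angle(markers: LabeledMarkerSet) -> float:
    """First metatarsophalangeal angle (degrees) at the metatarsal head."""
    return angle_at_vertex(markers.get(L.HM), markers.get(L.MT1_MID), markers.get(L.DIP1))


# --------------------------------------------------------------------------
# Series computation
# --------------------------------------------------------------------------

@dataclass
class AngleSeries:
    """Per-frame values (degrees) of the five angles; NaN where undefined."""

    mla: np.ndarray
    ca: np.ndarray
    ank: np.ndarray
    ai: np.ndarray
    mtp: np.ndarray
    mla_variant: str = "equation"

    @property
    def n_frames(self) -> int:
        return len(self.mla)

    def series(self, name: str) -> np.ndarray:
        return getattr(self, name.lower())

    def as_dict(self) -> Dict[str, np.ndarray]:
        return {name: self.series(name) for name in ANGLE_NAMES}


def compute_angle_series(traj: TrajectorySet, side: str,
                         mla_variant: str = "equation") -> AngleSeries:
    """All five angle series for one side, NaN-propagating per frame.

    A frame missing any defining landmark yields NaN for that angle only;
    the other angles are unaffected.
    """
    def m(label: L) -> np.ndarray:
        return traj.marker(side, label)

    if mla_variant == "equation":
        mla = angle_at_vertex_series(m(L.NV), m(L.MM), m(L.HM))
    elif mla_variant == "text":
        mla = angle_at_vertex_series(m(L.NV), m(L.HM), m(L.CALC))
    else:
        raise ValueError(f"unknown MLA variant {mla_variant!r}")

    ca = angle_at_vertex_series(m(L.PAJL), m(L.ACH), m(L.GMTJ))
    zero = np.zeros_like(m(L.CALC))
    ank = angle_at_vertex_series(zero, m(L.HM) - m(L.CALC), m(L.KNEE) - m(L.MM))
    ai = signed_inclination_series(m(L.MM), m(L.KNEE))
    mtp = angle_at_vertex_series(m(L.HM), m(L.MT1_MID), m(L.DIP1))
    return AngleSeries(mla=mla, ca=ca, ank=ank, ai=ai, mtp=mtp,
                       mla_variant=mla_variant)


def mtp_extension_series(traj: TrajectorySet, side: str) -> np.ndarray:
    """Hallux extension (degrees) per frame: 180 - MTP angle."""
    return 180.0 - angle_at_vertex_series(
        traj.marker(side, L.HM), traj.marker(side, L.MT1_MID),
        traj.marker(side, L.DIP1),
    )


# --------------------------------------------------------------------------
# Phase anchoring
# --------------------------------------------------------------------------

@dataclass
class PhaseAnchoredAngles:
    """The 19 phase-anchored scalars for one gait cycle (degrees)."""

    values: Dict[str, float] = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_dict(self) -> Dict[str, float]:
        return dict(self.values)


def extract_phase_angles(series: AngleSeries, events: CycleEvents) -> PhaseAnchoredAngles:
    """Sample each angle series at its anchor event frames (19 scalars).

    ``CA_TSt`` is never produced. A missing (NaN) angle at an anchor frame
    propagates as NaN with a logged reason.
    """
    event_frames = dict(zip(("IC", "LR", "MSt", "TSt", "PSw", "HE", "ISw"), events))
    out: Dict[str, float] = {}
    for angle, anchor_events in ANCHOR_EVENTS.items():
        values = series.series(angle)
        for event in anchor_events:
            frame = event_frames[event]
            if not 0 <= frame < series.n_frames:
                raise IndexError(
                    f"event {event} frame {frame} outside series of length "
                    f"{series.n_frames}"
                )
            value = float(values[frame])
            if np.isnan(value):
                logger.warning(
                    "%s_%s missing: %s undefined at frame %d (missing landmark)",
                    angle, event, angle, frame,
                )
            out[f"{angle}_{event}"] = value
    return PhaseAnchoredAngles(values=out)


def anchored_table(series: AngleSeries, cycles: Sequence[CycleEvents],
                   side: str) -> List[dict]:
    """Tidy rows (cycle, side, name, value_deg) over all cycles."""
    rows: List[dict] = []
    for k, ev in enumerate(cycles):
        anchored = extract_phase_angles(series, ev)
        for name in ANCHOR_NAMES:
            rows.append({"cycle": k, "side": side, "name": name,
                         "value_deg": anchored[name]})
    return rows
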
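"""Rule-based stance-event detection and 14-class subphase labeling.

Stance is described by 7 events per gait cycle:

==== =======================================================================
IC   initial contact: the heel drops below the ground-contact threshold
LR   loading response (foot flat): the first-metatarsal head drops below the
     threshold while the heel is down
MSt  midstance: the contralateral hallux rises off the ground
     (contralateral toe-off, start of single-limb support)
TSt  terminal stance: the tibia passes through vertical (signed inclination
     of the MM->KNEE segment crosses 0 from posterior to anterior)
PSw  pre-swing: contralateral initial contact
HE   peak hallux extension (argmax of MTP-1 extension before toe-off)
ISw  initial swing: the hallux rises off the ground
==== =======================================================================

Each event instant occupies exactly one frame; frames strictly between two
consecutive events carry the corresponding transition label, giving the
14-class per-frame taxonomy (7 states + 7 transitions).

Ground contact is thresholded at the marker's standing height (estimated
from the lowest decile of its trajectory) plus a 5 mm offset, with 3 mm of
hysteresis to prevent chatter. Height signals are smoothed with a centred
3-frame moving average before crossings are located; crossings are linearly
interpolated between frames and rounded to the nearest frame. The detector
is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, NamedTuple, Optional, Sequence

import numpy as np

from .anatomy import AnatomicalLabel, TrajectorySet
from .geometry import signed_inclination_series

#: The 14 subphase classes in cyclic order.
SUBPHASE_LABELS = (
    "IC", "IC_to_LR", "LR", "LR_to_MSt", "MSt", "MSt_to_TSt", "TSt",
    "TSt_to_PSw", "PSw", "PSw_to_HE", "HE", "HE_to_ISw", "ISw", "ISw_to_IC",
)

#: State (event-instant) labels in event order.
EVENT_NAMES = ("IC", "LR", "MSt", "TSt", "PSw", "HE", "ISw")

UNLABELED = ""


class NoCycleError(RuntimeError):
    """No complete gait cycle could be found in the recording."""


class CoverageError(RuntimeError):
    """A marker required for event detection is observed too rarely."""


class EventOrderingError(ValueError):
    """Events violate the strict cyclic order IC < LR < ... < ISw."""


class CycleEvents(NamedTuple):
    """Frame indices of the 7 stance events of one gait cycle."""

    ic: int
    lr: int
    mst: int
    tst: int
    psw: int
    he: int
    isw: int

    def validate(self) -> "CycleEvents":
        if not all(a < b for a, b in zip(self, self[1:])):
            raise EventOrderingError(f"events not strictly increasing: {self}")
        return self


@dataclass
class EventConfig:
    """Tunables of the rule-based event detector."""

    contact_offset_m: float = 0.005     # threshold above standing height
    hysteresis_m: float = 0.003
    baseline_percentile: float = 10.0   # standing-height estimate
    smooth_window: int = 3              # centred moving average, frames
    min_coverage: float = 0.90          # required marker observation rate


#: Markers the detector needs on *each* side.
REQUIRED_MARKERS = (
    AnatomicalLabel.CALC, AnatomicalLabel.HM, AnatomicalLabel.DIP1,
    AnatomicalLabel.MM, AnatomicalLabel.KNEE,
)


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average; NaNs are bridged by linear interpolation first."""
    x = _fill_gaps(np.asarray(x, dtype=float))
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.concatenate([np.repeat(x[0], pad), x, np.repeat(x[-1], pad)])
    return np.convolve(padded, kernel, mode="valid")[: len(x)]


def _fill_gaps(x: np.ndarray) -> np.ndarray:
    """Linearly interpolate interior NaNs (detector-internal only)."""
    bad = ~np.isfinite(x)
    if not bad.any():
        return x
    if bad.all():
        raise CoverageError("signal has no finite samples")
    idx = np.arange(len(x))
    out = x.copy()
    out[bad] = np.interp(idx[bad], idx[~bad], x[~bad])
    return out


def falling_crossings(y: np.ndarray, threshold: float, hysteresis: float) -> List[float]:
    """Sub-frame times where ``y`` falls through ``threshold``.

    A crossing is reported only after the signal has re-armed above
    ``threshold + hysteresis``; the crossing time is linearly interpolated
    between the bracketing frames.
    """
    times: List[float] = []
    armed = y[0] > threshold + hysteresis
    for i in range(1, len(y)):
        if not armed and y[i] > threshold + hysteresis:
            armed = True
        elif armed and y[i] < threshold <= y[i - 1]:
            frac = (y[i - 1] - threshold) / (y[i - 1] - y[i])
            times.append(i - 1 + frac)
            armed = False
    return times


def rising_crossings(y: np.ndarray, threshold: float, hysteresis: float) -> List[float]:
    """Sub-frame times where ``y`` rises through ``threshold`` (armed below)."""
    times: List[float] = []
    armed = y[0] < threshold - hysteresis
    for i in range(1, len(y)):
        if not armed and y[i] < threshold - hysteresis:
            armed = True
        elif armed and y[i] > threshold >= y[i - 1]:
            frac = (threshold - y[i - 1]) / (y[i] - y[i - 1])
            times.append(i - 1 + frac)
            armed = False
    return times


def contact_threshold(y: np.ndarray, config: EventConfig) -> float:
    """Ground-contact threshold: lowest-decile height + 5 mm offset."""
    return float(np.nanpercentile(y, config.baseline_percentile)) + config.contact_offset_m


def _height(traj: TrajectorySet, side: str, label: AnatomicalLabel,
            config: EventConfig) -> np.ndarray:
    return moving_average(traj.marker(side, label)[:, 1], config.smooth_window)


def _first_after(times: Sequence[float], t0: float, t1: float) -> Optional[float]:
    for t in times:
        if t0 < t < t1:
            return t
    return None


def detect_events(traj: TrajectorySet, side: str,
                  config: Optional[EventConfig] = None) -> List[CycleEvents]:
    """Detect the 7 stance events for every complete cycle of ``side``.

    Raises
    ------
    CoverageError
        If a required marker is observed in fewer than 90% of frames.
    NoCycleError
        If no complete gait cycle is present.
    """
    config = config or EventConfig()
    other = "left" if side == "right" else "right"
    for s in (side, other):
        for label in REQUIRED_MARKERS:
            cov = traj.coverage(s, label)
            if cov < config.min_coverage:
                raise CoverageError(
                    f"marker {label.value} ({s}) observed in {cov:.0%} of frames, "
                    f"need >= {config.min_coverage:.0%}"
                )

    heel = _height(traj, side, AnatomicalLabel.CALC, config)
    fore = _height(traj, side, AnatomicalLabel.HM, config)
    toe = _height(traj, side, AnatomicalLabel.DIP1, config)
    c_heel = _height(traj, other, AnatomicalLabel.CALC, config)
    c_toe = _height(traj, other, AnatomicalLabel.DIP1, config)

    hys = config.hysteresis_m
    ic_times = falling_crossings(heel, contact_threshold(heel, config), hys)
    lr_times = falling_crossings(fore, contact_threshold(fore, config), hys)
    isw_times = rising_crossings(toe, contact_threshold(toe, config), hys)
    mst_times = rising_crossings(c_toe, contact_threshold(c_toe, config), hys)
    psw_times = falling_crossings(c_heel, contact_threshold(c_heel, config), hys)

    # tibia verticality: posterior -> anterior zero crossing
    mm = traj.marker(side, AnatomicalLabel.MM).copy()
    knee = traj.marker(side, AnatomicalLabel.KNEE).copy()
    for arr in (mm, knee):
        for axis in range(3):
            arr[:, axis] = moving_average(arr[:, axis], config.smooth_window)
    ai = signed_inclination_series(mm, knee)
    tst_times = rising_crossings(_fill_gaps(ai), 0.0, 0.0)

    if not ic_times:
        raise NoCycleError("no initial contact found (no heel-height crossings)")

    # Heel-strike of the contralateral foot also defines PSw; MTP extension
    # peak (HE) is located within [PSw, ISw] on the smoothed extension series.
    from .angles import mtp_extension_series  # late import avoids a cycle
    ext = moving_average(mtp_extension_series(traj, side), config.smooth_window)

    cycles: List[CycleEvents] = []
    bounds = list(ic_times[1:]) + [float(traj.n_frames)]  # last cycle may end
    for t_ic, t_next in zip(ic_times, bounds):            # at the recording edge
        # Each crossing is unique within a cycle, so every event is located
        # independently in the (IC, next IC) window; strict frame ordering
        # is then enforced deterministically (rounding can collapse events
        # that are designed/observed less than a frame apart, e.g. LR/MSt).
        found = [_first_after(times, t_ic, t_next)
                 for times in (lr_times, mst_times, tst_times, psw_times,
                               isw_times)]
        if None in found:
            continue  # incomplete cycle at a recording boundary
        f_ic = int(round(t_ic))
        f_lr, f_mst, f_tst, f_psw, f_isw = 0, 0, 0, 0, 0
        frames = [f_ic]
        for t in found:
            frames.append(max(int(round(t)), frames[-1] + 1))
        f_ic, f_lr, f_mst, f_tst, f_psw, f_isw = frames
        f_isw = max(f_isw, f_psw + 2)  # leave room for the HE instant
        if f_isw >= len(ext):
            continue
        window = ext[f_psw + 1: f_isw]  # HE strictly between PSw and ISw
        he = f_psw + 1 + int(np.argmax(window))  # earliest frame wins ties
        cycles.append(CycleEvents(ic=f_ic, lr=f_lr, mst=f_mst, tst=f_tst,
                                  psw=f_psw, he=he, isw=f_isw).validate())

    if not cycles:
        raise NoCycleError("no complete gait cycle with all 7 events")
    return cycles


def label_subphases(events: Sequence[CycleEvents], n_frames: int) -> np.ndarray:
    """Per-frame 14-class labels from per-cycle events.

    Each event frame receives its state label; frames strictly between two
    consecutive events receive the transition label; frames after ISw up to
    (excluding) the next cycle's IC — or the end of the recording for the
    last cycle — receive ``ISw_to_IC``. Frames outside any detected cycle
    stay unlabeled (empty string).
    """
    labels = np.full(n_frames, UNLABELED, dtype=object)
    ordered = sorted(events, key=lambda e: e.ic)
    for ev in ordered:
        ev.validate()
    for k, ev in enumerate(ordered):
        frames = list(ev)
        for i, (name, f) in enumerate(zip(EVENT_NAMES, frames)):
            if 0 <= f < n_frames:
                labels[f] = name
            if i + 1 < len(frames):
                a, b = frames[i], frames[i + 1]
                labels[max(a + 1, 0): min(b, n_frames)] = f"{name}_to_{EVENT_NAMES[i + 1]}"
        end = ordered[k + 1].ic if k + 1 < len(ordered) else n_frames
        labels[max(ev.isw + 1, 0): min(end, n_frames)] = "ISw_to_IC"
    return labels.astype(str)
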
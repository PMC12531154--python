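"""Forward-kinematic synthetic gait generator with exact ground truth.

The generator poses an 11-marker lower-limb model frame by frame from
scheduled gait-phase profiles and emits marker trajectories together with
the ground-truth events, per-frame subphase labels and angle series that
every other module is tested against.

Design principles
-----------------
* Every scheduled quantity is realised *exactly* by the package's own
  definitions: the shank is posed from the tibia-inclination schedule, the
  navicular is placed by an inscribed-angle construction so the arch angle
  equals the MLA schedule, the posterior calcaneus marker is posed from the
  subtalar schedule, and the first-metatarsal shaft marker is posed from
  the MTP-extension schedule. The ankle angle is emergent (it is fully
  determined once foot and shank are posed).
* Heel, forefoot and hallux height profiles are piecewise linear with
  their ground-contact threshold crossings placed exactly at the scheduled
  event fractions, and locally linear over a few frames around each
  crossing so that a centred moving average does not move the crossing.
* Both sides are generated with a half-cycle phase offset, which makes the
  contralateral-event definitions (midstance = contralateral toe-off,
  pre-swing = contralateral initial contact) exact: with an initial-swing
  fraction of 0.60, contralateral toe-off lands at 0.10 of the own cycle.
* Noise is isotropic Gaussian per marker per frame from a single seeded
  generator; a zero-noise copy of the trajectories is retained as truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.interpolate import PchipInterpolator

from .anatomy import SIDES, AnatomicalLabel as L, TrajectorySet
from .angles import AngleSeries, compute_angle_series
from .markers import CameraModel, Frame, look_at
from .segmentation import CycleEvents, label_subphases

DEFAULT_EVENT_FRACTIONS: Dict[str, float] = {
    "IC": 0.00, "LR": 0.08, "MSt": 0.10, "TSt": 0.31,
    "PSw": 0.50, "HE": 0.56, "ISw": 0.60,
}


class ParameterError(ValueError):
    """Infeasible generator parameters (e.g. non-positive segment lengths)."""


@dataclass
class GaitModelParams:
    """Study-condition parameters of the synthetic treadmill recording.

    Defaults emulate a 5 s, 30 fps treadmill capture at a 1.0 cycle/s
    cadence with a 60% stance fraction and 2 mm marker noise.
    """

    fps: float = 30.0
    duration_s: float = 5.0
    cadence: float = 1.0                    # gait cycles per second
    stance_fraction: float = 0.60
    event_fractions: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EVENT_FRACTIONS))
    phase0: float = 0.8                     # right-foot phase at frame 0
    contralateral_offset: float = 0.5
    treadmill_speed: float = 1.0            # m/s, metadata only
    noise_sd: float = 0.002                 # metres
    seed: int = 0

    # limb geometry (metres)
    tibia_len: float = 0.38
    gastroc_len: float = 0.20
    heel_lift: float = 0.06
    forefoot_lift: float = 0.05
    toe_lift: float = 0.04
    contact_offset_m: float = 0.005         # matches the detector threshold

    # angle-profile amplitudes (degrees)
    ai_posterior_deg: float = 8.0
    ai_anterior_deg: float = 12.0
    mtp_extension_deg: float = 30.0
    mla_neutral_deg: float = 140.0
    mla_compression_deg: float = 8.0
    eversion_deg: float = 6.0

    #: occlusion spans: (side, label, start_frame, end_frame) -> NaN samples
    occlusions: List[Tuple[str, L, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("tibia_len", "gastroc_len", "heel_lift", "forefoot_lift",
                     "toe_lift", "fps", "duration_s", "cadence"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if not 0 < self.stance_fraction < 1:
            raise ParameterError("stance_fraction must lie in (0, 1)")
        fractions = [self.event_fractions[k] for k in
                     ("IC", "LR", "MSt", "TSt", "PSw", "HE", "ISw")]
        if not all(a < b for a, b in zip(fractions, fractions[1:])):
            raise ParameterError("event fractions must be strictly increasing")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")

    @property
    def n_frames(self) -> int:
        return int(round(self.fps * self.duration_s))

    @property
    def frames_per_cycle(self) -> float:
        return self.fps / self.cadence


class GaitSchedule:
    """Scheduled per-phase profiles (phase in cycles, [0, 1))."""

    def __init__(self, p: GaitModelParams):
        self.params = p
        thr_heel = 2.0 * p.contact_offset_m / p.heel_lift
        thr_fore = 2.0 * p.contact_offset_m / p.forefoot_lift
        thr_toe = 2.0 * p.contact_offset_m / p.toe_lift
        ef = p.event_fractions
        # piecewise-linear height shapes: each contact threshold crossing is
        # the midpoint of a linear segment spanning ~4 frames at 30 f/cycle
        self._heel_knots = (
            np.array([0.067, 0.34, 0.50, 0.866, 0.933]),
            np.array([0.0, 0.0, 1.0, 1.0, thr_heel]),
        )
        lr = ef["LR"]
        self._fore_knots = (
            np.array([lr - 0.067, lr + 0.067, 0.58, 0.75, 0.92]),
            np.array([thr_fore, 0.0, 0.0, 1.0, 1.0]),
        )
        isw = ef["ISw"]
        self._toe_knots = (
            np.array([0.10, isw - 0.067, isw + 0.067, 0.75, 0.90, 0.967]),
            np.array([0.0, 0.0, thr_toe, 1.0, 1.0, thr_toe]),
        )
        post, ant = p.ai_posterior_deg, p.ai_anterior_deg
        tst = ef["TSt"]
        self._ai = _periodic_pchip(
            [0.0, ef["LR"], ef["MSt"], tst - 0.06, tst, tst + 0.06,
             0.42, 0.60, 0.80, 1.0],
            [-0.5 * post, -post, -0.75 * post, -0.26 * post, 0.0, 0.175 * ant,
             ant, 0.5 * ant, -0.125 * post, -0.5 * post],
        )
        he = ef["HE"]
        self._ext = _periodic_pchip(
            [0.0, he - 0.20, he, he + 0.08, 0.80, 1.0],
            [0.0, 0.0, p.mtp_extension_deg, 0.87 * p.mtp_extension_deg, 0.0, 0.0],
        )
        self._mla_bump = _periodic_pchip(
            [0.0, 0.08, 0.20, 0.31, 0.45, 0.60, 0.85, 1.0],
            [0.15, 0.6, 1.0, 0.8, 0.2, 0.0, 0.0, 0.15],
        )
        self._ev_bump = _periodic_pchip(
            [0.0, 0.10, 0.20, 0.35, 0.50, 0.60, 0.80, 1.0],
            [0.2, 0.9, 1.0, 0.6, 0.2, 0.05, 0.0, 0.2],
        )

    def phase(self, side: str, frames: np.ndarray) -> np.ndarray:
        p = self.params
        offset = 0.0 if side == "right" else p.contralateral_offset
        return np.mod(frames / p.fps * p.cadence + p.phase0 + offset, 1.0)

    def heel_height(self, phi):   # above standing baseline, metres
        x, f = self._heel_knots
        return self.params.heel_lift * np.interp(phi, x, f, period=1.0)

    def forefoot_height(self, phi):
        x, f = self._fore_knots
        return self.params.forefoot_lift * np.interp(phi, x, f, period=1.0)

    def toe_height(self, phi):
        x, f = self._toe_knots
        return self.params.toe_lift * np.interp(phi, x, f, period=1.0)

    def ai(self, phi):
        return self._ai(phi)

    def mtp_extension(self, phi):
        return self._ext(phi)

    def mla(self, phi):
        return self.params.mla_neutral_deg + \
            self.params.mla_compression_deg * self._mla_bump(phi)

    def subtalar(self, phi):
        return 180.0 - self.params.eversion_deg * self._ev_bump(phi)


def _periodic_pchip(x: Sequence[float], y: Sequence[float]):
    """Monotone cubic through knots, evaluated periodically on [0, 1)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if not np.isclose(y[0], y[-1]):
        raise ValueError("periodic profile must close (y[0] == y[-1])")
    xx = np.concatenate([x[:-1] - 1.0, x, x[1:] + 1.0])
    yy = np.concatenate([y[:-1], y, y[1:]])
    interp = PchipInterpolator(xx, yy)
    return lambda phi: interp(np.mod(phi, 1.0))


# baseline marker heights (standing, metres) and sagittal z offsets
_BASE_Y = {L.CALC: 0.025, L.HM: 0.020, L.DIP1: 0.015, L.MM: 0.075}
_BASE_Z = {L.CALC: -0.08, L.MM: -0.02, L.HM: 0.07, L.DIP1: 0.12}
_X_OFFSET = 0.10       # mediolateral distance of each foot from the midline
_SHAFT_LEN = 0.03      # HM -> MT1_MID
_ACH_DROP = 0.06       # PAJL -> ACH
_PAJL_BACK = 0.045     # MM -> PAJL (posterior)
_Z_SWAY = 0.02         # fore-aft oscillation amplitude


@dataclass
class SyntheticRecording:
    """Trajectories plus self-consistent ground truth."""

    trajectories: TrajectorySet
    noiseless: TrajectorySet
    truth_events: Dict[str, List[CycleEvents]]
    truth_labels: Dict[str, np.ndarray]
    truth_angles: Dict[str, AngleSeries]
    schedule: GaitSchedule
    params: GaitModelParams


def _pose_side(schedule: GaitSchedule, side: str, frames: np.ndarray
               ) -> Dict[L, np.ndarray]:
    """Pose the 11 markers of one side for all frames (noiseless)."""
    p = schedule.params
    phi = schedule.phase(side, frames)
    n = len(frames)
    sx = _X_OFFSET if side == "right" else -_X_OFFSET
    s_lat = 1.0 if side == "right" else -1.0
    z_sway = _Z_SWAY * np.sin(2.0 * np.pi * phi)

    def col(x, y, z):
        out = np.empty((n, 3))
        out[:, 0], out[:, 1], out[:, 2] = x, y, z
        return out

    heel_h = schedule.heel_height(phi)
    markers: Dict[L, np.ndarray] = {}
    markers[L.CALC] = col(sx, _BASE_Y[L.CALC] + heel_h, _BASE_Z[L.CALC] + z_sway)
    markers[L.HM] = col(sx, _BASE_Y[L.HM] + schedule.forefoot_height(phi),
                        _BASE_Z[L.HM] + z_sway)
    markers[L.DIP1] = col(sx, _BASE_Y[L.DIP1] + schedule.toe_height(phi),
                          _BASE_Z[L.DIP1] + z_sway)
    mm = col(sx, _BASE_Y[L.MM] + 0.8 * heel_h, _BASE_Z[L.MM] + z_sway)
    markers[L.MM] = mm

    # shank posed from the tibia-inclination schedule (positive = anterior)
    ai = np.radians(schedule.ai(phi))
    u_shank = col(0.0, np.cos(ai), np.sin(ai))
    markers[L.KNEE] = mm + p.tibia_len * u_shank

    # navicular from the MLA schedule: inscribed-angle construction in the
    # sagittal plane, apex dorsal to the MM-HM chord
    theta = np.radians(schedule.mla(phi))
    chord = markers[L.HM] - mm
    c = np.linalg.norm(chord, axis=1)
    d = (c / 2.0) / np.tan(theta / 2.0)
    perp = np.zeros_like(chord)
    perp[:, 1] = chord[:, 2]
    perp[:, 2] = -chord[:, 1]
    perp /= np.linalg.norm(perp, axis=1, keepdims=True)
    flip = perp[:, 1] < 0
    perp[flip] *= -1.0
    markers[L.NV] = (mm + markers[L.HM]) / 2.0 + d[:, None] * perp

    # first-metatarsal shaft marker from the MTP-extension schedule
    ext = np.radians(schedule.mtp_extension(phi))
    u = markers[L.HM] - markers[L.DIP1]
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    rot = np.zeros_like(u)
    rot[:, 1] = u[:, 1] * np.cos(ext) + u[:, 2] * np.sin(ext)
    rot[:, 2] = -u[:, 1] * np.sin(ext) + u[:, 2] * np.cos(ext)
    markers[L.MT1_MID] = markers[L.HM] + _SHAFT_LEN * rot

    # posterior chain: PAJL level with MM; ACH posed from the subtalar
    # schedule within the plane spanned by the shank axis and the lateral axis
    pajl = mm + np.array([0.0, 0.0, -_PAJL_BACK])
    markers[L.PAJL] = pajl
    markers[L.GMTJ] = pajl + p.gastroc_len * u_shank
    delta = np.radians(180.0 - schedule.subtalar(phi))
    lateral = np.zeros_like(u_shank)
    lateral[:, 0] = s_lat
    ach_dir = -np.cos(delta)[:, None] * u_shank + np.sin(delta)[:, None] * lateral
    markers[L.ACH] = pajl + _ACH_DROP * ach_dir

    markers[L.CALF] = mm + np.array([0.04 * s_lat, 0.28, -0.02])
    return markers


def _truth_events(p: GaitModelParams, side: str) -> List[CycleEvents]:
    """Event frames implied by the schedule, for cycles fully in-recording."""
    offset = 0.0 if side == "right" else p.contralateral_offset
    fpc = p.frames_per_cycle
    events: List[CycleEvents] = []
    names = ("IC", "LR", "MSt", "TSt", "PSw", "HE", "ISw")
    k_min = int(np.floor(-(p.phase0 + offset))) - 1
    k_max = int(np.ceil(p.n_frames / fpc + 1))
    for k in range(k_min, k_max):
        frames = [int(round((k - p.phase0 - offset + p.event_fractions[e]) * fpc))
                  for e in names]
        if frames[0] < 0 or frames[-1] >= p.n_frames:
            continue
        events.append(CycleEvents(*frames).validate())
    return events


def generate(params: Optional[GaitModelParams] = None, **overrides
             ) -> SyntheticRecording:
    """Generate a synthetic bilateral recording with ground truth.

    Deterministic given ``params.seed``; repeated calls are bit-identical.
    """
    if params is None:
        params = GaitModelParams(**overrides)
    elif overrides:
        params = replace(params, **overrides)
    schedule = GaitSchedule(params)
    frames = np.arange(params.n_frames, dtype=float)

    clean_data = {side: _pose_side(schedule, side, frames) for side in SIDES}
    noiseless = TrajectorySet(fps=params.fps, n_frames=params.n_frames,
                              data={s: dict(m) for s, m in clean_data.items()},
                              treadmill_speed=params.treadmill_speed)

    rng = np.random.default_rng(params.seed)
    noisy_data: Dict[str, Dict[L, np.ndarray]] = {}
    for side in SIDES:
        noisy_data[side] = {}
        for label in L:
            arr = clean_data[side][label].copy()
            if params.noise_sd > 0:
                arr += rng.normal(0.0, params.noise_sd, size=arr.shape)
            noisy_data[side][label] = arr
    for side, label, start, end in params.occlusions:
        noisy_data[side][label][start:end] = np.nan
    trajectories = TrajectorySet(fps=params.fps, n_frames=params.n_frames,
                                 data=noisy_data,
                                 treadmill_speed=params.treadmill_speed)

    truth_events = {side: _truth_events(params, side) for side in SIDES}
    truth_labels = {side: label_subphases(truth_events[side], params.n_frames)
                    for side in SIDES}
    truth_angles = {side: compute_angle_series(noiseless, side)
                    for side in SIDES}
    return SyntheticRecording(
        trajectories=trajectories, noiseless=noiseless,
        truth_events=truth_events, truth_labels=truth_labels,
        truth_angles=truth_angles, schedule=schedule, params=params,
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

BACKGROUND_RGB = (180, 25, 25)   # red sock / backdrop
MARKER_RGB = (255, 255, 255)


def default_medial_camera(side: str = "right") -> CameraModel:
    """Lateral/medial camera: 52 cm from the foot, 40 cm above the ground."""
    sx = _X_OFFSET if side == "right" else -_X_OFFSET
    position = (sx + (0.52 if side == "right" else -0.52), 0.40, 0.0)
    rotation, translation = look_at(position, (sx, 0.20, 0.01))
    return CameraModel(fx=450.0, fy=450.0, cx=320.0, cy=288.0,
                       rotation=rotation, translation=translation)


def default_posterior_camera() -> CameraModel:
    """Posterior camera: 40 cm behind the treadmill, 40 cm high."""
    position = (0.0, 0.40, -0.40 - 0.08)
    rotation, translation = look_at(position, (0.0, 0.20, 0.0))
    return CameraModel(fx=450.0, fy=450.0, cx=320.0, cy=288.0,
                       rotation=rotation, translation=translation)


def render_scene(world_points: Sequence, camera: CameraModel,
                 marker_diameter_m: float = 0.01, timestamp: float = 0.0
                 ) -> Tuple[Frame, List[Tuple[float, float, float]]]:
    """Render white anti-aliased disks on a red background, with depth.

    Returns the frame and the true projected (u, v, depth) of each point.
    Raises :class:`~footkin.markers.ProjectionError` for points behind the
    camera.
    """
    h, w = camera.height, camera.width
    rgb = np.empty((h, w, 3), dtype=float)
    rgb[:] = BACKGROUND_RGB
    depth = np.zeros((h, w), dtype=np.float32)
    truth: List[Tuple[float, float, float]] = []
    projected = [camera.project(p) for p in world_points]
    for (u, v, z) in sorted(projected, key=lambda t: -t[2]):  # far first
        truth.append((u, v, z))
        r = camera.fx * (marker_diameter_m / 2.0) / z
        u0, u1 = int(np.floor(u - r - 2)), int(np.ceil(u + r + 2))
        v0, v1 = int(np.floor(v - r - 2)), int(np.ceil(v + r + 2))
        u0, v0 = max(u0, 0), max(v0, 0)
        u1, v1 = min(u1, w - 1), min(v1, h - 1)
        if u1 < u0 or v1 < v0:
            continue
        uu, vv = np.meshgrid(np.arange(u0, u1 + 1), np.arange(v0, v1 + 1))
        dist = np.hypot(uu - u, vv - v)
        coverage = np.clip(r + 0.5 - dist, 0.0, 1.0)
        patch = rgb[v0:v1 + 1, u0:u1 + 1]
        patch[:] = patch * (1 - coverage[..., None]) + \
            np.array(MARKER_RGB) * coverage[..., None]
        depth[v0:v1 + 1, u0:u1 + 1][coverage > 0.5] = z
    truth.sort(key=lambda t: (t[1], t[0]))
    frame = Frame(rgb=np.round(rgb).astype(np.uint8), depth=depth,
                  timestamp=timestamp, camera=camera)
    return frame, truth


def render_frames(rec: SyntheticRecording, camera: CameraModel,
                  side: str = "right", labels: Optional[Sequence[L]] = None,
                  frames: Optional[Sequence[int]] = None,
                  marker_diameter_m: float = 0.01):
    """Render selected frames of a recording; yields (frame, truth) pairs."""
    labels = list(labels) if labels is not None else list(L)
    frame_idx = frames if frames is not None else range(rec.params.n_frames)
    for f in frame_idx:
        pts = [rec.noiseless.marker(side, lab)[f] for lab in labels]
        yield render_scene(pts, camera, marker_diameter_m,
                           timestamp=f / rec.params.fps)
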
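"""Clinical angle operators, series computation and phase anchoring."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from footkin.anatomy import AnatomicalLabel as L, TrajectorySet, marker_set_from_mapping
from footkin.angles import (
    ANCHOR_EVENTS,
    ANCHOR_NAMES,
    AngleSeries,
    ankle_angle,
    compute_angle_series,
    extract_phase_angles,
    mla_angle,
    mtp_angle,
    subtalar_angle,
    tibia_inclination,
)
from footkin.anatomy import MissingMarkerError
from footkin.segmentation import CycleEvents, detect_events
from footkin.geometry import DegenerateGeometryError


def law_of_cosines_angle(vertex, a, b):
    va = np.linalg.norm(np.subtract(a, vertex))
    vb = np.linalg.norm(np.subtract(b, vertex))
    ab = np.linalg.norm(np.subtract(a, b))
    return np.degrees(np.arccos(np.clip(
        (va**2 + vb**2 - ab**2) / (2 * va * vb), -1, 1)))


def test_mla_variants_canonical_and_oracle(rng):
    ms = marker_set_from_mapping("right", {
        L.NV: (0, 0, 0), L.MM: (0, 1, 0), L.HM: (1, 0, 0), L.CALC: (0, 0, -1)})
    assert mla_angle(ms, "equation") == pytest.approx(90.0, abs=1e-12)
    flat = marker_set_from_mapping("right", {
        L.NV: (0, 0, 0), L.HM: (0, 0, 1), L.CALC: (0, 0, -1)})
    assert mla_angle(flat, "text") == pytest.approx(180.0, abs=1e-9)
    for _ in range(50):
        pts = {lab: tuple(rng.uniform(-1, 1, 3))
               for lab in (L.NV, L.MM, L.HM, L.CALC)}
        ms = marker_set_from_mapping("left", pts)
        assert mla_angle(ms, "equation") == pytest.approx(
            law_of_cosines_angle(pts[L.NV], pts[L.MM], pts[L.HM]), abs=1e-9)
        assert mla_angle(ms, "text") == pytest.approx(
            law_of_cosines_angle(pts[L.NV], pts[L.HM], pts[L.CALC]), abs=1e-9)


def test_mla_missing_marker_named():
    ms = marker_set_from_mapping("right", {L.NV: (0, 0, 0), L.HM: (1, 0, 0)})
    with pytest.raises(MissingMarkerError, match="MM"):
        mla_angle(ms, "equation")


def test_subtalar_neutral_and_hand_oracle():
    neutral = marker_set_from_mapping("right", {
        L.ACH: (0, -1, 0), L.PAJL: (0, 0, 0), L.GMTJ: (0, 1, 0)})
    assert subtalar_angle(neutral) == pytest.approx(180.0, abs=1e-9)
    everted = marker_set_from_mapping("right", {
        L.ACH: (0.05, -1, 0), L.PAJL: (0, 0, 0), L.GMTJ: (0, 1, 0)})
    # hand check: 180 - atan(0.05) = 177.1376...
    assert subtalar_angle(everted) == pytest.approx(
        180.0 - np.degrees(np.arctan(0.05)), abs=1e-9)


def test_ankle_angle_planar_cases(rng):
    base = {L.CALC: (0, 0, 0), L.HM: (0, 0, 1),
            L.MM: (0, 0, 0.5), L.KNEE: (0, 1, 0.5)}
    assert ankle_angle(marker_set_from_mapping("right", base)) == \
        pytest.approx(90.0, abs=1e-9)
    tilted = dict(base)
    tilted[L.KNEE] = (0, np.cos(np.radians(10)), 0.5 + np.sin(np.radians(10)))
    assert ankle_angle(marker_set_from_mapping("right", tilted)) == \
        pytest.approx(80.0, abs=1e-9)
    # random planar configurations against a 2D atan2 oracle
    for _ in range(50):
        foot_dir = rng.uniform(-1, 1, 2)
        shank_dir = rng.uniform(-1, 1, 2)
        if min(np.linalg.norm(foot_dir), np.linalg.norm(shank_dir)) < 1e-3:
            continue
        ms = marker_set_from_mapping("right", {
            L.CALC: (0, 0, 0), L.HM: (0, foot_dir[0], foot_dir[1]),
            L.MM: (0, 2, 0), L.KNEE: (0, 2 + shank_dir[0], shank_dir[1])})
        expected = np.degrees(abs(
            np.arctan2(foot_dir[1], foot_dir[0]) -
            np.arctan2(shank_dir[1], shank_dir[0])))
        expected = min(expected, 360 - expected)
        assert ankle_angle(ms) == pytest.approx(expected, abs=1e-9)


def test_tibia_inclination_sign_convention():
    vertical = marker_set_from_mapping("right", {L.MM: (0, 0, 0), L.KNEE: (0, 1, 0)})
    assert tibia_inclination(vertical) == pytest.approx(0.0, abs=1e-12)
    anterior = marker_set_from_mapping("right", {L.MM: (0, 0, 0), L.KNEE: (0, 1, 0.1)})
    assert tibia_inclination(anterior) == pytest.approx(
        np.degrees(np.arctan(0.1)), abs=1e-9)
    with pytest.raises(DegenerateGeometryError):
        tibia_inclination(marker_set_from_mapping(
            "right", {L.MM: (0, 0, 0), L.KNEE: (0, 0, 0)}))


def test_mtp_angle_neutral_and_extension():
    neutral = marker_set_from_mapping("right", {
        L.MT1_MID: (0, 0, -1), L.HM: (0, 0, 0), L.DIP1: (0, 0, 1)})
    assert mtp_angle(neutral) == pytest.approx(180.0, abs=1e-9)
    ext = np.radians(30)
    extended = marker_set_from_mapping("right", {
        L.MT1_MID: (0, 0, -1), L.HM: (0, 0, 0),
        L.DIP1: (0, np.sin(ext), np.cos(ext))})
    assert mtp_angle(extended) == pytest.approx(150.0, abs=1e-9)


def test_series_rigid_invariance_except_ai(noiseless_rec):
    traj = noiseless_rec.noiseless
    base = compute_angle_series(traj, "right")
    rot = Rotation.from_euler("xyz", [17, -31, 8], degrees=True).as_matrix()
    shift = np.array([0.3, -0.1, 1.2])
    moved = TrajectorySet(fps=traj.fps, n_frames=traj.n_frames, data={
        s: {lab: arr @ rot.T + shift for lab, arr in m.items()}
        for s, m in traj.data.items()})
    rotated = compute_angle_series(moved, "right")
    for name in ("MLA", "CA", "ANK", "MTP"):
        np.testing.assert_allclose(rotated.series(name), base.series(name),
                                   atol=1e-9)
    assert np.nanmax(np.abs(rotated.ai - base.ai)) > 1.0  # AI is not invariant

    # vertical-axis-preserving transform (yaw + translation) preserves AI too
    yaw = Rotation.from_euler("y", 40, degrees=True).as_matrix()
    yawed = TrajectorySet(fps=traj.fps, n_frames=traj.n_frames, data={
        s: {lab: arr @ yaw.T + np.array([0.1, 0.2, 0.3])
            for lab, arr in m.items()}
        for s, m in traj.data.items()})
    ai2 = compute_angle_series(yawed, "right").ai
    # yaw mixes the anterior sign reference; magnitude is preserved
    np.testing.assert_allclose(np.abs(ai2), np.abs(base.ai), atol=1e-9)


def test_missing_marker_affects_only_its_angles(noiseless_rec):
    traj = noiseless_rec.noiseless
    data = {s: {lab: arr.copy() for lab, arr in m.items()}
            for s, m in traj.data.items()}
    data["right"][L.NV][10] = np.nan
    broken = compute_angle_series(
        TrajectorySet(fps=30, n_frames=150, data=data), "right")
    assert np.isnan(broken.mla[10])
    for name in ("CA", "ANK", "AI", "MTP"):
        assert np.isfinite(broken.series(name)[10])
    assert np.isfinite(broken.mla[11])


def test_anchoring_constant_series():
    const = AngleSeries(*(np.full(40, v) for v in (140.0, 178.0, 90.0, 3.0, 175.0)))
    anchored = extract_phase_angles(const, CycleEvents(0, 5, 10, 15, 20, 25, 30))
    assert set(anchored.as_dict()) == set(ANCHOR_NAMES)
    assert len(ANCHOR_NAMES) == 19
    assert anchored["MLA_IC"] == 140.0 and anchored["AI_TSt"] == 3.0
    assert "CA_TSt" not in anchored.as_dict()
    assert "TSt" not in ANCHOR_EVENTS["CA"]


def test_anchoring_out_of_range_event_raises():
    const = AngleSeries(*(np.full(20, 1.0) for _ in range(5)))
    with pytest.raises(IndexError):
        extract_phase_angles(const, CycleEvents(0, 5, 10, 15, 18, 19, 25))


def test_anchored_values_equal_series_at_event_frames(noiseless_rec):
    traj = noiseless_rec.trajectories
    series = compute_angle_series(traj, "right")
    for ev in detect_events(traj, "right"):
        anchored = extract_phase_angles(series, ev)
        frames = dict(zip(("IC", "LR", "MSt", "TSt", "PSw", "HE", "ISw"), ev))
        for name, value in anchored.as_dict().items():
            angle, event = name.rsplit("_", 1)
            assert value == series.series(angle)[frames[event]]


def test_pipeline_recovers_scheduled_anchors(noiseless_rec):
    """End-to-end: detected events + computed series == generator truth."""
    for side in ("left", "right"):
        series = compute_angle_series(noiseless_rec.trajectories, side)
        truth_series = noiseless_rec.truth_angles[side]
        detected = detect_events(noiseless_rec.trajectories, side)
        for ev, truth_ev in zip(detected, noiseless_rec.truth_events[side]):
            got = extract_phase_angles(series, ev).as_dict()
            want = extract_phase_angles(truth_series, truth_ev).as_dict()
            for name in ANCHOR_NAMES:
                assert got[name] == pytest.approx(want[name], abs=0.5), name
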
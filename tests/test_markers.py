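"""Marker detection, back-projection and anatomical labeling."""

import numpy as np
import pytest

from footkin.anatomy import MEDIAL_LABELS, POSTERIOR_LABELS, AnatomicalLabel as L
from footkin.markers import (
    AmbiguousLabelingError,
    CameraModel,
    DetectionConfig,
    Frame,
    MarkerDetection,
    MissingDepthError,
    ProjectionError,
    UnlabelableError,
    backproject,
    detect_markers,
    label_markers,
)
from footkin.synthetic import default_medial_camera, render_scene


def _disk_frame(centers, radius=5.0, size=(200, 200)):
    """Red background with anti-aliased white disks at (u, v) centers."""
    h, w = size
    rgb = np.empty((h, w, 3), float)
    rgb[:] = (180, 25, 25)
    uu, vv = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    for (u, v) in centers:
        cov = np.clip(radius + 0.5 - np.hypot(uu - u, vv - v), 0, 1)
        rgb = rgb * (1 - cov[..., None]) + np.array([255.0] * 3) * cov[..., None]
    return Frame(rgb=np.round(rgb).astype(np.uint8), depth=None, timestamp=0.0)


def test_single_disk_subpixel_centroid():
    frame = _disk_frame([(50.0, 60.0)])
    dets = detect_markers(frame)
    assert len(dets) == 1
    assert np.hypot(dets[0].u - 50.0, dets[0].v - 60.0) < 0.5


def test_small_disk_rejected_by_size_filter():
    frame = _disk_frame([(50.0, 60.0)], radius=0.5)
    assert detect_markers(frame) == []


def test_detection_count_monotone_in_min_diameter():
    frame = _disk_frame([(30, 30), (80, 80), (130, 40)], radius=4)
    counts = [len(detect_markers(frame, DetectionConfig(min_diameter_px=d)))
              for d in (2, 6, 9, 20)]
    assert counts[0] == 3
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_contrastless_image_yields_no_detections():
    blank = Frame(rgb=np.full((50, 50, 3), 180, np.uint8), depth=None, timestamp=0.0)
    assert detect_markers(blank) == []


def test_eleven_disks_detected_and_matched(rng):
    centers = []
    while len(centers) < 11:
        c = rng.uniform(15, 185, 2)
        if all(np.hypot(*(c - np.array(o))) > 14 for o in centers):
            centers.append(tuple(c))
    frame = _disk_frame(centers, radius=5)
    dets = detect_markers(frame)
    assert len(dets) == 11
    for det in dets:
        err = min(np.hypot(det.u - u, det.v - v) for u, v in centers)
        assert err < 0.5


def test_backproject_canonical_cases():
    cam = CameraModel(fx=500, fy=500, cx=320, cy=240)
    d = MarkerDetection(u=320, v=240, area=1, equivalent_diameter=1,
                        circularity=1, depth_m=1.0)
    assert np.allclose(backproject(d, cam), (0, 0, 1.0))
    d2 = MarkerDetection(u=320 + 500, v=240, area=1, equivalent_diameter=1,
                         circularity=1, depth_m=2.0)
    assert np.allclose(backproject(d2, cam), (2.0, 0, 2.0))
    with pytest.raises(MissingDepthError):
        backproject(MarkerDetection(u=0, v=0, area=1, equivalent_diameter=1,
                                    circularity=1), cam)


def test_project_backproject_identity(rng):
    cam = default_medial_camera("right")
    for _ in range(20):
        world = rng.uniform([-0.1, 0.0, -0.2], [0.25, 0.5, 0.2])
        u, v, z = cam.project(world)
        det = MarkerDetection(u=u, v=v, area=1, equivalent_diameter=1,
                              circularity=1, depth_m=z)
        assert np.linalg.norm(np.asarray(backproject(det, cam)) - world) < 1e-9


def test_project_behind_camera_raises():
    cam = CameraModel(fx=500, fy=500, cx=320, cy=240)
    with pytest.raises(ProjectionError):
        cam.project((0, 0, -1.0))


def test_render_detect_backproject_roundtrip(noiseless_rec):
    cam = default_medial_camera("right")
    pts = [noiseless_rec.noiseless.marker("right", lab)[40] for lab in L]
    frame, truth = render_scene(pts, cam)
    dets = detect_markers(frame)
    assert len(dets) == 11
    for det, (u, v, z) in zip(dets, truth):
        assert np.hypot(det.u - u, det.v - v) <= 0.5
        world = np.asarray(backproject(det, cam))
        err = min(np.linalg.norm(world - np.asarray(p)) for p in pts)
        assert err <= 0.002


def _dets_with_world(points):
    return [MarkerDetection(u=0, v=0, area=1, equivalent_diameter=1,
                            circularity=1, world=tuple(p)) for p in points]


def test_medial_labeling_from_rendered_frame(noiseless_rec):
    cam = default_medial_camera("right")
    pts = [noiseless_rec.noiseless.marker("right", lab)[40]
           for lab in MEDIAL_LABELS]
    frame, _ = render_scene(pts, cam)
    dets = detect_markers(frame)
    dets = [MarkerDetection(**{**d.__dict__, "world": backproject(d, cam)})
            for d in dets]
    ms = label_markers(dets, "medial", "right")
    for lab, p in zip(MEDIAL_LABELS, pts):
        assert np.linalg.norm(np.asarray(ms.get(lab)) - np.asarray(p)) < 2e-3


def test_wrong_count_unlabelable():
    with pytest.raises(UnlabelableError):
        label_markers(_dets_with_world(np.zeros((6, 3))), "medial", "right")


def test_posterior_triple_ordered_bottom_to_top():
    pts = [(0, 0.02, -0.06), (0, 0.08, -0.06), (0, 0.25, -0.05)]
    ms = label_markers(_dets_with_world(pts), "posterior", "left")
    assert tuple(ms.get(lab) for lab in POSTERIOR_LABELS) == \
        tuple(tuple(map(float, p)) for p in pts)


def test_ambiguous_heights_raise():
    pts = [(0, 0.02, -0.06), (0, 0.0205, -0.06), (0, 0.25, -0.05)]
    with pytest.raises(AmbiguousLabelingError):
        label_markers(_dets_with_world(pts), "posterior", "left")
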
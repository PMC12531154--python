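"""Detection of circular high-contrast markers in RGB(-D) frames.

Markers are 1 cm white buttons on a hue-distinct (red) background; anything
smaller than a 2 mm-equivalent blob is rejected as unreliable. Detection
operates on a grayscale-contrast channel: Otsu (or fixed) thresholding,
connected-component labeling, and size + circularity filtering, with
intensity-weighted subpixel centroids. Detections carrying depth are lifted
to 3D through a pinhole camera model.

Image convention: origin top-left, ``u`` rightward (column), ``v`` downward
(row), 0-based, subpixel centroids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from skimage import measure
from skimage.filters import threshold_otsu

from .anatomy import (
    LATERAL_LABELS,
    MEDIAL_LABELS,
    POSTERIOR_LABELS,
    AnatomicalLabel,
    LabeledMarkerSet,
)
from .geometry import Point3D

logger = logging.getLogger(__name__)


class MissingDepthError(ValueError):
    """Back-projection was requested without a usable depth sample."""


class ProjectionError(ValueError):
    """A world point cannot be projected (at or behind the camera plane)."""


class UnlabelableError(ValueError):
    """The detection count does not match the view's expected marker count."""


class AmbiguousLabelingError(ValueError):
    """Two detections are geometrically indistinguishable for labeling."""


@dataclass
class CameraModel:
    """Pinhole camera with a rigid camera-to-world pose.

    Camera axes: x right, y down, z forward (optical axis). A camera-frame
    point ``p`` maps to world coordinates as ``R @ p + t``.
    """

    fx: float
    fy: float
    cx: float
    cy: float
    width: int = 640
    height: int = 576
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("camera rotation must be orthonormal")

    def world_to_camera(self, world) -> np.ndarray:
        return self.rotation.T @ (np.asarray(world, float) - self.translation)

    def camera_to_world(self, cam) -> np.ndarray:
        return self.rotation @ np.asarray(cam, float) + self.translation

    def project(self, world) -> Tuple[float, float, float]:
        """World point -> (u, v, depth). Raises ProjectionError if behind."""
        x, y, z = self.world_to_camera(world)
        if z <= 1e-9:
            raise ProjectionError(f"point at camera depth {z:.4f} m")
        return (self.fx * x / z + self.cx, self.fy * y / z + self.cy, z)


def look_at(position, target, up=(0.0, 1.0, 0.0)) -> Tuple[np.ndarray, np.ndarray]:
    """Camera pose (rotation, translation) looking from ``position`` at ``target``.

    The optical (z) axis points at the target; the image v axis points
    opposite to world ``up`` (rows grow downward).
    """
    position = np.asarray(position, float)
    forward = np.asarray(target, float) - position
    forward /= np.linalg.norm(forward)
    right = np.cross(forward, np.asarray(up, float))
    right /= np.linalg.norm(right)
    down = np.cross(forward, right)
    rotation = np.column_stack([right, down, forward])
    return rotation, position


@dataclass
class Frame:
    """One synthetic RGB(-D) frame."""

    rgb: np.ndarray                  # (H, W, 3) uint8
    depth: Optional[np.ndarray]      # (H, W) float32 metres, 0 = no depth
    timestamp: float
    camera: Optional[CameraModel] = None

    def __post_init__(self) -> None:
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError("rgb must be (H, W, 3)")
        if self.depth is not None:
            if self.depth.shape != self.rgb.shape[:2]:
                raise ValueError("depth must match rgb spatial shape")
            if np.any(self.depth < 0):
                raise ValueError("depth values must be >= 0")


@dataclass
class DetectionConfig:
    """Blob-detection thresholds."""

    threshold: Optional[float] = None   # None -> Otsu on the contrast channel
    min_diameter_px: float = 2.0        # ~2 mm-equivalent at working distance
    max_diameter_px: float = 60.0
    min_circularity: float = 0.7
    min_contrast: float = 10.0          # grey levels; below -> warn, no output

    @staticmethod
    def min_diameter_for(camera: CameraModel, distance_m: float,
                         physical_m: float = 0.002) -> float:
        """Pixel size of a physical diameter at a working distance."""
        return camera.fx * physical_m / distance_m


@dataclass
class MarkerDetection:
    """A detected circular blob, optionally lifted to 3D."""

    u: float
    v: float
    area: float
    equivalent_diameter: float
    circularity: float
    depth_m: Optional[float] = None
    world: Optional[Point3D] = None

    @property
    def centroid(self) -> Tuple[float, float]:
        return (self.u, self.v)


def _contrast_channel(rgb: np.ndarray) -> np.ndarray:
    """Luminance channel; white markers are bright on the darker background."""
    return rgb.astype(float) @ np.array([0.2126, 0.7152, 0.0722])


def detect_markers(frame: Frame, config: Optional[DetectionConfig] = None
                   ) -> List[MarkerDetection]:
    """Detect bright circular blobs passing size and circularity filters.

    Returns detections sorted by (v, u). An empty or contrastless image
    yields an empty list (with a logged warning for the contrastless case).
    """
    config = config or DetectionConfig()
    channel = _contrast_channel(frame.rgb)
    if channel.max() - channel.min() < config.min_contrast:
        logger.warning("frame has no usable contrast (range %.1f); no detections",
                       channel.max() - channel.min())
        return []
    thr = config.threshold if config.threshold is not None else threshold_otsu(channel)
    binary = channel > thr
    labeled = measure.label(binary)
    detections: List[MarkerDetection] = []
    for region in measure.regionprops(labeled, intensity_image=channel):
        diameter = region.equivalent_diameter_area
        if not (config.min_diameter_px <= diameter <= config.max_diameter_px):
            continue
        perimeter = region.perimeter
        circularity = (4.0 * np.pi * region.area / perimeter ** 2
                       if perimeter > 0 else 0.0)
        circularity = min(circularity, 1.0)
        if circularity < config.min_circularity:
            continue
        v, u = region.centroid_weighted
        depth = None
        if frame.depth is not None:
            rr, cc = region.coords[:, 0], region.coords[:, 1]
            samples = frame.depth[rr, cc]
            samples = samples[samples > 0]
            if samples.size:
                depth = float(np.median(samples))
        detections.append(MarkerDetection(
            u=float(u), v=float(v), area=float(region.area),
            equivalent_diameter=float(diameter), circularity=float(circularity),
            depth_m=depth,
        ))
    detections.sort(key=lambda d: (d.v, d.u))
    return detections


def backproject(detection: MarkerDetection, camera: CameraModel) -> Point3D:
    """Lift a detection with depth to a world-frame 3D point.

    Camera-frame point: ((u - cx) d / fx, (v - cy) d / fy, d), mapped
    through the camera pose to world coordinates.
    """
    if detection.depth_m is None or detection.depth_m <= 0:
        raise MissingDepthError(
            f"detection at ({detection.u:.1f}, {detection.v:.1f}) has no depth"
        )
    d = detection.depth_m
    cam = np.array([
        (detection.u - camera.cx) * d / camera.fx,
        (detection.v - camera.cy) * d / camera.fy,
        d,
    ])
    return Point3D(*camera.camera_to_world(cam))


_EXPECTED_COUNT = {"medial": 7, "posterior": 3, "lateral": 1}


def label_markers(detections: Sequence[MarkerDetection], view: str, side: str,
                  camera: Optional[CameraModel] = None,
                  ambiguity_tol_m: float = 2e-3) -> LabeledMarkerSet:
    """Assign anatomical labels to detections by geometric ordering.

    Detections must carry world coordinates (set them via
    :func:`backproject`, or pass ``camera`` to back-project here). Medial
    view: the knee is the most superior marker, the malleolus the next;
    the calcaneus is the most posterior of the foot markers and the
    remaining four order anterior-to-posterior as DIP1, HM, MT1_MID, NV.
    Posterior view orders ACH, PAJL, GMTJ bottom-to-top.
    """
    if view not in _EXPECTED_COUNT:
        raise ValueError(f"unknown view {view!r}")
    expected = _EXPECTED_COUNT[view]
    if len(detections) != expected:
        raise UnlabelableError(
            f"{view} view expects {expected} markers, found {len(detections)}"
        )
    worlds = []
    for det in detections:
        if det.world is None:
            if camera is None:
                raise ValueError("detections lack world coordinates and no "
                                 "camera was given")
            det = MarkerDetection(**{**det.__dict__, "world": backproject(det, camera)})
        worlds.append(np.asarray(det.world, float))
    worlds = np.array(worlds)

    def order_by(points: np.ndarray, key: np.ndarray) -> np.ndarray:
        srt = np.argsort(key, kind="stable")
        gaps = np.diff(key[srt])
        if np.any(np.abs(gaps) < ambiguity_tol_m):
            raise AmbiguousLabelingError(
                f"two candidates within {ambiguity_tol_m * 1e3:.1f} mm along the "
                "ordering axis"
            )
        return srt

    positions = {}
    if view == "posterior":
        order = order_by(worlds, worlds[:, 1])  # bottom-to-top: ACH, PAJL, GMTJ
        for label, idx in zip(POSTERIOR_LABELS, order):
            positions[label] = Point3D(*worlds[idx])
    elif view == "lateral":
        positions[LATERAL_LABELS[0]] = Point3D(*worlds[0])
    else:  # medial
        by_height = np.argsort(worlds[:, 1])
        knee, mm = by_height[-1], by_height[-2]
        if worlds[knee, 1] - worlds[mm, 1] < ambiguity_tol_m:
            raise AmbiguousLabelingError("knee/malleolus height ambiguity")
        foot = [i for i in range(7) if i not in (knee, mm)]
        foot_pts = worlds[foot]
        order = order_by(foot_pts, -foot_pts[:, 2])  # anterior first
        # anterior-to-posterior: DIP1, HM, MT1_MID, NV, CALC (most posterior)
        seq = (AnatomicalLabel.DIP1, AnatomicalLabel.HM, AnatomicalLabel.MT1_MID,
               AnatomicalLabel.NV, AnatomicalLabel.CALC)
        positions[AnatomicalLabel.KNEE] = Point3D(*worlds[knee])
        positions[AnatomicalLabel.MM] = Point3D(*worlds[mm])
        for label, idx in zip(seq, order):
            positions[label] = Point3D(*foot_pts[idx])
    return LabeledMarkerSet(side=side, positions=positions)
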
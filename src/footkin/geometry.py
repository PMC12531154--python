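"""3D point/vector primitives and the two angle operators used throughout.

Axis convention (package-wide): X mediolateral, Y vertical (up positive),
Z direction of walking progression (anterior positive). All lengths are in
metres, all angles in degrees (the clinical convention).

Left and right feet are handled by mirroring X; every angle definition is
side-agnostic after mirroring.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

#: Vectors shorter than this (metres) are considered degenerate.
DEGENERATE_TOL = 1e-9

#: The vertical (up) axis.
VERTICAL = np.array([0.0, 1.0, 0.0])


class DegenerateGeometryError(ValueError):
    """Raised when an angle is requested for a zero-length vector."""


class Point3D(NamedTuple):
    """A 3D point in metres (X mediolateral, Y up, Z anterior)."""

    x: float
    y: float
    z: float

    def to_array(self) -> np.ndarray:
        return np.array(self, dtype=float)


def _as_xyz(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape[-1] != 3:
        raise ValueError(f"expected 3D coordinates, got shape {a.shape}")
    return a


def angle_at_vertex(vertex, a, b) -> float:
    """Angle in degrees at ``vertex`` between the rays to ``a`` and ``b``.

    Computes theta = arccos(v1.v2 / (|v1||v2|)) with v1 = a - vertex,
    v2 = b - vertex. The result lies in [0, 180], is symmetric in (a, b),
    and is invariant under rigid transforms of all three points and under
    uniform scaling about the vertex.

    Raises
    ------
    DegenerateGeometryError
        If ``a`` or ``b`` coincides with the vertex within ``DEGENERATE_TOL``.
    """
    v1 = _as_xyz(a) - _as_xyz(vertex)
    v2 = _as_xyz(b) - _as_xyz(vertex)
    n1 = float(np.linalg.norm(v1))
    n2 = float(np.linalg.norm(v2))
    if n1 < DEGENERATE_TOL or n2 < DEGENERATE_TOL:
        raise DegenerateGeometryError(
            f"degenerate angle: ray length(s) {n1:.3e}, {n2:.3e} m below "
            f"tolerance {DEGENERATE_TOL} m"
        )
    c = float(np.dot(v1, v2)) / (n1 * n2)
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def angle_between(u, v) -> float:
    """Angle in degrees between two free vectors (range [0, 180])."""
    return angle_at_vertex(np.zeros(3), u, v)


def signed_inclination(distal, proximal) -> float:
    """Signed tilt (degrees) of the segment distal->proximal from vertical.

    The unsigned magnitude is the angle between ``proximal - distal`` and the
    vertical axis (0, 1, 0). The sign is positive when the proximal point lies
    anterior (greater Z) to the distal point ("anterior tilting") and negative
    when posterior.

    Raises
    ------
    DegenerateGeometryError
        On a zero-length segment.
    """
    v = _as_xyz(proximal) - _as_xyz(distal)
    n = float(np.linalg.norm(v))
    if n < DEGENERATE_TOL:
        raise DegenerateGeometryError("coincident distal/proximal points")
    mag = float(np.degrees(np.arccos(np.clip(v[1] / n, -1.0, 1.0))))
    sign = -1.0 if v[2] < 0 else 1.0
    return sign * mag


# ---------------------------------------------------------------------------
# Vectorised variants operating on (n, 3) trajectories. Frames where any
# coordinate is NaN, or where a ray is degenerate, yield NaN instead of
# raising (a missing marker must never abort a whole recording).
# ---------------------------------------------------------------------------


def angle_at_vertex_series(vertex, a, b) -> np.ndarray:
    """Per-frame :func:`angle_at_vertex` over (n, 3) arrays; NaN-propagating."""
    v1 = np.atleast_2d(_as_xyz(a)) - np.atleast_2d(_as_xyz(vertex))
    v2 = np.atleast_2d(_as_xyz(b)) - np.atleast_2d(_as_xyz(vertex))
    n1 = np.linalg.norm(v1, axis=-1)
    n2 = np.linalg.norm(v2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.einsum("ij,ij->i", v1, v2) / (n1 * n2)
        out = np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))
    out[(n1 < DEGENERATE_TOL) | (n2 < DEGENERATE_TOL)] = np.nan
    return out


def signed_inclination_series(distal, proximal) -> np.ndarray:
    """Per-frame :func:`signed_inclination` over (n, 3) arrays; NaN-propagating."""
    v = np.atleast_2d(_as_xyz(proximal)) - np.atleast_2d(_as_xyz(distal))
    n = np.linalg.norm(v, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mag = np.degrees(np.arccos(np.clip(v[:, 1] / n, -1.0, 1.0)))
    sign = np.where(v[:, 2] < 0, -1.0, 1.0)
    out = sign * mag
    out[n < DEGENERATE_TOL] = np.nan
    return out


def mirror_x(points) -> np.ndarray:
    """Mirror coordinates across the sagittal plane (X -> -X)."""
    a = _as_xyz(points).copy()
    a[..., 0] *= -1.0
    return a
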
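"""Mid-sagittal coordinate frame from orthogonal laser traces.

The structured-light rig projects a horizontal and a vertical laser onto the
face; both curves are captured with the T0 scan in the same coordinates.
From them the measurement frame is built:

* Origin — intersection of the two traces (closest-approach midpoint of
  their total-least-squares lines; the physical lasers never cross exactly).
* Plane 1 (horizontal plane) — through the origin and the two
  farthest-apart points of the complete horizontal trace.
* Line 1 (vertical axis) — through the origin, perpendicular to Plane 1.
* Line 2 — origin to the vertical-trace point farthest from the origin
  (the vertical laser follows the mid-facial profile, so Line 2 is tilted
  out of Plane 1).
* Plane 2 (mid-sagittal plane) — spanned by Line 1 and Line 2.
* Line 3 (projection direction) — normal of Plane 2, oriented toward the
  subject's right.

The frame is built once, on T0; later scans are rigidly registered into it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .mesh_io import LaserTrace

__all__ = ["Plane", "Line", "SagittalFrame", "fit_line_tls",
           "laser_origin", "build_frame", "FrameError"]


class FrameError(ValueError):
    """Degenerate or inconsistent laser geometry."""


def _unit(v, err="zero-length vector"):
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-300:
        raise FrameError(err)
    return v / n


@dataclass(frozen=True)
class Plane:
    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        object.__setattr__(self, "normal", _unit(self.normal, "plane normal is zero"))

    def signed_distance(self, points):
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d = (pts - self.point) @ self.normal
        return d if d.size > 1 else float(d[0])


@dataclass(frozen=True)
class Line:
    point: np.ndarray
    direction: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        object.__setattr__(self, "direction",
                           _unit(self.direction, "line direction is zero"))


def fit_line_tls(points: np.ndarray) -> Line:
    """Total-least-squares 3D line through a point set (centroid + first
    principal direction). Sign of the direction follows the point ordering
    (first -> last)."""
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 2:
        raise FrameError("need >= 2 points to fit a line")
    c = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - c, full_matrices=False)
    d = vt[0]
    if np.dot(d, pts[-1] - pts[0]) < 0:
        d = -d
    return Line(c, d)


def _line_crossing(lh: Line, lv: Line):
    d1, d2 = lh.direction, lv.direction
    cross = np.cross(d1, d2)
    n2 = np.dot(cross, cross)
    if n2 < np.sin(np.radians(0.1)) ** 2:
        raise FrameError("laser traces are parallel; no intersection")
    w = lv.point - lh.point
    t1 = np.dot(np.cross(w, d2), cross) / n2
    t2 = np.dot(np.cross(w, d1), cross) / n2
    p1 = lh.point + t1 * d1
    p2 = lv.point + t2 * d2
    return 0.5 * (p1 + p2), float(np.linalg.norm(p1 - p2))


def laser_origin(horizontal: LaserTrace, vertical: LaserTrace,
                 max_gap: float = 2.0, window: float = 15.0) -> np.ndarray:
    """Intersection of the two laser traces.

    Each trace is reduced to a total-least-squares 3D line and the origin
    is the midpoint of the common-perpendicular segment. Because recorded
    laser curves follow the facial surface (they are straight only in
    projection), the line fits are refined locally: after a global fit, each
    trace is re-fit using only points within ``window`` mm of the current
    crossing estimate, twice. For straight traces this is identical to the
    single global fit. A final closest approach >= ``max_gap`` mm means the
    traces do not cross and raises :class:`FrameError`.
    """
    hp, vp = horizontal.points, vertical.points
    lh, lv = fit_line_tls(hp), fit_line_tls(vp)
    origin, gap = _line_crossing(lh, lv)
    # seed the local refinement at the closest pair of raw trace points,
    # which is robust to trace curvature
    d2 = np.sum((hp[:, None, :] - vp[None, :, :]) ** 2, axis=2)
    i, j = np.unravel_index(np.argmin(d2), d2.shape)
    seed = 0.5 * (hp[i] + vp[j])
    for _ in range(3):
        hsel = hp[np.linalg.norm(hp - seed, axis=1) < window]
        vsel = vp[np.linalg.norm(vp - seed, axis=1) < window]
        if len(hsel) < 2 or len(vsel) < 2:
            break
        lh, lv = fit_line_tls(hsel), fit_line_tls(vsel)
        origin, gap = _line_crossing(lh, lv)
        seed = origin
    if gap >= max_gap:
        raise FrameError(
            f"laser traces do not cross (closest approach {gap:.2f} mm "
            f">= {max_gap} mm)")
    return origin


@dataclass(frozen=True)
class SagittalFrame:
    """Measurement frame: origin, the two construction planes, the vertical
    axis (Line 1) and the projection direction (Line 3 = mid-sagittal
    normal, pointing to the subject's right)."""

    origin: np.ndarray
    horizontal_plane: Plane
    midsagittal_plane: Plane
    projection_direction: np.ndarray
    vertical_axis: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "projection_direction",
                           _unit(self.projection_direction))
        object.__setattr__(self, "vertical_axis", _unit(self.vertical_axis))

    @property
    def in_plane_axis(self) -> np.ndarray:
        """Unit axis in the mid-sagittal plane completing a right-handed
        (in_plane, vertical, projection) triad."""
        return np.cross(self.vertical_axis, self.projection_direction)

    def height(self, points):
        """Signed coordinate along the projection direction (subject-right
        positive), measured from the mid-sagittal plane."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        h = (pts - self.origin) @ self.projection_direction
        return h if h.size > 1 else float(h[0])

    def plane_coords(self, points) -> np.ndarray:
        """2D coordinates of the orthogonal projection of ``points`` onto
        the mid-sagittal plane (axes: in-plane, vertical)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        rel = pts - self.origin
        return np.column_stack([rel @ self.in_plane_axis, rel @ self.vertical_axis])

    def vertical_coord(self, points):
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        v = (pts - self.origin) @ self.vertical_axis
        return v if v.size > 1 else float(v[0])

    # serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "origin": self.origin.tolist(),
            "horizontal_plane": {"point": self.horizontal_plane.point.tolist(),
                                 "normal": self.horizontal_plane.normal.tolist()},
            "midsagittal_plane": {"point": self.midsagittal_plane.point.tolist(),
                                  "normal": self.midsagittal_plane.normal.tolist()},
            "projection_direction": self.projection_direction.tolist(),
            "vertical_axis": self.vertical_axis.tolist(),
        }

    def save(self, path):
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_dict(cls, d) -> "SagittalFrame":
        return cls(
            origin=np.array(d["origin"]),
            horizontal_plane=Plane(np.array(d["horizontal_plane"]["point"]),
                                   np.array(d["horizontal_plane"]["normal"])),
            midsagittal_plane=Plane(np.array(d["midsagittal_plane"]["point"]),
                                    np.array(d["midsagittal_plane"]["normal"])),
            projection_direction=np.array(d["projection_direction"]),
            vertical_axis=np.array(d["vertical_axis"]),
        )

    @classmethod
    def load(cls, path) -> "SagittalFrame":
        return cls.from_dict(json.loads(Path(path).read_text()))


def build_frame(horizontal: LaserTrace, vertical: LaserTrace) -> SagittalFrame:
    """Construct the mid-sagittal frame from the two laser traces.

    ``horizontal`` must be the complete (direct) trace, ordered subject-left
    to subject-right; ``vertical`` is ordered inferior to superior. Those
    orderings orient Line 3 (toward the right) and Line 1 (upward).
    """
    if horizontal.kind == "horizontal-reflected":
        raise FrameError("frame must be built from the complete horizontal "
                         "laser, not a reflected trace")
    origin = laser_origin(horizontal, vertical)

    # farthest-apart pair of horizontal-trace points ("as far as possible")
    hp = horizontal.points
    d2 = np.sum((hp[:, None, :] - hp[None, :, :]) ** 2, axis=2)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    n1 = np.cross(hp[i] - origin, hp[j] - origin)
    if np.linalg.norm(n1) < 1e-9:
        raise FrameError("horizontal trace collinear with origin; "
                         "cannot build horizontal plane")
    # Line 1: vertical axis = Plane 1 normal, oriented upward along the
    # vertical trace ordering (inferior -> superior)
    v_axis = n1 / np.linalg.norm(n1)
    if np.dot(v_axis, vertical.points[-1] - vertical.points[0]) < 0:
        v_axis = -v_axis
    plane1 = Plane(origin, v_axis)

    # Line 2: origin -> farthest vertical-trace point
    vp = vertical.points
    far = vp[np.argmax(np.linalg.norm(vp - origin, axis=1))]
    l2 = far - origin
    l2n = np.linalg.norm(l2)
    if l2n < 1e-12:
        raise FrameError("vertical trace degenerate at origin")
    l2 = l2 / l2n
    sin_angle = np.linalg.norm(np.cross(v_axis, l2))
    if sin_angle < np.sin(np.radians(0.1)):
        raise FrameError("Line 2 parallel to Line 1 within 0.1 degrees; "
                         "mid-sagittal plane undefined")
    if abs(np.dot(v_axis, l2)) < np.sin(np.radians(0.1)):
        raise FrameError("vertical trace coplanar with the horizontal plane; "
                         "degenerate frame")

    n2 = _unit(np.cross(v_axis, l2))
    # orient toward the subject's right (left-to-right trace ordering)
    if np.dot(n2, hp[-1] - hp[0]) < 0:
        n2 = -n2
    plane2 = Plane(origin, n2)

    return SagittalFrame(origin=origin, horizontal_plane=plane1,
                         midsagittal_plane=plane2,
                         projection_direction=n2, vertical_axis=v_axis)
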
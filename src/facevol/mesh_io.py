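"""Surface-scan, landmark, and laser-trace I/O.

All coordinates are millimetres. Meshes travel as ASCII Wavefront OBJ; only
``v``/``f`` (and, for laser files, ``l`` and ``o``/``g``) records carry
geometry — texture, normal and material records are ignored on read.
Landmarks travel as plain CSV ``code,x,y,z``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._surface import SurfaceIndex

__all__ = [
    "SurfaceScan", "LandmarkSet", "LaserTrace",
    "read_obj", "write_obj", "read_landmarks", "write_landmarks",
    "read_lasers", "write_lasers",
    "LANDMARK_CODES", "LASER_KINDS", "MeshIOError",
]

#: soft-tissue (capulometric) landmark codes; the trailing prime marks a
#: skin-surface point as opposed to the underlying skull landmark
LANDMARK_CODES = ("pt'", "al'", "ex'", "ch'", "cf'")

LASER_KINDS = ("horizontal-complete", "horizontal-reflected", "vertical")


class MeshIOError(ValueError):
    """Malformed input file."""


@dataclass
class SurfaceScan:
    """A facial surface capture at one time point.

    vertices : (n, 3) float array, mm
    faces : (m, 3) int array of vertex indices
    label : time-point tag, e.g. "T0"
    """

    vertices: np.ndarray
    faces: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.faces = np.ascontiguousarray(self.faces, dtype=int)
        if self.vertices.size == 0 or self.faces.size == 0:
            raise MeshIOError("empty mesh")
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshIOError("vertices must be (n, 3)")
        if not np.all(np.isfinite(self.vertices)):
            raise MeshIOError("non-finite vertex coordinates")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise MeshIOError("face references out-of-range vertex index")
        self.faces = self._drop_degenerate(self.vertices, self.faces)
        if len(self.faces) == 0:
            raise MeshIOError("mesh has no non-degenerate faces")

    @staticmethod
    def _drop_degenerate(vertices, faces, eps=1e-12):
        tri = vertices[faces]
        a2 = np.linalg.norm(np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
        distinct = (faces[:, 0] != faces[:, 1]) & (faces[:, 1] != faces[:, 2]) \
            & (faces[:, 0] != faces[:, 2])
        return faces[(a2 > eps) & distinct]

    # -- geometry helpers -------------------------------------------------
    def as_trimesh(self):
        import trimesh
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    @property
    def area(self) -> float:
        tri = self.vertices[self.faces]
        return float(0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1).sum())

    def surface_index(self) -> SurfaceIndex:
        return SurfaceIndex(self.vertices, self.faces)

    def copy(self, label=None) -> "SurfaceScan":
        return SurfaceScan(self.vertices.copy(), self.faces.copy(),
                           self.label if label is None else label)


@dataclass
class LaserTrace:
    """Ordered 3D polyline of one projected laser.

    The complete (direct) horizontal trace is the one used for frame
    construction; the mirror-reflected traces are broken mid-face and are
    carried only for bookkeeping. Horizontal traces are ordered from the
    subject's left to the subject's right; vertical traces from inferior to
    superior. These orderings fix the frame's sign conventions.
    """

    kind: str
    points: np.ndarray

    def __post_init__(self):
        if self.kind not in LASER_KINDS:
            raise MeshIOError(f"unknown laser kind {self.kind!r}")
        self.points = np.ascontiguousarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 2:
            raise MeshIOError("laser trace needs >= 2 points of shape (n, 3)")
        if not np.all(np.isfinite(self.points)):
            raise MeshIOError("non-finite laser point")


@dataclass
class LandmarkSet:
    """Named anthropometric landmarks plus the ordered mandible lower border.

    ``points[side][code]`` holds one 3D point per code per side; the
    mandible border is an ordered (k, 3) polyline per side (codes ``mb1``,
    ``mb2``, ... in the CSV).
    """

    points: dict = field(default_factory=dict)
    mandible: dict = field(default_factory=dict)
    warnings_: list = field(default_factory=list)

    def get(self, code: str, side: str = "R") -> np.ndarray:
        try:
            return self.points[side][code]
        except KeyError:
            raise KeyError(f"landmark {code!r} (side {side}) not present") from None

    def has(self, code: str, side: str = "R") -> bool:
        return side in self.points and code in self.points[side]

    def border(self, side: str = "R") -> np.ndarray:
        if side not in self.mandible or len(self.mandible[side]) == 0:
            raise KeyError(f"no mandible border points for side {side}")
        return self.mandible[side]

    def sides(self):
        return sorted(set(self.points) | set(self.mandible))


# ---------------------------------------------------------------------------
# OBJ

def _parse_floats(parts, path, lineno, n=3):
    try:
        vals = [float(x) for x in parts[:n]]
    except ValueError:
        raise MeshIOError(f"{path}:{lineno}: malformed vertex record") from None
    if len(vals) < n:
        raise MeshIOError(f"{path}:{lineno}: vertex record needs {n} coordinates")
    return vals


def _face_index(token, nverts, path, lineno):
    idx_str = token.split("/")[0]
    try:
        i = int(idx_str)
    except ValueError:
        raise MeshIOError(f"{path}:{lineno}: malformed face index {token!r}") from None
    if i < 0:
        i = nverts + i
    else:
        i = i - 1
    if i < 0 or i >= nverts:
        raise MeshIOError(f"{path}:{lineno}: face index {token!r} out of range")
    return i


def read_obj(path, label: str | None = None) -> SurfaceScan:
    """Read an ASCII OBJ into a :class:`SurfaceScan`.

    Polygonal faces with more than three vertices are triangulated by a
    deterministic fan from the first vertex, so the vertex list is unchanged.
    """
    path = Path(path)
    vertices, faces = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            tag = parts[0]
            if tag == "v":
                vertices.append(_parse_floats(parts[1:], path, lineno))
            elif tag == "f":
                if len(parts) < 4:
                    raise MeshIOError(f"{path}:{lineno}: face needs >= 3 vertices")
                idx = [_face_index(t, len(vertices), path, lineno) for t in parts[1:]]
                for k in range(1, len(idx) - 1):  # fan from first vertex
                    faces.append((idx[0], idx[k], idx[k + 1]))
            # vt/vn/usemtl/mtllib/o/g/l/s ignored for geometry
    if not vertices or not faces:
        raise MeshIOError(f"{path}: no mesh geometry (need v and f records)")
    return SurfaceScan(np.array(vertices), np.array(faces),
                       label if label is not None else path.stem)


def write_obj(path, scan: SurfaceScan) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# facevol surface scan {scan.label}\n")
        for v in scan.vertices:
            fh.write(f"v {v[0]:.8f} {v[1]:.8f} {v[2]:.8f}\n")
        for f in scan.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


# ---------------------------------------------------------------------------
# laser traces (OBJ dialect: one `o <kind>` group per trace, `v` points in
# polyline order, optional `l` records)

def read_lasers(path) -> dict:
    path = Path(path)
    traces: dict[str, list] = {}
    current = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if parts[0] in ("o", "g"):
                if len(parts) < 2:
                    raise MeshIOError(f"{path}:{lineno}: unnamed group")
                current = parts[1]
                traces.setdefault(current, [])
            elif parts[0] == "v":
                if current is None:
                    raise MeshIOError(
                        f"{path}:{lineno}: laser point before any o/g group")
                traces[current].append(_parse_floats(parts[1:], path, lineno))
    if not traces:
        raise MeshIOError(f"{path}: no laser traces found")
    out = {}
    for kind, pts in traces.items():
        out[kind] = LaserTrace(kind, np.array(pts))
    return out


def write_lasers(path, traces) -> None:
    if isinstance(traces, dict):
        traces = list(traces.values())
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# facevol laser traces\n")
        offset = 1
        for tr in traces:
            fh.write(f"o {tr.kind}\n")
            for p in tr.points:
                fh.write(f"v {p[0]:.8f} {p[1]:.8f} {p[2]:.8f}\n")
            idx = " ".join(str(i) for i in range(offset, offset + len(tr.points)))
            fh.write(f"l {idx}\n")
            offset += len(tr.points)


# ---------------------------------------------------------------------------
# landmarks

def _split_code(code: str, path, lineno):
    if ":" in code:
        base, side = code.rsplit(":", 1)
        if side not in ("L", "R"):
            raise MeshIOError(f"{path}:{lineno}: side must be L or R, got {side!r}")
    else:
        base, side = code, "R"
    if base not in LANDMARK_CODES and not (
            base.startswith("mb") and base[2:].isdigit()):
        raise MeshIOError(f"{path}:{lineno}: unknown landmark code {base!r}")
    return base, side


def read_landmarks(path, scan: SurfaceScan | None = None,
                   tolerance: float = 1.0) -> LandmarkSet:
    """Read ``code,x,y,z`` CSV landmarks, optionally validated against a scan.

    Codes are the Table-style abbreviations (``pt'``, ``al'``, ``ex'``,
    ``ch'``, ``cf'``) or ``mb<k>`` for the k-th mandible-lower-border point,
    optionally suffixed ``:L``/``:R`` (default ``R``). A landmark farther
    than ``tolerance`` mm from the scan surface triggers a warning (recorded
    on the returned set), not an error.
    """
    path = Path(path)
    lm = LandmarkSet()
    border_raw: dict[str, list] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) != 4:
                raise MeshIOError(f"{path}:{lineno}: expected code,x,y,z")
            base, side = _split_code(parts[0], path, lineno)
            try:
                pt = np.array([float(x) for x in parts[1:]])
            except ValueError:
                raise MeshIOError(f"{path}:{lineno}: malformed coordinates") from None
            if base.startswith("mb"):
                border_raw.setdefault(side, []).append((int(base[2:]), pt))
            else:
                side_map = lm.points.setdefault(side, {})
                if base in side_map:
                    raise MeshIOError(
                        f"{path}:{lineno}: duplicate landmark {base!r} for side {side}")
                side_map[base] = pt
    for side, items in border_raw.items():
        items.sort(key=lambda t: t[0])
        lm.mandible[side] = np.array([p for _, p in items])

    if scan is not None:
        index = scan.surface_index()
        for side in lm.sides():
            named = [(c, p) for c, p in lm.points.get(side, {}).items()]
            named += [(f"mb{i + 1}", p)
                      for i, p in enumerate(lm.mandible.get(side, []))]
            if not named:
                continue
            pts = np.array([p for _, p in named])
            _, dist, _ = index.query(pts)
            for (code, _), d in zip(named, dist):
                if d > tolerance:
                    msg = (f"landmark {code}:{side} lies {d:.2f} mm off the "
                           f"scan surface (tolerance {tolerance} mm)")
                    lm.warnings_.append(msg)
                    warnings.warn(msg, stacklevel=2)
    return lm


def write_landmarks(path, lm: LandmarkSet) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# code,x,y,z\n")
        for side in lm.sides():
            for code, p in lm.points.get(side, {}).items():
                fh.write(f"{code}:{side},{p[0]:.6f},{p[1]:.6f},{p[2]:.6f}\n")
            for i, p in enumerate(lm.mandible.get(side, [])):
                fh.write(f"mb{i + 1}:{side},{p[0]:.6f},{p[1]:.6f},{p[2]:.6f}\n")
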
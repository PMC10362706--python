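"""Synthetic phantoms with analytic ground truth.

Every fixture used by the tests and the acceptance checks is generated
here, so each geometric quantity the pipeline measures has a closed form:

* Face phantoms — a smooth paraboloid face shell ``x = F(y, z)`` (y lateral
  toward the subject's right, z vertical, x anteroposterior) observed at
  T0/T1/T2. Follow-up scans differ by an optional known rigid perturbation,
  optional Gaussian surface noise, and "swelling" deformations modeled as
  Gaussian bumps displacing the surface along +y. Because a bump displaces
  the surface purely along the projection direction as a function of the
  mid-sagittal footprint coordinates (x, z), the projected-volume change it
  adds is exactly the 2D Gaussian integral 2*pi*A*sigma^2.

  The phantom cheek is deliberately larger and flatter than an anatomical
  cheek so that the largest test bumps (sigma = 10 mm) fit with truncated
  mass below 0.1% of their analytic volume.

* Laser traces — exact intersection curves of the T0 shell with the z = 0
  (horizontal) and y = 0 (vertical) planes, optionally perturbed.

* Patch phantoms — height fields ``y = g(x, z)`` over a rectangle (plane /
  spherical cap), used for direct volume-integration oracles.

* CBCT phantoms — voxel grids with a bone-like plate and tooth-like
  spherical blobs of known analytic volume, removable at T2.

* Rater tables — two-way random-effects data with known variance
  components, hence known expected ICC(2,1).

All randomness flows through a single integer seed; identical specs give
bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point, Polygon

from .cbct import SelectionBox, VoxelVolume, write_dicom
from .mesh_io import LandmarkSet, LaserTrace, SurfaceScan
from .region import BuccalPatch
from .registration import RigidTransform
from .sagittal_frame import Plane, SagittalFrame
from .stats import RaterTable

__all__ = [
    "GaussianBump", "PhantomSpec", "FaceSeries", "make_face_series",
    "random_bumps", "CbctPhantomSpec", "CbctSeries", "make_cbct_series",
    "make_rater_table", "grid_patch", "canonical_frame", "SpecError",
]

#: clearance (in sigmas) guaranteeing truncated bump mass < 0.1% of
#: 2*pi*A*sigma^2: 1 - exp(-r^2 / 2 sigma^2) >= 0.999  =>  r >= 3.717 sigma
TRUNCATION_SIGMAS = math.sqrt(2.0 * math.log(1000.0))


class SpecError(ValueError):
    pass


# ---------------------------------------------------------------------------
# face phantom

@dataclass(frozen=True)
class GaussianBump:
    """Radial Gaussian swelling in mid-sagittal footprint coordinates.

    center : (x, z) mm in the projection plane
    amplitude : peak displacement along +y, mm
    sigma : width, mm; analytic projected volume = 2*pi*amplitude*sigma^2
    timepoints : which scans carry the bump
    """

    center: tuple
    amplitude: float
    sigma: float
    timepoints: tuple = ("T1", "T2")

    @property
    def volume_mm3(self) -> float:
        return 2.0 * math.pi * self.amplitude * self.sigma ** 2


#: parameter-plane (y, z) landmark layout of the right buccal loop. The
#: medial boundary stays >= 12 mm lateral of the mid-sagittal plane so the
#: +-10 mm ring sweep never reaches the opposite side of the face.
_DEFAULT_LANDMARKS = {
    "pt'": (95.0, 6.0),
    "al'": (22.0, 10.0),
    "ex'": (13.0, 14.0),
    "ch'": (16.0, -95.0),
}
_DEFAULT_BORDER = [(12.0, -106.0), (45.0, -115.0), (72.0, -108.0),
                   (88.0, -90.0), (94.0, -60.0), (95.0, -30.0)]


@dataclass(frozen=True)
class PhantomSpec:
    """Face-series phantom description.

    The default geometry is the "cheek" paraboloid shell
    ``x = depth - y^2/curve_y - z^2/curve_z`` sampled on a regular (y, z)
    grid. ``resolution`` is the grid step in mm.
    """

    family: str = "cheek"
    extent: tuple = ((-105.0, 105.0), (-125.0, 85.0))
    resolution: float = 0.5
    depth: float = 120.0
    curve_y: float = 109.0
    curve_z: float = 800.0
    #: vertical relief features of the upper face, each (amplitude mm,
    #: center z mm, width mm): a brow ridge and a frontal eminence. Real
    #: faces have strong vertical relief there, and the upper-third
    #: registration depends on it.
    brow: tuple = ((6.0, 18.0, 6.0), (5.0, 55.0, 12.0))
    bumps: tuple = ()
    rigid_t1: RigidTransform | None = None
    rigid_t2: RigidTransform | None = None
    noise_sigma: float = 0.0
    laser_noise_sigma: float = 0.0
    seed: int = 0
    landmarks_param: dict = field(default_factory=lambda: dict(_DEFAULT_LANDMARKS))
    border_param: tuple = tuple(_DEFAULT_BORDER)


@dataclass
class FaceSeries:
    scans: dict
    lasers: dict
    landmarks: LandmarkSet
    truth: dict
    spec: PhantomSpec


def _shell_height(spec: PhantomSpec, y, z):
    x = spec.depth - y ** 2 / spec.curve_y - z ** 2 / spec.curve_z
    if spec.brow:
        ridges = spec.brow
        if np.ndim(ridges[0]) == 0:  # single (amp, z0, sig) triple
            ridges = (ridges,)
        for amp, z0, sig in ridges:
            x = x + amp * np.exp(-((np.asarray(z, dtype=float) - z0) ** 2)
                                 / (2.0 * sig ** 2))
    return x


def _grid_mesh(spec: PhantomSpec):
    (y0, y1), (z0, z1) = spec.extent
    res = spec.resolution
    ys = np.arange(y0, y1 + res / 2, res)
    zs = np.arange(z0, z1 + res / 2, res)
    yy, zz = np.meshgrid(ys, zs, indexing="ij")
    xx = _shell_height(spec, yy, zz)
    vertices = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    ny, nz = len(ys), len(zs)
    i, j = np.meshgrid(np.arange(ny - 1), np.arange(nz - 1), indexing="ij")
    v00 = (i * nz + j).ravel()
    v01 = v00 + 1
    v10 = v00 + nz
    v11 = v10 + 1
    faces = np.vstack([np.column_stack([v00, v10, v11]),
                       np.column_stack([v00, v11, v01])])
    return vertices, faces, (ny, nz)


def _footprint_polygon(spec: PhantomSpec) -> Polygon:
    """Mid-sagittal-plane (x, z) footprint of the right buccal loop."""
    order = ["pt'", "al'", "ex'", "ch'"]
    pts = [spec.landmarks_param[c] for c in order]
    pts += [p for p in spec.border_param]
    yz = np.array(pts)
    x = _shell_height(spec, yz[:, 0], yz[:, 1])
    poly = Polygon(np.column_stack([x, yz[:, 1]]))
    if not poly.is_valid:
        poly = poly.buffer(0)
    return poly


def _validate_bumps(spec: PhantomSpec):
    poly = _footprint_polygon(spec)
    for b in spec.bumps:
        clearance = poly.exterior.distance(Point(b.center))
        needed = TRUNCATION_SIGMAS * b.sigma
        if not poly.contains(Point(b.center)) or clearance < needed:
            raise SpecError(
                f"bump at {b.center} (sigma {b.sigma}) is not fully inside "
                f"the patch footprint: clearance {clearance:.1f} mm < "
                f"{needed:.1f} mm required for < 0.1% truncation")


def _bump_displacement(spec: PhantomSpec, vertices: np.ndarray,
                       timepoint: str) -> np.ndarray:
    """Displacement along +y at each vertex (right side only)."""
    dy = np.zeros(len(vertices))
    x, y, z = vertices[:, 0], vertices[:, 1], vertices[:, 2]
    right = y > 0
    for b in spec.bumps:
        if timepoint not in b.timepoints:
            continue
        r2 = (x - b.center[0]) ** 2 + (z - b.center[1]) ** 2
        dy += np.where(right,
                       b.amplitude * np.exp(-r2 / (2.0 * b.sigma ** 2)), 0.0)
    return dy


def make_face_series(spec: PhantomSpec) -> FaceSeries:
    """Generate the T0/T1/T2 scan series with lasers, landmarks and truth.

    T0 is the noiseless baseline in the canonical pose. T1/T2 carry the
    spec's deformations, then Gaussian surface noise along vertex normals,
    then the rigid perturbation (simulating a different acquisition pose).
    The truth record holds the analytic added projected volume per period
    and the perturbation transforms.
    """
    if spec.family != "cheek":
        raise SpecError("face series requires the 'cheek' family; use "
                        "grid_patch for plane / spherical-cap phantoms")
    _validate_bumps(spec)
    rng = np.random.default_rng(spec.seed)
    vertices, faces, _ = _grid_mesh(spec)

    scans = {"T0": SurfaceScan(vertices.copy(), faces.copy(), "T0")}
    added = {}
    for tp, rigid in (("T1", spec.rigid_t1), ("T2", spec.rigid_t2)):
        v = vertices.copy()
        dy = _bump_displacement(spec, v, tp)
        v[:, 1] += dy
        if spec.noise_sigma > 0:
            import trimesh
            normals = np.asarray(
                trimesh.Trimesh(v, faces, process=False).vertex_normals)
            v = v + normals * rng.normal(0.0, spec.noise_sigma,
                                         size=len(v))[:, None]
        if rigid is not None:
            v = rigid.apply(v)
        scans[tp] = SurfaceScan(v, faces.copy(), tp)
        added[tp] = float(sum(b.volume_mm3 for b in spec.bumps
                              if tp in b.timepoints))

    # analytic truth for the three periods (right side)
    truth = {
        "stvc_mm3": {
            "T1-T0": added["T1"],
            "T2-T0": added["T2"],
            "T2-T1": added["T2"] - added["T1"],
        },
        "transforms": {"T1": spec.rigid_t1, "T2": spec.rigid_t2},
    }

    # laser traces: exact plane sections of the T0 shell
    (y0, y1), (z0, z1) = spec.extent
    ys = np.linspace(y0 + 5.0, y1 - 5.0, 81)       # left -> right
    zs = np.linspace(z0 + 5.0, z1 - 5.0, 61)       # inferior -> superior
    hpts = np.column_stack([_shell_height(spec, ys, 0.0), ys, np.zeros_like(ys)])
    vpts = np.column_stack([_shell_height(spec, 0.0, zs), np.zeros_like(zs), zs])
    if spec.laser_noise_sigma > 0:
        hpts = hpts + rng.normal(0, spec.laser_noise_sigma, hpts.shape)
        vpts = vpts + rng.normal(0, spec.laser_noise_sigma, vpts.shape)
    lasers = {
        "horizontal-complete": LaserTrace("horizontal-complete", hpts),
        "vertical": LaserTrace("vertical", vpts),
    }

    lm = LandmarkSet()
    for side, sign in (("R", 1.0), ("L", -1.0)):
        side_map = {}
        for code, (py, pz) in spec.landmarks_param.items():
            side_map[code] = np.array([_shell_height(spec, py, pz),
                                       sign * py, pz])
        lm.points[side] = side_map
        lm.mandible[side] = np.array(
            [[_shell_height(spec, py, pz), sign * py, pz]
             for py, pz in spec.border_param])

    return FaceSeries(scans=scans, lasers=lasers, landmarks=lm,
                      truth=truth, spec=spec)


def random_bumps(seed: int, n: int = 1,
                 amplitude_range=(0.5, 3.0), sigma_range=(4.0, 10.0),
                 timepoints=("T1", "T2"),
                 base_spec: PhantomSpec | None = None) -> tuple:
    """Draw bumps with centers uniformly placed inside the safe region of
    the footprint (clearance >= 3.72 sigma from the boundary)."""
    spec = base_spec if base_spec is not None else PhantomSpec()
    poly = _footprint_polygon(spec)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        a = float(rng.uniform(*amplitude_range))
        s = float(rng.uniform(*sigma_range))
        safe = poly.buffer(-(TRUNCATION_SIGMAS * s + 0.5))
        if safe.is_empty:
            raise SpecError(f"no admissible bump center for sigma {s:.1f}")
        minx, minz, maxx, maxz = safe.bounds
        for _ in range(10000):
            c = (float(rng.uniform(minx, maxx)), float(rng.uniform(minz, maxz)))
            if safe.contains(Point(c)):
                out.append(GaussianBump(center=c, amplitude=a, sigma=s,
                                        timepoints=tuple(timepoints)))
                break
        else:  # pragma: no cover
            raise SpecError("rejection sampling failed")
    return tuple(out)


# ---------------------------------------------------------------------------
# simple patch phantoms (analytic volume oracles)

def canonical_frame() -> SagittalFrame:
    """Frame with the mid-sagittal plane at y = 0, projection direction +y
    (subject-right), vertical axis +z."""
    return SagittalFrame(
        origin=np.zeros(3),
        horizontal_plane=Plane(np.zeros(3), np.array([0.0, 0.0, 1.0])),
        midsagittal_plane=Plane(np.zeros(3), np.array([0.0, 1.0, 0.0])),
        projection_direction=np.array([0.0, 1.0, 0.0]),
        vertical_axis=np.array([0.0, 0.0, 1.0]),
    )


def grid_patch(family: str = "plane", size=(20.0, 20.0), distance: float = 30.0,
               resolution: float = 1.0, radius: float = 60.0,
               bumps: tuple = (), side: str = "R") -> BuccalPatch:
    """Rectangular height-field patch ``y = g(x, z)`` with its perimeter as
    the boundary loop, in the canonical frame.

    family "plane": g = distance (an exact prism of volume area x distance).
    family "spherical-cap": g = distance + sqrt(r^2 - x^2 - z^2) - r,
    centered over the rectangle. Gaussian ``bumps`` (in (x, z)) are added
    onto g.
    """
    sx, sz = size
    xs = np.arange(-sx / 2, sx / 2 + resolution / 2, resolution)
    zs = np.arange(-sz / 2, sz / 2 + resolution / 2, resolution)
    xx, zz = np.meshgrid(xs, zs, indexing="ij")
    if family == "plane":
        yy = np.full_like(xx, distance)
    elif family == "spherical-cap":
        r2 = radius ** 2 - xx ** 2 - zz ** 2
        if np.any(r2 <= 0):
            raise SpecError("patch extends beyond the sphere radius")
        yy = distance + np.sqrt(r2) - radius
    else:
        raise SpecError(f"unknown patch family {family!r}")
    for b in bumps:
        r2 = (xx - b.center[0]) ** 2 + (zz - b.center[1]) ** 2
        yy = yy + b.amplitude * np.exp(-r2 / (2.0 * b.sigma ** 2))
    sign = 1.0 if side == "R" else -1.0
    vertices = np.column_stack([xx.ravel(), sign * yy.ravel(), zz.ravel()])
    nx, nz = len(xs), len(zs)
    i, j = np.meshgrid(np.arange(nx - 1), np.arange(nz - 1), indexing="ij")
    v00 = (i * nz + j).ravel()
    faces = np.vstack([np.column_stack([v00, v00 + nz, v00 + nz + 1]),
                       np.column_stack([v00, v00 + nz + 1, v00 + 1])])
    # perimeter loop, counter-clockwise in (x, z)
    bottom = [i * nz + 0 for i in range(nx)]
    right = [(nx - 1) * nz + j for j in range(1, nz)]
    top = [i * nz + (nz - 1) for i in range(nx - 2, -1, -1)]
    left = [0 * nz + j for j in range(nz - 2, 0, -1)]
    boundary = np.array(bottom + right + top + left, dtype=int)
    return BuccalPatch(vertices=vertices, faces=faces, boundary=boundary,
                       side=side, label="patch")


# ---------------------------------------------------------------------------
# CBCT phantom

@dataclass(frozen=True)
class ToothBlob:
    """Spherical tooth-like insert of known analytic volume."""

    center: tuple = (0.0, 0.0, 0.0)
    radius: float = 8.0
    intensity: float = 2800.0
    jaw: str = "maxilla"
    removed_at_t2: bool = True

    @property
    def volume_mm3(self) -> float:
        return 4.0 / 3.0 * math.pi * self.radius ** 3


@dataclass(frozen=True)
class CbctPhantomSpec:
    """Two-timepoint CBCT phantom: background + bone plate + tooth blobs.

    ``shape`` is (nz, ny, nx); ``spacing`` (dx, dy, dz) mm. Intensities sit
    inside/outside the clinical threshold window: background 50 (soft
    tissue, below), bone plate 1500 and blobs 2800 (both inside the default
    [550, 3300] window).
    """

    shape: tuple = (96, 96, 96)
    spacing: tuple = (0.25, 0.25, 0.25)
    background: float = 50.0
    bone_intensity: float = 1500.0
    bone_plate: tuple | None = ((2.0, 4.0), None, None)  # (x0,x1) slab in mm
    blobs: tuple = (ToothBlob(center=(12.0, 12.0, 12.0)),)
    noise_sigma: float = 0.0
    seed: int = 0


@dataclass
class CbctSeries:
    t0: VoxelVolume
    t2: VoxelVolume
    boxes: list
    truth: dict
    spec: CbctPhantomSpec


def _world_grids(spec: CbctPhantomSpec):
    nz, ny, nx = spec.shape
    dx, dy, dz = spec.spacing
    xs = np.arange(nx) * dx
    ys = np.arange(ny) * dy
    zs = np.arange(nz) * dz
    return np.meshgrid(zs, ys, xs, indexing="ij")  # zz, yy, xx (world mm)


def make_cbct_series(spec: CbctPhantomSpec, write_dirs=None) -> CbctSeries:
    """Build the T0/T2 volumes; T2 lacks every blob flagged
    ``removed_at_t2``. Truth holds each blob's analytic volume and a
    selection box enclosing it with 2 mm margin. Optionally writes DICOM
    series to ``write_dirs=(dir_t0, dir_t2)``."""
    nz, ny, nx = spec.shape
    dx, dy, dz = spec.spacing
    extent = np.array([nx * dx, ny * dy, nz * dz])
    zz, yy, xx = _world_grids(spec)

    base = np.full(spec.shape, spec.background, dtype=float)
    if spec.bone_plate is not None:
        (x0, x1) = spec.bone_plate[0]
        base[(xx >= x0) & (xx <= x1)] = spec.bone_intensity

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma > 0:
        base = base + rng.normal(0, spec.noise_sigma, spec.shape)

    t0 = base.copy()
    t2 = base.copy()
    boxes = []
    truth_blobs = []
    for blob in spec.blobs:
        c = np.asarray(blob.center, dtype=float)
        if np.any(c - blob.radius < 0) or np.any(c + blob.radius > extent):
            raise SpecError(f"blob at {blob.center} r={blob.radius} extends "
                            "outside the grid")
        inside = ((xx - c[0]) ** 2 + (yy - c[1]) ** 2
                  + (zz - c[2]) ** 2) <= blob.radius ** 2
        t0[inside] = blob.intensity
        if not blob.removed_at_t2:
            t2[inside] = blob.intensity
        margin = 2.0
        boxes.append(SelectionBox(min_corner=c - blob.radius - margin,
                                  max_corner=c + blob.radius + margin,
                                  jaw=blob.jaw))
        truth_blobs.append({"jaw": blob.jaw,
                            "volume_mm3": blob.volume_mm3,
                            "removed": blob.removed_at_t2})

    removed = sum(b["volume_mm3"] for b in truth_blobs if b["removed"])
    truth = {"blobs": truth_blobs, "removed_volume_mm3": removed,
             "htvc_ml": -removed / 1000.0}
    vol_t0 = VoxelVolume(np.round(t0).astype(np.int16), spec.spacing)
    vol_t2 = VoxelVolume(np.round(t2).astype(np.int16), spec.spacing)
    if write_dirs is not None:
        write_dicom(vol_t0, write_dirs[0], "phantom T0", seed=spec.seed * 2 + 1)
        write_dicom(vol_t2, write_dirs[1], "phantom T2", seed=spec.seed * 2 + 2)
    return CbctSeries(t0=vol_t0, t2=vol_t2, boxes=boxes, truth=truth,
                      spec=spec)


# ---------------------------------------------------------------------------
# rater tables

def make_rater_table(n: int, k: int, var_subject: float, var_rater: float,
                     var_error: float, seed: int = 0) -> RaterTable:
    """Two-way random-effects table ``y_ij = s_i + r_j + e_ij`` with the
    stated variance components; expected
    ICC(2,1) = var_subject / (var_subject + var_rater + var_error)."""
    if min(var_subject, var_rater, var_error) < 0:
        raise SpecError("variances must be non-negative")
    rng = np.random.default_rng(seed)
    s = rng.normal(0, math.sqrt(var_subject), size=(n, 1)) if var_subject else np.zeros((n, 1))
    r = rng.normal(0, math.sqrt(var_rater), size=(1, k)) if var_rater else np.zeros((1, k))
    e = rng.normal(0, math.sqrt(var_error), size=(n, k)) if var_error else np.zeros((n, k))
    return RaterTable(s + r + e)
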
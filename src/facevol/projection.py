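"""Boundary transfer by the ring model and projected-volume measurement.

The measurement region is fixed once, on the T0 scan, as a closed boundary
loop on the cheek. To measure the *same* region on later scans without
re-drawing it, the loop is swept +-``half_length`` mm along Line 3 (the
mid-sagittal normal) into an open "ring" surface; cutting a registered
follow-up scan with that ring reproduces the T0 region on the new surface.
The soft-tissue volume (STV) of a patch is then the volume of the solid
between the patch and its orthogonal projection onto the mid-sagittal
plane; the change between two time points (STVC) is the difference of
STVs.

The cut is implemented in the projection plane: scan triangles are
projected along the sweep direction and clipped in 2D against the T0
boundary polygon, then lifted back to 3D barycentrically. On open,
non-watertight facial scans this is equivalent to the Boolean subtraction
of the ring but far more robust, and it makes the self-cut (cutting T0
with its own ring) exact up to floating point.

STV is computed by signed-prism summation: each triangle contributes
(signed distance of its centroid to the mid-sagittal plane) x (its area
projected onto that plane). For a patch projecting injectively this equals
the volume of the closed projected solid; it is the natural generalization
otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from shapely.geometry import Polygon

from .mesh_io import SurfaceScan
from .region import BuccalPatch, RegionError
from .sagittal_frame import SagittalFrame

__all__ = ["RingModel", "VolumeResult", "StvChange", "extrude_ring",
           "boolean_cut", "stv", "stvc", "ProjectionError"]

#: sweep half-length of the ring model, mm (boundary extruded this far in
#: both directions along Line 3)
DEFAULT_HALF_LENGTH = 10.0


class ProjectionError(ValueError):
    """Ring construction or cut failure."""


@dataclass
class RingModel:
    """Open band swept from a boundary loop along the projection direction.

    ``loop`` is the ordered closed T0 boundary (first vertex not repeated);
    every ring vertex decomposes as ``loop[i] + s * direction`` with
    ``|s| <= half_length``.
    """

    loop: np.ndarray
    direction: np.ndarray
    half_length: float
    vertices: np.ndarray
    faces: np.ndarray
    self_intersecting: bool = False

    def as_scan(self) -> SurfaceScan:
        return SurfaceScan(self.vertices.copy(), self.faces.copy(), "ring")


@dataclass
class VolumeResult:
    """Projected soft-tissue volume of one patch at one time point."""

    stv_ml: float
    side: str
    timepoint: str
    area_mm2: float
    volume_mm3: float
    qc: dict = field(default_factory=dict)


@dataclass
class StvChange:
    """STVC: later-minus-earlier difference of projected volumes (ml)."""

    value_ml: float
    period: str
    side: str

    def __float__(self):
        return float(self.value_ml)


def _projection_basis(direction: np.ndarray):
    """Deterministic orthonormal (u, v) basis spanning the plane normal to
    ``direction``."""
    d = np.asarray(direction, dtype=float)
    n = np.linalg.norm(d)
    if abs(n - 1.0) > 1e-6:
        raise ProjectionError("sweep direction must be a unit vector")
    d = d / n
    helper = np.eye(3)[np.argmin(np.abs(d))]
    u = np.cross(d, helper)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return d, u, v


def extrude_ring(patch, direction: np.ndarray,
                 half_length: float = DEFAULT_HALF_LENGTH) -> RingModel:
    """Sweep the patch boundary loop +-``half_length`` mm along ``direction``.

    The interior faces of the patch are discarded; only the swept band (a
    triangulated quad strip with two parallel boundary loops) remains.
    Accepts a :class:`BuccalPatch` or a raw closed (n, 3) loop.
    """
    if half_length <= 0:
        raise ProjectionError("sweep half-length must be positive")
    loop = patch.boundary_coords if isinstance(patch, BuccalPatch) \
        else np.asarray(patch, dtype=float)
    if loop.ndim != 2 or len(loop) < 3:
        raise ProjectionError("boundary loop needs >= 3 points")
    d, u, v = _projection_basis(direction)

    n = len(loop)
    lower = loop - half_length * d
    upper = loop + half_length * d
    vertices = np.vstack([lower, upper])
    faces = []
    for i in range(n):
        j = (i + 1) % n
        # quad (lower_i, lower_j, upper_j, upper_i), fan from first vertex
        faces.append((i, j, n + j))
        faces.append((i, n + j, n + i))
    faces = np.array(faces, dtype=int)

    loop2d = np.column_stack([loop @ u, loop @ v])
    poly = Polygon(loop2d)
    self_intersecting = not poly.is_valid
    if self_intersecting:
        warnings.warn("swept band self-intersects when projected along the "
                      "sweep direction; downstream cut may be ambiguous",
                      stacklevel=2)
    return RingModel(loop=loop.copy(), direction=d, half_length=float(half_length),
                     vertices=vertices, faces=faces,
                     self_intersecting=self_intersecting)


# ---------------------------------------------------------------------------
# 2D helpers for the cut

def _ear_clip(coords: np.ndarray) -> list:
    """Triangulate a simple 2D polygon (no holes) by ear clipping.

    Returns index triples into ``coords``. Polygons from clipping a convex
    triangle against a simple loop are small, so O(n^2) is fine.
    """
    n = len(coords)
    if n < 3:
        return []
    area2 = 0.0
    for i in range(n):
        j = (i + 1) % n
        area2 += coords[i, 0] * coords[j, 1] - coords[j, 0] * coords[i, 1]
    order = list(range(n)) if area2 >= 0 else list(range(n - 1, -1, -1))
    tris = []
    guard = 0
    while len(order) > 3 and guard < 10 * n * n:
        guard += 1
        m = len(order)
        clipped = False
        for k in range(m):
            i0, i1, i2 = order[(k - 1) % m], order[k], order[(k + 1) % m]
            a, b, c = coords[i0], coords[i1], coords[i2]
            cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
            if cross <= 1e-14 * (np.abs(b - a).sum() * np.abs(c - a).sum() + 1e-30):
                continue  # reflex or degenerate corner
            # no other polygon vertex inside the candidate ear
            ok = True
            for idx in order:
                if idx in (i0, i1, i2):
                    continue
                p = coords[idx]
                d1 = (b[0] - a[0]) * (p[1] - a[1]) - (b[1] - a[1]) * (p[0] - a[0])
                d2 = (c[0] - b[0]) * (p[1] - b[1]) - (c[1] - b[1]) * (p[0] - b[0])
                d3 = (a[0] - c[0]) * (p[1] - c[1]) - (a[1] - c[1]) * (p[0] - c[0])
                if d1 >= 0 and d2 >= 0 and d3 >= 0:
                    ok = False
                    break
            if ok:
                tris.append((i0, i1, i2))
                order.pop(k)
                clipped = True
                break
        if not clipped:
            break
    if len(order) == 3:
        tris.append(tuple(order))
    return tris


def _lift_2d(points2d, tri2d, tri3d):
    """Map 2D points back onto the 3D triangle via the affine (barycentric)
    inverse of the projection. Returns None when the projected triangle is
    degenerate (edge-on to the sweep direction)."""
    m = np.column_stack([tri2d[1] - tri2d[0], tri2d[2] - tri2d[0]])
    det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
    scale = np.abs(m).max()
    if abs(det) < 1e-12 * max(scale * scale, 1e-30):
        return None
    minv = np.array([[m[1, 1], -m[0, 1]], [-m[1, 0], m[0, 0]]]) / det
    lam = (np.atleast_2d(points2d) - tri2d[0]) @ minv.T
    return (tri3d[0] + lam[:, 0:1] * (tri3d[1] - tri3d[0])
            + lam[:, 1:2] * (tri3d[2] - tri3d[0]))


def boolean_cut(ring: RingModel, scan: SurfaceScan) -> BuccalPatch:
    """Cut ``scan`` (already registered into the T0 frame) with the ring.

    Returns the part of the scan whose projection along the sweep direction
    falls inside the T0 boundary loop, with the intersection curve as its
    boundary: triangles fully inside are kept, triangles crossing the loop
    are clipped exactly in the projection plane and lifted back to 3D.

    Raises :class:`ProjectionError` when the ring misses the scan, when the
    scan crosses the band beyond ``half_length`` (out of the sweep band), or
    when several well-separated surface components lie inside the loop
    (ambiguous cut; the error lists their areas).
    """
    d, u, v = _projection_basis(ring.direction)
    loop2d = np.column_stack([ring.loop @ u, ring.loop @ v])
    poly = Polygon(loop2d)
    if not poly.is_valid:
        poly = poly.buffer(0)
        if poly.is_empty:
            raise ProjectionError("boundary loop projects to an invalid polygon")

    verts2d = np.column_stack([scan.vertices @ u, scan.vertices @ v])
    raw_in = shapely.contains_xy(poly, verts2d[:, 0], verts2d[:, 1])
    # restrict to the height reach of the swept band: surface sheets on the
    # far side of the mid-sagittal plane (e.g. the opposite cheek) project
    # into the same loop but are beyond the ring
    loop_heights = ring.loop @ d
    vh = scan.vertices @ d
    in_reach = (vh >= loop_heights.min() - ring.half_length) & \
               (vh <= loop_heights.max() + ring.half_length)
    inside = raw_in & in_reach
    n_in = inside[scan.faces].sum(axis=1)

    # vertices lying exactly on the loop polygon (the self-cut and
    # translation-invariance cases: the boundary passes through mesh
    # vertices) classify as "outside" under strict containment; detect them
    # so boundary-touching faces are kept whole instead of being clipped or
    # dropped
    exterior = poly.exterior
    snap = 1e-6
    on_boundary = np.zeros(len(scan.vertices), dtype=bool)
    checked = inside.copy()  # inside vertices need no boundary test
    cand_faces = scan.faces[(n_in > 0) & (n_in < 3)]
    cand_v = np.unique(cand_faces[~inside[cand_faces]])
    # grow the on-boundary set along chains of boundary-touching faces
    # (staircase corners of an edge-walk loop are reachable only through
    # other on-boundary vertices)
    for _ in range(len(scan.faces)):
        cand_v = cand_v[~checked[cand_v]]
        if len(cand_v) == 0:
            break
        dists = np.array([exterior.distance(shapely.Point(p))
                          for p in verts2d[cand_v]])
        hits = cand_v[dists < snap]
        checked[cand_v] = True
        if len(hits) == 0:
            break
        on_boundary[hits] = True
        touched = scan.faces[np.isin(scan.faces, hits).any(axis=1)]
        cand_v = np.unique(touched[~inside[touched]])
    on_boundary &= in_reach
    in_or_on = inside | on_boundary
    n_on = in_or_on[scan.faces].sum(axis=1)
    # corner faces: all three vertices on the loop, interior decided by the
    # centroid (their non-loop neighbours already supplied the on_boundary
    # flags above)
    all_on = (n_on == 3) & (n_in == 0)
    if all_on.any():
        cent = verts2d[scan.faces[all_on]].mean(axis=1)
        cent_in = shapely.contains_xy(poly, cent[:, 0], cent[:, 1])
        promote = np.zeros(len(scan.faces), dtype=bool)
        promote[np.flatnonzero(all_on)[cent_in]] = True
    else:
        promote = np.zeros(len(scan.faces), dtype=bool)

    full = (n_on == 3) & ((n_in > 0) | promote)
    mixed = (n_in > 0) & (n_on < 3)
    if not full.any() and not mixed.any():
        raise ProjectionError("ring does not intersect the scan "
                              "(no scan face projects into the loop)")

    # connected components of the candidate faces
    cand = full | mixed
    cand_idx = np.flatnonzero(cand)
    tri3d_all = scan.vertices[scan.faces]
    tri_areas = 0.5 * np.linalg.norm(
        np.cross(tri3d_all[:, 1] - tri3d_all[:, 0],
                 tri3d_all[:, 2] - tri3d_all[:, 0]), axis=1)
    mesh = scan.as_trimesh()
    adj = np.asarray(mesh.face_adjacency)
    both = cand[adj[:, 0]] & cand[adj[:, 1]]
    sub = adj[both]
    pos = -np.ones(len(scan.faces), dtype=int)
    pos[cand_idx] = np.arange(len(cand_idx))
    g = coo_matrix((np.ones(len(sub)), (pos[sub[:, 0]], pos[sub[:, 1]])),
                   shape=(len(cand_idx), len(cand_idx)))
    n_comp, comp = connected_components(g, directed=False)
    comp_areas = np.bincount(comp, weights=tri_areas[cand_idx], minlength=n_comp)

    # a component is band-valid when its boundary-crossing faces cross the
    # loop cylinder within +-half_length of the T0 boundary height (a sheet
    # that only projects into the loop, e.g. the opposite cheek or a scan
    # displaced beyond the sweep, is not cut by the ring)
    closed2d = np.vstack([loop2d, loop2d[:1]])
    seg_len = np.linalg.norm(np.diff(closed2d, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg_len)])
    closed_h = np.concatenate([loop_heights, loop_heights[:1]])
    mixed_idx = np.flatnonzero(mixed)
    # a mixed face either genuinely crosses the loop polygon (some vertex
    # projects outside it) or was cropped by the height-reach filter while
    # projecting fully inside the loop; the latter means surface content
    # inside the cylinder continues beyond the band
    poly_cross = np.zeros(len(mixed_idx), dtype=bool)
    if len(mixed_idx):
        poly_cross = (~raw_in[scan.faces[mixed_idx]]).any(axis=1)
        m2d = verts2d[scan.faces[mixed_idx]].mean(axis=1)
        mh = vh[scan.faces[mixed_idx]].mean(axis=1)
        s_m = np.array([exterior.project(shapely.Point(c)) for c in m2d])
        m_off = np.abs(mh - np.interp(s_m, arc, closed_h))
    comp_valid = np.ones(n_comp, dtype=bool)
    for ci in range(n_comp):
        if not len(mixed_idx):
            break
        in_c = comp[pos[mixed_idx]] == ci
        if (in_c & ~poly_cross).any():
            comp_valid[ci] = False  # reach-cropped content: beyond the band
        elif (in_c & poly_cross).any():
            comp_valid[ci] = bool(np.min(m_off[in_c & poly_cross])
                                  <= ring.half_length + 0.5)
    # a genuine cut reproduces the measured region; debris slivers smaller
    # than 5% of the loop's own projected area are not candidate cuts
    valid = comp_valid & (comp_areas >= 0.05 * poly.area)
    if not valid.any():
        raise ProjectionError(
            "scan crosses the boundary cylinder only beyond the sweep band "
            f"(half-length {ring.half_length} mm); no ring intersection")
    areas_valid = np.where(valid, comp_areas, 0.0)
    main = int(np.argmax(areas_valid))
    significant = valid & (comp_areas > 0.01 * comp_areas[main])
    if significant.sum() > 1:
        raise ProjectionError(
            "ambiguous cut: multiple surface components inside the loop, "
            f"areas (mm^2): {sorted(comp_areas[significant], reverse=True)}")
    keep_mask = np.zeros(len(scan.faces), dtype=bool)
    keep_mask[cand_idx[comp == main]] = True

    full_faces = scan.faces[full & keep_mask]
    mixed_idx = np.flatnonzero(mixed & keep_mask)

    new_vertices = [scan.vertices]
    new_faces = [full_faces]
    cut_points2d = []
    cut_points3d = []
    n_offset = len(scan.vertices)
    boundary_eps = 1e-9 * max(1.0, np.abs(loop2d).max())
    exterior = poly.exterior

    for fi in mixed_idx:
        f = scan.faces[fi]
        t2 = verts2d[f]
        t3 = scan.vertices[f]
        tri_poly = Polygon(t2)
        if not tri_poly.is_valid or tri_poly.area < 1e-14:
            continue  # edge-on to the projection; negligible contribution
        inter = tri_poly.intersection(poly)
        if inter.is_empty:
            continue
        geoms = (inter.geoms if inter.geom_type in ("MultiPolygon",
                                                    "GeometryCollection")
                 else [inter])
        for gpoly in geoms:
            if gpoly.geom_type != "Polygon" or gpoly.area < 1e-12:
                continue
            coords = np.array(gpoly.exterior.coords[:-1])
            lifted = _lift_2d(coords, t2, t3)
            if lifted is None:
                continue
            tris = _ear_clip(coords)
            if not tris:
                continue
            new_vertices.append(lifted)
            new_faces.append(np.array(tris, dtype=int) + n_offset)
            on_edge = np.array([exterior.distance(shapely.Point(c)) for c in coords])
            sel = on_edge < max(boundary_eps, 1e-7)
            if sel.any():
                cut_points2d.append(coords[sel])
                cut_points3d.append(lifted[sel])
            n_offset += len(coords)

    vertices = np.vstack(new_vertices)
    faces = np.vstack([f for f in new_faces if len(f)]) if new_faces else None
    if faces is None or len(faces) == 0:
        raise ProjectionError("cut produced no faces")

    # sweep-band check and ordered cut curve
    heights = vertices @ d
    loop_h = ring.loop @ d
    closed2d = np.vstack([loop2d, loop2d[:1]])
    seg_len = np.linalg.norm(np.diff(closed2d, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg_len)])
    closed_h = np.concatenate([loop_h, loop_h[:1]])
    boundary_idx = np.array([], dtype=int)
    if cut_points2d:
        cpts2d = np.vstack(cut_points2d)
        cpts3d = np.vstack(cut_points3d)
        s = np.array([exterior.project(shapely.Point(c)) for c in cpts2d])
        ref_h = np.interp(s, arc, closed_h)
        over = np.abs(cpts3d @ d - ref_h) - ring.half_length
        if np.any(over > 1e-6):
            raise ProjectionError(
                "scan crosses the boundary cylinder beyond the sweep band "
                f"(max overshoot {float(np.max(over)):.2f} mm past "
                f"half-length {ring.half_length} mm); no ring intersection")
        order = np.argsort(s)
        cpts3d = cpts3d[order]
        # deduplicate near-coincident curve samples
        if len(cpts3d):
            keep = np.ones(len(cpts3d), dtype=bool)
            dists = np.linalg.norm(np.diff(cpts3d, axis=0), axis=1)
            keep[1:] = dists > 1e-9
            cpts3d = cpts3d[keep]
        start = len(vertices)
        vertices = np.vstack([vertices, cpts3d])
        boundary_idx = np.arange(start, start + len(cpts3d))

    used = np.unique(np.concatenate([faces.ravel(), boundary_idx]))
    remap = -np.ones(len(vertices), dtype=int)
    remap[used] = np.arange(len(used))
    side = "R"  # caller overrides; sign handling lives in stv()
    try:
        return BuccalPatch(vertices=vertices[used], faces=remap[faces],
                           boundary=remap[boundary_idx] if len(boundary_idx)
                           else np.array([], dtype=int),
                           side=side, label=scan.label,
                           provenance={"cut": True,
                                       "half_length": ring.half_length})
    except RegionError as exc:
        raise ProjectionError(f"cut produced a degenerate patch: {exc}") from exc


def stv(patch: BuccalPatch, frame: SagittalFrame, side: str | None = None,
        mixed_sign_tolerance: float = 1e-3) -> VolumeResult:
    """Projected soft-tissue volume of a patch against the mid-sagittal plane.

    Signed-prism summation: sum over triangles of (signed centroid distance
    to the plane, positive on the patch's anatomical side) x (triangle area
    projected onto the plane). Patches crossing the plane by more than
    ``mixed_sign_tolerance`` of their area are rejected; smaller violations
    are clipped to zero height. 1 ml = 1000 mm^3.
    """
    side = side or patch.side
    sign = 1.0 if side == "R" else -1.0
    tri = patch.vertices[patch.faces]
    h = sign * np.asarray(frame.height(patch.vertices))
    h_c = h[patch.faces].mean(axis=1)

    p2 = frame.plane_coords(patch.vertices)
    t2 = p2[patch.faces]
    proj_area = 0.5 * np.abs(
        (t2[:, 1, 0] - t2[:, 0, 0]) * (t2[:, 2, 1] - t2[:, 0, 1])
        - (t2[:, 2, 0] - t2[:, 0, 0]) * (t2[:, 1, 1] - t2[:, 0, 1]))
    area3d = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)

    neg_area = float(area3d[h_c < 0].sum())
    total_area = float(area3d.sum())
    if total_area <= 0:
        raise ProjectionError("patch has zero area")
    if neg_area > mixed_sign_tolerance * total_area:
        raise ProjectionError(
            f"patch crosses the mid-sagittal plane ({neg_area / total_area:.2%} "
            f"of its area on the wrong side; tolerance "
            f"{mixed_sign_tolerance:.2%})")
    volume_mm3 = float(np.sum(np.maximum(h_c, 0.0) * proj_area))
    return VolumeResult(stv_ml=volume_mm3 / 1000.0, side=side,
                        timepoint=patch.label, area_mm2=total_area,
                        volume_mm3=volume_mm3,
                        qc={"clipped_area_fraction": neg_area / total_area})


def stvc(later: VolumeResult, earlier: VolumeResult) -> StvChange:
    """Soft-tissue volume change, later minus earlier (ml)."""
    if later.side != earlier.side:
        raise ProjectionError(
            f"side mismatch: {later.side} vs {earlier.side}")
    return StvChange(value_ml=later.stv_ml - earlier.stv_ml,
                     period=f"{later.timepoint}-{earlier.timepoint}",
                     side=later.side)
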
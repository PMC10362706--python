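"""Buccal-region division on the baseline scan.

The cheek region is outlined by surface polylines connecting the
soft-tissue landmarks: posterotragion (pt') to alare (al'), a nasal-side
closure al' to exocanthion (ex'), exocanthion to cheilion (ch'), cheilion
down to the chin foot point (cf', the perpendicular foot of ch' on the
mandibular lower border), and finally along the mandible border back to
pt'. The operator's freehand "draw" is formalized as shortest edge-walks
(Dijkstra with Euclidean edge weights) between the mesh vertices nearest
each landmark, which makes the boundary reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.spatial import cKDTree
from shapely.geometry import Polygon

from .mesh_io import LandmarkSet, SurfaceScan

__all__ = ["BoundaryPath", "BuccalPatch", "chin_footpoint", "surface_path",
           "extract_buccal", "RegionError"]


class RegionError(ValueError):
    """Boundary-loop or flood-fill failure."""


@dataclass
class BoundaryPath:
    """Ordered vertex indices forming an edge-walk between two landmarks."""

    indices: np.ndarray

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        if len(self.indices) < 2:
            raise RegionError("boundary path needs >= 2 vertices")

    def length(self, scan: SurfaceScan) -> float:
        pts = scan.vertices[self.indices]
        return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


@dataclass
class BuccalPatch:
    """One cheek sub-mesh with its closed ordered boundary loop.

    ``boundary`` indexes into ``vertices``; the loop is closed implicitly
    (last connects back to first). ``side`` is "L" or "R".
    """

    vertices: np.ndarray
    faces: np.ndarray
    boundary: np.ndarray
    side: str = "R"
    label: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=int)
        self.boundary = np.asarray(self.boundary, dtype=int)
        if self.area <= 0:
            raise RegionError("patch area must be positive")

    @property
    def boundary_coords(self) -> np.ndarray:
        return self.vertices[self.boundary]

    @property
    def area(self) -> float:
        tri = self.vertices[self.faces]
        return float(0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1).sum())

    def as_scan(self) -> SurfaceScan:
        return SurfaceScan(self.vertices.copy(), self.faces.copy(), self.label)

    def vertex_normals(self) -> np.ndarray:
        import trimesh
        return np.asarray(
            trimesh.Trimesh(self.vertices, self.faces, process=False).vertex_normals)


def chin_footpoint(ch: np.ndarray, mandible_border: np.ndarray) -> np.ndarray:
    """Foot of the perpendicular from ch' onto the piecewise-linear mandible
    lower border (closest point on the polyline; ends are clamped)."""
    border = np.asarray(mandible_border, dtype=float)
    ch = np.asarray(ch, dtype=float)
    if border.ndim != 2 or len(border) < 2:
        raise RegionError("mandible border needs >= 2 points")
    a = border[:-1]
    b = border[1:]
    ab = b - a
    denom = np.einsum("ij,ij->i", ab, ab)
    t = np.clip(np.einsum("ij,ij->i", ch - a, ab) / np.maximum(denom, 1e-300), 0, 1)
    feet = a + t[:, None] * ab
    d = np.linalg.norm(feet - ch, axis=1)
    return feet[np.argmin(d)]


def _edge_graph(scan: SurfaceScan):
    """Sparse undirected edge graph with Euclidean weights."""
    f = scan.faces
    edges = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    edges = np.sort(edges, axis=1)
    edges = np.unique(edges, axis=0)
    w = np.linalg.norm(scan.vertices[edges[:, 0]] - scan.vertices[edges[:, 1]], axis=1)
    n = len(scan.vertices)
    g = coo_matrix((np.concatenate([w, w]),
                    (np.concatenate([edges[:, 0], edges[:, 1]]),
                     np.concatenate([edges[:, 1], edges[:, 0]]))), shape=(n, n))
    return g.tocsr()


def _dijkstra_path(graph, src: int, dst: int) -> np.ndarray:
    dist, pred = dijkstra(graph, directed=False, indices=src,
                          return_predecessors=True)
    if not np.isfinite(dist[dst]):
        raise RegionError("no surface path between landmarks "
                          "(disconnected mesh components)")
    path = [dst]
    while path[-1] != src:
        path.append(int(pred[path[-1]]))
    return np.array(path[::-1], dtype=int)


def surface_path(scan: SurfaceScan, a: np.ndarray, b: np.ndarray,
                 _graph=None, _vtree=None) -> BoundaryPath:
    """Shortest edge-walk between the mesh vertices nearest ``a`` and ``b``."""
    graph = _graph if _graph is not None else _edge_graph(scan)
    vtree = _vtree if _vtree is not None else cKDTree(scan.vertices)
    ia = int(vtree.query(np.asarray(a, dtype=float))[1])
    ib = int(vtree.query(np.asarray(b, dtype=float))[1])
    if ia == ib:
        raise RegionError("landmarks map to the same mesh vertex")
    return BoundaryPath(_dijkstra_path(graph, ia, ib))


def _loop_plane_coords(points: np.ndarray) -> np.ndarray:
    """2D PCA coordinates of points in the loop's best-fit plane."""
    c = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - c, full_matrices=False)
    return (points - c) @ vt[:2].T


def _boundary_edge_set(scan: SurfaceScan):
    """Edges adjacent to exactly one face (the open border of the scan)."""
    f = scan.faces
    edges = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    edges = np.sort(edges, axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    return {tuple(e) for e in uniq[counts == 1]}


def extract_buccal(scan: SurfaceScan, landmarks: LandmarkSet, side: str = "R",
                   nasal_closure: bool = True) -> BuccalPatch:
    """Extract one buccal patch bounded by the landmark loop.

    The loop runs pt' -> al' [-> ex' if ``nasal_closure``] -> ch' -> cf' ->
    mandible border -> pt'. The enclosed sub-mesh is the flood fill of
    faces not crossing the loop, seeded at the face nearest the loop
    centroid on the inside.
    """
    required = ["pt'", "al'", "ch'"] + (["ex'"] if nasal_closure else [])
    for code in required:
        if not landmarks.has(code, side):
            raise RegionError(f"required landmark {code!r} missing for side {side}")
    border = landmarks.border(side)
    ch = landmarks.get("ch'", side)
    cf = (landmarks.get("cf'", side) if landmarks.has("cf'", side)
          else chin_footpoint(ch, border))

    # mandible-border points between cf' and the pt' end of the border
    pt = landmarks.get("pt'", side)
    seg_d = np.linalg.norm(border - cf, axis=1)
    near = int(np.argmin(seg_d))
    to_end = np.linalg.norm(border[-1] - pt)
    to_start = np.linalg.norm(border[0] - pt)
    if to_end <= to_start:
        border_run = [p for p in border[near:] if np.linalg.norm(p - cf) > 1e-9]
    else:
        border_run = [p for p in border[near::-1] if np.linalg.norm(p - cf) > 1e-9]

    waypoints = [pt, landmarks.get("al'", side)]
    if nasal_closure:
        waypoints.append(landmarks.get("ex'", side))
    waypoints += [ch, cf] + border_run

    graph = _edge_graph(scan)
    vtree = cKDTree(scan.vertices)
    # map waypoints to mesh vertices; nearby landmarks (e.g. cf' on top of a
    # border point) may snap to the same vertex and are deduplicated
    ids = [int(vtree.query(np.asarray(w, dtype=float))[1]) for w in waypoints]
    dedup = [ids[0]]
    for i in ids[1:]:
        if i != dedup[-1]:
            dedup.append(i)
    if len(dedup) > 1 and dedup[-1] == dedup[0]:
        dedup.pop()
    if len(dedup) < 3:
        raise RegionError("fewer than 3 distinct boundary waypoints")
    # route each segment on the graph minus vertices already used by earlier
    # segments, so the assembled loop is simple by construction (successive
    # geodesics may otherwise share staircase vertices near narrow corners)
    loop: list[int] = []
    used = np.zeros(len(scan.vertices), dtype=bool)
    n_vert = len(scan.vertices)
    for a, b in zip(dedup, dedup[1:] + [dedup[0]]):
        blocked = used.copy()
        blocked[[a, b]] = False
        allowed = np.flatnonzero(~blocked)
        sub = graph[allowed][:, allowed]
        remap = -np.ones(n_vert, dtype=int)
        remap[allowed] = np.arange(len(allowed))
        try:
            seg_sub = _dijkstra_path(sub, int(remap[a]), int(remap[b]))
        except RegionError:
            raise RegionError(
                "boundary loop failed to close: no simple surface path "
                "between consecutive landmarks") from None
        seg = allowed[seg_sub]
        loop.extend(seg[:-1].tolist())
        used[seg] = True
    loop_idx = np.array(loop, dtype=int)
    if len(loop_idx) < 3:
        raise RegionError("boundary loop failed to close")
    if len(np.unique(loop_idx)) != len(loop_idx):
        raise RegionError("boundary loop self-intersects (repeated vertex)")

    # flood fill over face adjacency, blocked at loop edges
    loop_edges = {tuple(sorted((int(loop_idx[i]), int(loop_idx[(i + 1) % len(loop_idx)]))))
                  for i in range(len(loop_idx))}
    mesh = scan.as_trimesh()
    adj = np.asarray(mesh.face_adjacency)
    adj_edges = np.sort(np.asarray(mesh.face_adjacency_edges), axis=1)
    blocked = np.array([tuple(e) in loop_edges for e in adj_edges])
    open_adj = adj[~blocked]
    n_faces = len(scan.faces)
    g = coo_matrix((np.ones(len(open_adj)),
                    (open_adj[:, 0], open_adj[:, 1])), shape=(n_faces, n_faces))
    _, comp = connected_components(g, directed=False)

    # seed: face whose centroid is nearest the loop centroid, restricted to
    # faces whose projection lies inside the loop polygon
    loop_pts = scan.vertices[loop_idx]
    centroid = loop_pts.mean(axis=0)
    c2 = _loop_plane_coords(np.vstack([loop_pts, scan.vertices[scan.faces].mean(axis=1)]))
    poly = Polygon(c2[: len(loop_pts)])
    if not poly.is_valid:
        poly = poly.buffer(0)
    face2d = c2[len(loop_pts):]
    inside = shapely.contains_xy(poly, face2d[:, 0], face2d[:, 1])
    if not inside.any():
        raise RegionError("no face projects inside the boundary loop")
    face_centroids = scan.vertices[scan.faces].mean(axis=1)
    d = np.linalg.norm(face_centroids - centroid, axis=1)
    d[~inside] = np.inf
    seed = int(np.argmin(d))

    patch_faces_mask = comp == comp[seed]
    patch_faces = scan.faces[patch_faces_mask]

    # leak check: the fill must not reach the open border of the scan
    scan_border = _boundary_edge_set(scan)
    leak_edges = scan_border - loop_edges
    if leak_edges:
        pf_edges = np.vstack([patch_faces[:, [0, 1]], patch_faces[:, [1, 2]],
                              patch_faces[:, [2, 0]]])
        pf_edges = {tuple(e) for e in np.sort(pf_edges, axis=1)}
        if pf_edges & leak_edges:
            raise RegionError("flood fill leaked to the scan border; "
                              "boundary loop does not enclose a region")

    used = np.unique(patch_faces)
    remap = -np.ones(len(scan.vertices), dtype=int)
    remap[used] = np.arange(len(used))
    if np.any(remap[loop_idx] < 0):
        raise RegionError("boundary loop vertices not contained in patch")
    return BuccalPatch(
        vertices=scan.vertices[used],
        faces=remap[patch_faces],
        boundary=remap[loop_idx],
        side=side,
        label=scan.label,
        provenance={"n_loop": int(len(loop_idx)), "nasal_closure": nasal_closure},
    )
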
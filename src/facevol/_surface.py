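"""Closest-point queries against a triangle mesh.

Candidate triangles are gathered from two KD-trees (triangle centroids and
mesh vertices); the exact closest point is then taken over the candidates
with a vectorized point-triangle projection. On the densely triangulated
scans this package works with, the candidate set always contains the true
nearest triangle.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

__all__ = ["closest_point_on_triangles", "SurfaceIndex"]


def closest_point_on_triangles(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Closest point on triangle ``triangles[i]`` to ``points[i]``, vectorized.

    Parameters
    ----------
    points : (n, 3) array
    triangles : (n, 3, 3) array of triangle vertices

    Returns
    -------
    (n, 3) array of closest points.

    Notes
    -----
    Region-based algorithm (Eberly): minimize the quadratic
    ``|B + s*E0 + t*E1 - P|^2`` over the barycentric domain
    ``s >= 0, t >= 0, s + t <= 1``.
    """
    p = np.asarray(points, dtype=float)
    tri = np.asarray(triangles, dtype=float)
    b = tri[:, 0]
    e0 = tri[:, 1] - b
    e1 = tri[:, 2] - b
    d = b - p

    a00 = np.einsum("ij,ij->i", e0, e0)
    a01 = np.einsum("ij,ij->i", e0, e1)
    a11 = np.einsum("ij,ij->i", e1, e1)
    b0 = np.einsum("ij,ij->i", e0, d)
    b1 = np.einsum("ij,ij->i", e1, d)

    det = np.maximum(a00 * a11 - a01 * a01, 0.0)
    s = a01 * b1 - a11 * b0
    t = a01 * b0 - a00 * b1

    eps = 1e-300
    with np.errstate(divide="ignore", invalid="ignore"):
        # interior solution
        inside = (s + t <= det) & (s >= 0) & (t >= 0) & (det > 0)
        inv_det = np.where(det > 0, 1.0 / np.maximum(det, eps), 0.0)
        s_in = s * inv_det
        t_in = t * inv_det

        # edge/vertex projections, clamped
        def _clamp01(x):
            return np.clip(x, 0.0, 1.0)

        # edge s (t = 0): minimize over s of f(s, 0)
        s_e0 = _clamp01(np.where(a00 > 0, -b0 / np.maximum(a00, eps), 0.0))
        # edge t (s = 0)
        t_e1 = _clamp01(np.where(a11 > 0, -b1 / np.maximum(a11, eps), 0.0))
        # hypotenuse edge (s + t = 1): param u along it
        num = a11 + b1 - a01 - b0
        den = a00 - 2.0 * a01 + a11
        u_h = _clamp01(np.where(den > 0, num / np.maximum(den, eps), 0.0))

    def _cost(ss, tt):
        q = b + ss[:, None] * e0 + tt[:, None] * e1 - p
        return np.einsum("ij,ij->i", q, q)

    cand_s = np.stack([np.where(inside, s_in, 0.0), s_e0, np.zeros_like(s_e0), u_h])
    cand_t = np.stack([np.where(inside, t_in, 0.0), np.zeros_like(t_e1), t_e1, 1.0 - u_h])
    costs = np.stack([
        np.where(inside, _cost(cand_s[0], cand_t[0]), np.inf),
        _cost(cand_s[1], cand_t[1]),
        _cost(cand_s[2], cand_t[2]),
        _cost(cand_s[3], cand_t[3]),
    ])
    best = np.argmin(costs, axis=0)
    idx = np.arange(p.shape[0])
    s_best = cand_s[best, idx]
    t_best = cand_t[best, idx]
    return b + s_best[:, None] * e0 + t_best[:, None] * e1


class SurfaceIndex:
    """Spatial index answering closest-point-on-surface queries.

    Parameters
    ----------
    vertices, faces : mesh arrays, float (n,3) / int (m,3)
    k_centroids, k_vertices : number of KD-tree candidates merged per query.
    """

    def __init__(self, vertices: np.ndarray, faces: np.ndarray,
                 k_centroids: int = 8, k_vertices: int = 6):
        self.vertices = np.asarray(vertices, dtype=float)
        self.faces = np.asarray(faces, dtype=int)
        self.triangles = self.vertices[self.faces]
        self._centroids = self.triangles.mean(axis=1)
        self._ctree = cKDTree(self._centroids)
        self._vtree = cKDTree(self.vertices)
        self._k_c = min(k_centroids, len(self.faces))
        self._k_v = min(k_vertices, len(self.vertices))
        # faces incident to each vertex (ragged, stored flat)
        order = np.argsort(self.faces.ravel(), kind="stable")
        self._incident_faces = np.repeat(np.arange(len(self.faces)), 3)[order]
        counts = np.bincount(self.faces.ravel(), minlength=len(self.vertices))
        self._incident_start = np.concatenate([[0], np.cumsum(counts)])
        e1 = self.triangles[:, 1] - self.triangles[:, 0]
        e2 = self.triangles[:, 2] - self.triangles[:, 0]
        n = np.cross(e1, e2)
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        self.face_normals = n / np.maximum(norm, 1e-300)

    def _candidates(self, points: np.ndarray) -> np.ndarray:
        _, cf = self._ctree.query(points, k=self._k_c)
        cf = np.atleast_2d(cf)
        _, vv = self._vtree.query(points, k=self._k_v)
        vv = np.atleast_2d(vv)
        out = []
        for i in range(points.shape[0]):
            vfaces = [
                self._incident_faces[self._incident_start[v]:self._incident_start[v + 1]]
                for v in np.atleast_1d(vv[i])
            ]
            out.append(np.unique(np.concatenate([np.atleast_1d(cf[i])] + vfaces)))
        return out

    def query(self, points: np.ndarray):
        """Closest surface points for ``points``.

        Returns
        -------
        closest : (n, 3) closest points on the surface
        dist : (n,) unsigned distances
        face : (n,) index of the triangle realizing the minimum
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        cands = self._candidates(pts)
        lengths = np.array([len(c) for c in cands])
        flat_faces = np.concatenate(cands)
        flat_pts = np.repeat(pts, lengths, axis=0)
        cp = closest_point_on_triangles(flat_pts, self.triangles[flat_faces])
        d2 = np.einsum("ij,ij->i", cp - flat_pts, cp - flat_pts)
        starts = np.concatenate([[0], np.cumsum(lengths)])
        closest = np.empty_like(pts)
        dist = np.empty(len(pts))
        face = np.empty(len(pts), dtype=int)
        for i in range(len(pts)):
            sl = slice(starts[i], starts[i + 1])
            j = int(np.argmin(d2[sl]))
            closest[i] = cp[sl][j]
            dist[i] = np.sqrt(d2[sl][j])
            face[i] = flat_faces[sl][j]
        return closest, dist, face
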
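"""Rigid alignment of follow-up scans to the baseline scan.

T0 is the fixed scan; T1/T2 are floated onto it with iterative closest
point restricted to the upper third of the face, which is assumed stable
over the follow-up (the measured cheek region is excluded from the
registration support). The ICP variant is point-to-plane with uniform
vertex subsampling and a small-angle Gauss-Newton update per iteration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation

from ._surface import SurfaceIndex
from .mesh_io import SurfaceScan
from .sagittal_frame import SagittalFrame

__all__ = ["RigidTransform", "crop_upper_third", "icp_register", "apply_transform"]


@dataclass
class RigidTransform:
    """Proper rigid motion ``x -> R x + t`` (rotation then translation)."""

    rotation: np.ndarray
    translation: np.ndarray
    converged: bool = True
    rms: float = float("nan")
    n_iter: int = 0

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        det = np.linalg.det(self.rotation)
        if abs(det - 1.0) > 1e-9:
            raise ValueError(f"rotation determinant {det} != +1")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation matrix is not orthonormal")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_rotvec_deg(cls, rotvec_deg, translation) -> "RigidTransform":
        r = Rotation.from_rotvec(np.asarray(rotvec_deg, dtype=float),
                                 degrees=True).as_matrix()
        return cls(r, translation)

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Composition ``self * other``: apply ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    @property
    def angle_deg(self) -> float:
        """Rotation magnitude in degrees."""
        return float(np.degrees(np.linalg.norm(
            Rotation.from_matrix(self.rotation).as_rotvec())))

    # serialization as 4x4 homogeneous matrix ----------------------------
    def to_matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m) -> "RigidTransform":
        m = np.asarray(m, dtype=float).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3])

    def save(self, path):
        Path(path).write_text(json.dumps({"matrix": self.to_matrix().tolist()},
                                         indent=2))

    @classmethod
    def load(cls, path) -> "RigidTransform":
        return cls.from_matrix(np.array(json.loads(Path(path).read_text())["matrix"]))


def crop_upper_third(scan: SurfaceScan, frame: SagittalFrame,
                     upper_fraction: float = 1.0 / 3.0) -> SurfaceScan:
    """Sub-mesh above the ``(1 - upper_fraction)`` quantile of the scan's
    height range along the frame's vertical axis. Faces are kept only when
    all three vertices survive."""
    if not 0.0 < upper_fraction < 1.0:
        raise ValueError("upper_fraction must be in (0, 1)")
    v = frame.vertical_coord(scan.vertices)
    v = np.atleast_1d(v)
    threshold = v.min() + (1.0 - upper_fraction) * (v.max() - v.min())
    keep = v > threshold
    face_keep = keep[scan.faces].all(axis=1)
    if not face_keep.any():
        raise ValueError("upper-third crop is empty")
    used = np.unique(scan.faces[face_keep])
    remap = -np.ones(len(scan.vertices), dtype=int)
    remap[used] = np.arange(len(used))
    return SurfaceScan(scan.vertices[used], remap[scan.faces[face_keep]],
                       label=f"{scan.label}:upper")


def apply_transform(scan: SurfaceScan, t: RigidTransform) -> SurfaceScan:
    """Map every vertex through ``t``; topology unchanged."""
    return SurfaceScan(t.apply(scan.vertices), scan.faces.copy(), scan.label)


def icp_register(floating: SurfaceScan, fixed_region: SurfaceScan,
                 max_iter: int = 100, tol: float = 1e-4,
                 samples: int = 5000, seed: int = 0,
                 init: RigidTransform | None = None) -> RigidTransform:
    """Point-to-plane ICP of ``floating`` onto ``fixed_region``.

    Uniformly subsamples ``samples`` floating vertices (seeded, without
    replacement, no trimming) and iterates closest-point correspondence
    against the fixed surface with a linearized rigid update. Iteration
    stops when the RMS point-to-plane residual improves by less than
    ``tol`` mm, or after ``max_iter`` iterations (then ``converged`` is
    False on the returned transform).

    Floating samples are restricted to the axis-aligned bounding box of the
    fixed region (padded by 10%), so only the overlapping part of the face
    drives the registration.
    """
    if len(floating.vertices) == 0 or len(fixed_region.vertices) == 0:
        raise ValueError("empty mesh passed to icp_register")
    index = SurfaceIndex(fixed_region.vertices, fixed_region.faces)

    # faces on the open border of the fixed region: correspondences landing
    # there belong to floating points outside the region and would bias the
    # fit, so they are rejected (border rejection, not distance trimming)
    ff = fixed_region.faces
    edges = np.sort(np.vstack([ff[:, [0, 1]], ff[:, [1, 2]], ff[:, [2, 0]]]), axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    border_vertices = np.zeros(len(fixed_region.vertices), dtype=bool)
    border_vertices[np.unique(uniq[counts == 1])] = True
    border_face = border_vertices[ff].any(axis=1)

    pts = floating.vertices
    lo = fixed_region.vertices.min(axis=0)
    hi = fixed_region.vertices.max(axis=0)
    # generous pad: initial misalignments of ~10 mm must keep the true
    # overlap inside the sample box (off-region samples are border-rejected)
    pad = 0.10 * (hi - lo) + 10.0
    in_box = np.all((pts >= lo - pad) & (pts <= hi + pad), axis=1)
    if in_box.sum() >= 100:
        pts = pts[in_box]
    rng = np.random.default_rng(seed)
    if len(pts) > samples:
        pts = pts[rng.choice(len(pts), size=samples, replace=False)]

    if init is None:
        # coarse initialization: align the centroid of the in-box floating
        # samples with the fixed-region centroid (pure translation)
        init = RigidTransform(np.eye(3),
                              fixed_region.vertices.mean(axis=0) - pts.mean(axis=0))
    t = init
    r, trans = t.rotation.copy(), t.translation.copy()
    prev_rms = np.inf
    last_step = np.inf
    converged = False
    rms = np.inf
    it = 0
    radius = float(np.linalg.norm(pts - pts.mean(axis=0), axis=1).max())
    for it in range(1, max_iter + 1):
        moved = pts @ r.T + trans
        closest, _, fidx = index.query(moved)
        keep = ~border_face[fidx]
        if keep.sum() < 10:
            raise ValueError("registration support too small: nearly all "
                             "correspondences fall on the fixed-region border")
        moved_k, closest_k = moved[keep], closest[keep]
        normals = index.face_normals[fidx[keep]]
        resid = np.einsum("ij,ij->i", moved_k - closest_k, normals)
        rms = float(np.sqrt(np.mean(resid ** 2)))
        # converge on a small RMS improvement only once the rigid update
        # itself has stalled (guards against transient correspondence
        # plateaus far from the optimum)
        if abs(prev_rms - rms) < tol and last_step < tol:
            converged = True
            break
        prev_rms = rms
        # linearized point-to-plane system in (omega, dt), solved about the
        # correspondence centroid for conditioning (rotation and translation
        # decouple there)
        cen = moved_k.mean(axis=0)
        a = np.hstack([np.cross(moved_k - cen, normals), normals])
        sol, *_ = np.linalg.lstsq(a, -resid, rcond=None)
        omega, dt = sol[:3], sol[3:]
        # trust region: cap the per-iteration motion at the sample cloud
        step = float(np.linalg.norm(dt) + np.linalg.norm(omega) * radius)
        max_step = 20.0
        if step > max_step:
            scale = max_step / step
            omega, dt = omega * scale, dt * scale
            step = max_step
        last_step = step
        dr = Rotation.from_rotvec(omega).as_matrix()
        r = dr @ r
        trans = dr @ (trans - cen) + cen + dt
        # re-orthonormalize against drift
        u, _, vt = np.linalg.svd(r)
        r = u @ vt

    return RigidTransform(r, trans, converged=converged, rms=rms, n_iter=it)
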
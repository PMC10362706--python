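"""Surface deviation analysis between corresponding patches.

For every vertex of the reference patch the signed closest-point distance
to the test surface is computed (positive when the test surface lies along
the reference outward normal, i.e. outside). Summaries use the population
formulas

    mu  = (1/N) sum X_i
    SD  = sqrt((1/N) sum (X_i - mu)^2)
    RMS = sqrt((1/N) sum X_i^2)

so that RMS^2 = mu^2 + SD^2 holds as an algebraic identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ._surface import SurfaceIndex

__all__ = ["DeviationResult", "compare", "write_distance_csv",
           "write_colormap_obj"]

#: correspondences farther than this are treated as spurious and excluded
DEFAULT_MAX_DIST = 10.0


@dataclass
class DeviationResult:
    distances: np.ndarray
    mu: float
    sd: float
    rms: float
    n: int
    kept: np.ndarray | None = None  # reference-vertex indices behind distances


def _as_mesh_arrays(obj):
    return np.asarray(obj.vertices, dtype=float), np.asarray(obj.faces, dtype=int)


def compare(reference, test, max_dist: float = DEFAULT_MAX_DIST) -> DeviationResult:
    """Signed closest-point distances from ``reference`` vertices to the
    ``test`` surface, with the mu/SD/RMS summaries.

    Accepts any mesh-like object exposing ``vertices`` and ``faces``
    (:class:`~facevol.region.BuccalPatch` or
    :class:`~facevol.mesh_io.SurfaceScan`). Correspondences with
    ``|X_i| > max_dist`` are excluded from N.
    """
    rv, rf = _as_mesh_arrays(reference)
    tv, tf = _as_mesh_arrays(test)

    import trimesh
    normals = np.asarray(trimesh.Trimesh(rv, rf, process=False).vertex_normals)

    index = SurfaceIndex(tv, tf)
    closest, dist, _ = index.query(rv)
    signs = np.sign(np.einsum("ij,ij->i", closest - rv, normals))
    signs[signs == 0] = 1.0
    x = signs * dist

    keep = np.abs(x) <= max_dist
    kept = np.flatnonzero(keep)
    x = x[keep]
    if len(x) == 0:
        raise ValueError("no correspondences within max_dist; "
                         "surfaces do not overlap")
    mu = float(np.mean(x))
    sd = float(np.sqrt(np.mean((x - mu) ** 2)))
    rms = float(np.sqrt(np.mean(x ** 2)))
    return DeviationResult(distances=x, mu=mu, sd=sd, rms=rms, n=int(len(x)),
                           kept=kept)


def write_distance_csv(path, reference, result: DeviationResult) -> None:
    """Per-vertex signed distances next to the reference coordinates."""
    rv, _ = _as_mesh_arrays(reference)
    idx = result.kept if result.kept is not None else np.arange(len(result.distances))
    with open(Path(path), "w") as fh:
        fh.write("x,y,z,signed_distance_mm\n")
        for i, d in zip(idx, result.distances):
            p = rv[i]
            fh.write(f"{p[0]:.6f},{p[1]:.6f},{p[2]:.6f},{d:.6f}\n")


def write_colormap_obj(path, reference, result: DeviationResult,
                       vmax: float | None = None) -> None:
    """Distance-map export: reference mesh with per-vertex colors encoding
    the signed distance (blue = inward, red = outward)."""
    rv, rf = _as_mesh_arrays(reference)
    d = np.zeros(len(rv))
    idx = result.kept if result.kept is not None else np.arange(len(result.distances))
    d[idx] = result.distances
    scale = vmax if vmax is not None else max(float(np.abs(d).max()), 1e-9)
    t = np.clip(d / scale, -1.0, 1.0)
    red = np.clip(t, 0, 1)
    blue = np.clip(-t, 0, 1)
    green = 1.0 - np.abs(t)
    with open(Path(path), "w") as fh:
        fh.write("# signed-distance color map\n")
        for p, r, g, b in zip(rv, red, green, blue):
            fh.write(f"v {p[0]:.6f} {p[1]:.6f} {p[2]:.6f} "
                     f"{r:.4f} {g:.4f} {b:.4f}\n")
        for f in rf:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")
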
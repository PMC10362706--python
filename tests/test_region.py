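"""Buccal-region division: footpoint, surface paths, patch extraction."""

import numpy as np
import pytest

from facevol.mesh_io import SurfaceScan
from facevol.region import (RegionError, chin_footpoint, extract_buccal,
                            surface_path)


# -- chin footpoint ---------------------------------------------------------

def test_footpoint_axis_aligned():
    border = np.array([[-5, 0, 0], [5, 0, 0]], dtype=float)
    assert np.allclose(chin_footpoint(np.array([0.0, 10.0, 0.0]), border),
                       [0, 0, 0])


def test_footpoint_clamps_to_segment_end():
    border = np.array([[0, 0, 0], [5, 0, 0]], dtype=float)
    assert np.allclose(chin_footpoint(np.array([9.0, 3.0, 0.0]), border),
                       [5, 0, 0])


def test_footpoint_matches_dense_sampling_oracle():
    rng = np.random.default_rng(7)
    border = np.cumsum(rng.uniform(-2, 2, size=(8, 3)), axis=0)
    ch = rng.uniform(-3, 3, 3)
    foot = chin_footpoint(ch, border)
    # oracle: densely sample every border segment
    samples = []
    for a, b in zip(border[:-1], border[1:]):
        w = np.linspace(0, 1, 20001)[:, None]
        samples.append(a * (1 - w) + b * w)
    samples = np.vstack(samples)
    d_oracle = np.linalg.norm(samples - ch, axis=1).min()
    assert abs(np.linalg.norm(foot - ch) - d_oracle) < 1e-6


def test_footpoint_empty_border_error():
    with pytest.raises(RegionError):
        chin_footpoint(np.zeros(3), np.zeros((1, 3)))


# -- surface paths ----------------------------------------------------------

def _flat_grid(n=12, spacing=1.0):
    xs = np.arange(n) * spacing
    xx, yy = np.meshgrid(xs, xs, indexing="ij")
    v = np.column_stack([xx.ravel(), yy.ravel(), np.zeros(xx.size)])
    i, j = np.meshgrid(np.arange(n - 1), np.arange(n - 1), indexing="ij")
    v00 = (i * n + j).ravel()
    f = np.vstack([np.column_stack([v00, v00 + n, v00 + n + 1]),
                   np.column_stack([v00, v00 + n + 1, v00 + 1])])
    return SurfaceScan(v, f)


def test_path_same_row_is_straight():
    scan = _flat_grid()
    path = surface_path(scan, np.array([0.0, 3.0, 0.0]),
                        np.array([11.0, 3.0, 0.0]))
    pts = scan.vertices[path.indices]
    assert np.allclose(pts[:, 1], 3.0)
    assert len(path.indices) == 12


def test_path_length_at_least_euclidean():
    scan = _flat_grid()
    a = np.array([0.0, 0.0, 0.0])
    b = np.array([11.0, 7.0, 0.0])
    path = surface_path(scan, a, b)
    assert path.length(scan) >= np.linalg.norm(a - b) - 1e-12


def test_path_cost_matches_networkx_oracle():
    """Independent shortest-path implementation on the same edge graph."""
    import networkx as nx
    rng = np.random.default_rng(5)
    scan = _flat_grid(10)
    # perturb heights so edge weights are non-trivial
    v = scan.vertices.copy()
    v[:, 2] = rng.uniform(0, 0.8, len(v))
    scan = SurfaceScan(v, scan.faces)
    a, b = scan.vertices[3], scan.vertices[-4]
    path = surface_path(scan, a, b)

    g = nx.Graph()
    edges = np.vstack([scan.faces[:, [0, 1]], scan.faces[:, [1, 2]],
                       scan.faces[:, [2, 0]]])
    for e in np.unique(np.sort(edges, axis=1), axis=0):
        w = np.linalg.norm(scan.vertices[e[0]] - scan.vertices[e[1]])
        g.add_edge(int(e[0]), int(e[1]), weight=w)
    oracle = nx.shortest_path_length(g, 3, len(v) - 4, weight="weight")
    assert abs(path.length(scan) - oracle) < 1e-9


def test_disconnected_mesh_no_path():
    scan = _flat_grid(6)
    far = SurfaceScan(scan.vertices + np.array([100.0, 0, 0]), scan.faces)
    combined = SurfaceScan(np.vstack([scan.vertices, far.vertices]),
                           np.vstack([scan.faces,
                                      far.faces + len(scan.vertices)]))
    with pytest.raises(RegionError, match="no surface path"):
        surface_path(combined, scan.vertices[0], far.vertices[0] + 100)


# -- buccal extraction ------------------------------------------------------

def test_extract_buccal_matches_param_classification_oracle(face_series, t0):
    """Patch face set equals brute-force point-in-loop classification in the
    phantom's (y, z) parameter plane (independent of the shapely seed test
    used internally)."""
    from matplotlib.path import Path as MplPath

    patch = extract_buccal(t0, face_series.landmarks, side="R")
    loop_yz = patch.boundary_coords[:, [1, 2]]
    poly = MplPath(loop_yz)
    cents = t0.vertices[t0.faces].mean(axis=1)[:, [1, 2]]
    inside = poly.contains_points(cents)
    assert abs(inside.sum() - len(patch.faces)) <= 2  # boundary-grazing faces
    # every patch face centroid is inside the loop polygon
    pc = patch.vertices[patch.faces].mean(axis=1)[:, [1, 2]]
    assert poly.contains_points(pc, radius=1e-9).mean() > 0.999


def test_patch_invariants(face_series, t0):
    patch = extract_buccal(t0, face_series.landmarks, side="R")
    assert 0 < patch.area < t0.area
    # boundary vertices all belong to the patch and form a closed cycle of
    # mesh edges
    bc = patch.boundary
    assert len(np.unique(bc)) == len(bc)
    edges = {tuple(sorted(e)) for e in
             np.vstack([patch.faces[:, [0, 1]], patch.faces[:, [1, 2]],
                        patch.faces[:, [2, 0]]])}
    for a, b in zip(bc, np.roll(bc, -1)):
        assert tuple(sorted((int(a), int(b)))) in edges


def test_extract_is_deterministic(face_series, t0):
    p1 = extract_buccal(t0, face_series.landmarks, side="R")
    p2 = extract_buccal(t0, face_series.landmarks, side="R")
    assert np.array_equal(p1.faces, p2.faces)
    assert np.array_equal(p1.boundary, p2.boundary)


def test_left_side_extraction(face_series, t0):
    patch = extract_buccal(t0, face_series.landmarks, side="L")
    assert patch.side == "L"
    assert patch.vertices[:, 1].max() < 0  # left cheek is y < 0


def test_missing_landmark_error(face_series, t0):
    import copy
    lm = copy.deepcopy(face_series.landmarks)
    del lm.points["R"]["al'"]
    with pytest.raises(RegionError, match="al'"):
        extract_buccal(t0, lm, side="R")


def test_loop_covering_whole_mesh_boundary_returns_whole_mesh(face_series):
    """Limit case: landmarks at the corners of an open sheet make the loop
    the full mesh border, so the patch is the whole mesh."""
    from facevol.mesh_io import LandmarkSet
    from facevol.synthetic import grid_patch

    scan = grid_patch("plane", size=(20.0, 20.0), resolution=1.0).as_scan()
    lo, hi = -10.0, 10.0
    lm = LandmarkSet()
    lm.points["R"] = {
        "pt'": np.array([hi, 20.0, hi]),   # top-right corner
        "al'": np.array([lo, 20.0, hi]),   # top-left
        "ch'": np.array([lo, 20.0, lo]),   # bottom-left
    }
    lm.mandible["R"] = np.array([[lo, 20.0, lo], [hi, 20.0, lo]])
    patch = extract_buccal(scan, lm, side="R", nasal_closure=False)
    assert len(patch.faces) == len(scan.faces)
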
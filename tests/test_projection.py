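"""Ring extrusion, Boolean cut, projected volume (STV/STVC)."""

import numpy as np
import pytest
from scipy import integrate

from facevol.projection import (ProjectionError, boolean_cut, extrude_ring,
                                stv, stvc)
from facevol.region import extract_buccal
from facevol.registration import RigidTransform, apply_transform
from facevol.synthetic import GaussianBump, canonical_frame, grid_patch

FRAME = canonical_frame()
EY = np.array([0.0, 1.0, 0.0])


# -- extrude_ring -----------------------------------------------------------

def test_square_loop_ring_area():
    """Perimeter-80 square swept +-10 mm -> developable band of 1600 mm^2."""
    loop = np.array([[0, 0, 0], [20, 0, 0], [20, 0, 20], [0, 0, 20]],
                    dtype=float)
    ring = extrude_ring(loop, EY, 10.0)
    tri = ring.vertices[ring.faces]
    area = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1).sum()
    assert area == pytest.approx(80 * 20, rel=1e-12)


def test_zero_half_length_rejected():
    loop = np.array([[0, 0, 0], [1, 0, 0], [1, 0, 1]], dtype=float)
    with pytest.raises(ProjectionError, match="half-length"):
        extrude_ring(loop, EY, 0.0)


def test_ring_vertex_decomposition():
    """Every ring vertex is boundary + s * direction with |s| <= 10."""
    patch = grid_patch("spherical-cap", size=(30, 30), resolution=1.5)
    ring = extrude_ring(patch, EY, 10.0)
    loop = patch.boundary_coords
    n = len(loop)
    for k, rv in enumerate(ring.vertices):
        b = loop[k % n]
        s = np.dot(rv - b, EY)
        assert abs(s) <= 10.0 + 1e-9
        assert np.linalg.norm(rv - b - s * EY) < 1e-9


def test_ring_has_two_open_boundary_loops():
    loop = np.array([[0, 0, 0], [20, 0, 0], [20, 0, 20], [0, 0, 20]],
                    dtype=float)
    ring = extrude_ring(loop, EY, 10.0)
    f = ring.faces
    edges = np.sort(np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]]),
                    axis=1)
    uniq, counts = np.unique(edges, axis=0, return_counts=True)
    border = uniq[counts == 1]
    # two parallel edge loops, each with as many edges as loop vertices
    assert len(border) == 2 * len(loop)


# -- stv --------------------------------------------------------------------

def test_prism_law_planar_square():
    """20 x 20 mm plane at 30 mm -> exactly 12 ml."""
    patch = grid_patch("plane", size=(20, 20), distance=30.0, resolution=1.0)
    result = stv(patch, FRAME)
    assert result.stv_ml == pytest.approx(12.0, abs=1e-12)


def test_patch_in_plane_zero_volume():
    patch = grid_patch("plane", size=(15, 15), distance=0.0, resolution=1.0)
    assert stv(patch, FRAME).stv_ml == pytest.approx(0.0, abs=1e-15)


def test_prism_law_random_planar_patches():
    rng = np.random.default_rng(2)
    for _ in range(5):
        sx, sz = rng.uniform(5, 40, 2)
        d = rng.uniform(1, 60)
        patch = grid_patch("plane", size=(sx, sz), distance=d, resolution=1.3)
        area2d = (np.ptp(patch.vertices[:, 0])) * (np.ptp(patch.vertices[:, 2]))
        assert stv(patch, FRAME).volume_mm3 == pytest.approx(area2d * d,
                                                             rel=1e-10)


def test_spherical_cap_matches_quadrature_oracle():
    """Signed-prism sum vs adaptive 2D quadrature of the analytic surface."""
    r, d, s = 60.0, 25.0, 30.0
    patch = grid_patch("spherical-cap", size=(s, s), distance=d,
                       resolution=0.4, radius=r)
    result = stv(patch, FRAME)
    oracle, err = integrate.dblquad(
        lambda z, x: d + np.sqrt(r * r - x * x - z * z) - r,
        -s / 2, s / 2, -s / 2, s / 2, epsabs=1e-9)
    assert result.volume_mm3 == pytest.approx(oracle, rel=2e-3)


def test_stv_additive_over_face_partition():
    from facevol.region import BuccalPatch
    patch = grid_patch("spherical-cap", size=(20, 20), resolution=1.0)
    half = len(patch.faces) // 2
    parts = []
    for faces in (patch.faces[:half], patch.faces[half:]):
        parts.append(BuccalPatch(vertices=patch.vertices, faces=faces,
                                 boundary=patch.boundary, side="R"))
    total = stv(patch, FRAME).volume_mm3
    assert total == pytest.approx(
        sum(stv(p, FRAME).volume_mm3 for p in parts), rel=1e-12)


def test_left_side_patch_positive_volume():
    patch = grid_patch("plane", size=(10, 10), distance=20.0, side="L")
    result = stv(patch, FRAME)
    assert result.stv_ml == pytest.approx(2.0, abs=1e-12)


def test_mixed_sign_patch_rejected():
    patch = grid_patch("plane", size=(10, 10), distance=20.0)
    v = patch.vertices.copy()
    v[: len(v) // 2, 1] *= -1  # fold half the patch across the plane
    patch.vertices = v
    with pytest.raises(ProjectionError, match="crosses the mid-sagittal"):
        stv(patch, FRAME)


# -- stvc -------------------------------------------------------------------

def test_stvc_identical_patches_zero():
    patch = grid_patch("plane", size=(12, 12), distance=25.0)
    a = stv(patch, FRAME)
    assert float(stvc(a, a)) == 0.0


def test_stvc_antisymmetry_and_labels():
    p0 = grid_patch("plane", size=(12, 12), distance=25.0)
    p1 = grid_patch("plane", size=(12, 12), distance=26.0)
    p0.label, p1.label = "T0", "T1"
    a, b = stv(p0, FRAME), stv(p1, FRAME)
    fwd, rev = stvc(b, a), stvc(a, b)
    assert float(fwd) == pytest.approx(-float(rev), abs=1e-15)
    assert fwd.period == "T1-T0"


def test_stvc_side_mismatch_rejected():
    r = stv(grid_patch("plane", size=(10, 10), distance=5.0, side="R"), FRAME)
    lft = stv(grid_patch("plane", size=(10, 10), distance=5.0, side="L"),
              FRAME)
    with pytest.raises(ProjectionError, match="side"):
        stvc(r, lft)


def test_gaussian_bump_adds_analytic_volume():
    """STVC between bumped and plain patches = 2 pi A sigma^2 within 2%."""
    a_mm, s_mm = 2.0, 6.0
    base = grid_patch("spherical-cap", size=(60, 60), resolution=1.0)
    bumped = grid_patch("spherical-cap", size=(60, 60), resolution=1.0,
                        bumps=(GaussianBump(center=(0.0, 0.0),
                                            amplitude=a_mm, sigma=s_mm),))
    base.label, bumped.label = "T0", "T1"
    change = stvc(stv(bumped, FRAME), stv(base, FRAME))
    truth = 2 * np.pi * a_mm * s_mm ** 2
    assert float(change) * 1000 == pytest.approx(truth, rel=0.02)


# -- boolean_cut ------------------------------------------------------------

@pytest.fixture(scope="module")
def cut_setup(face_series, t0, frame):
    patch0 = extract_buccal(t0, face_series.landmarks, side="R")
    ring = extrude_ring(patch0, frame.projection_direction, 10.0)
    return patch0, ring


def test_self_cut_recovers_patch_area(cut_setup, t0):
    patch0, ring = cut_setup
    cut = boolean_cut(ring, t0)
    assert cut.area == pytest.approx(patch0.area, rel=1e-3)


def test_cut_invariant_under_sweep_translation(cut_setup, t0, frame):
    patch0, ring = cut_setup
    moved = apply_transform(t0, RigidTransform(
        np.eye(3), frame.projection_direction * 1.0))
    cut = boolean_cut(ring, moved)
    assert cut.area == pytest.approx(patch0.area, rel=5e-3)


def test_cut_beyond_band_errors(cut_setup, t0, frame):
    _, ring = cut_setup
    moved = apply_transform(t0, RigidTransform(
        np.eye(3), frame.projection_direction * 15.0))
    with pytest.raises(ProjectionError, match="no ring intersection"):
        boolean_cut(ring, moved)


def test_cut_missing_scan_errors(cut_setup, t0):
    _, ring = cut_setup
    far = apply_transform(t0, RigidTransform(np.eye(3),
                                             np.array([0.0, 0.0, 500.0])))
    with pytest.raises(ProjectionError):
        boolean_cut(ring, far)
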
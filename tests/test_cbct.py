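"""CBCT pipeline: DICOM I/O, alignment, segmentation, voxel counting."""

import shutil

import numpy as np
import pytest

from facevol.cbct import (CbctError, RoiMask, SelectionBox, VoxelVolume,
                          align_jaw, htvc, load_dicom, mask_subtract,
                          threshold_segment, write_dicom)
from facevol.registration import RigidTransform
from facevol.synthetic import CbctPhantomSpec, ToothBlob, make_cbct_series


def _vol(data, spacing=(0.5, 0.5, 0.5)):
    return VoxelVolume(np.asarray(data), spacing)


# -- DICOM ------------------------------------------------------------------

def test_dicom_round_trip_identical(tmp_path):
    rng = np.random.default_rng(0)
    data = rng.integers(-500, 3000, size=(24, 20, 16)).astype(np.int16)
    vol = VoxelVolume(data, (0.4, 0.4, 0.4))
    write_dicom(vol, tmp_path / "s")
    back = load_dicom(tmp_path / "s")
    assert np.array_equal(back.data, data)


def test_anisotropic_spacing_preserved(tmp_path):
    vol = VoxelVolume(np.zeros((10, 12, 14), dtype=np.int16),
                      (0.25, 0.25, 0.5))
    write_dicom(vol, tmp_path / "s")
    back = load_dicom(tmp_path / "s")
    assert back.spacing == pytest.approx((0.25, 0.25, 0.5))


def test_shuffled_slice_order_reconstructed(tmp_path):
    """File order on disk must not matter: position-sorted reconstruction."""
    rng = np.random.default_rng(1)
    data = rng.integers(0, 1000, size=(16, 8, 8)).astype(np.int16)
    vol = VoxelVolume(data, (0.5, 0.5, 0.5))
    src = tmp_path / "ordered"
    write_dicom(vol, src)
    shuffled = tmp_path / "shuffled"
    shuffled.mkdir()
    files = sorted(src.iterdir())
    perm = rng.permutation(len(files))
    for new_i, f in zip(perm, files):
        shutil.copy(f, shuffled / f"x_{new_i:04d}.dcm")
    a = load_dicom(src)
    b = load_dicom(shuffled)
    assert np.array_equal(a.data, b.data)


def test_empty_directory_error(tmp_path):
    (tmp_path / "empty").mkdir()
    with pytest.raises(CbctError, match="no DICOM series"):
        load_dicom(tmp_path / "empty")


# -- threshold --------------------------------------------------------------

def test_window_includes_constant_volume():
    mask = threshold_segment(_vol(np.full((4, 4, 4), 500.0)), 400, 700)
    assert mask.mask.all() and not mask.empty_warning


def test_window_excluding_everything_warns():
    with pytest.warns(UserWarning, match="no"):
        mask = threshold_segment(_vol(np.full((4, 4, 4), 500.0)), 600, 700)
    assert not mask.mask.any() and mask.empty_warning


def test_threshold_matches_exhaustive_oracle():
    rng = np.random.default_rng(2)
    data = rng.integers(0, 4000, size=(12, 11, 10))
    mask = threshold_segment(_vol(data), 550, 3300)
    count = 0
    for z in range(12):
        for y in range(11):
            for x in range(10):
                if 550 <= data[z, y, x] <= 3300:
                    count += 1
                    assert mask.mask[z, y, x]
    assert mask.count == count


def test_invalid_window_rejected():
    with pytest.raises(CbctError):
        threshold_segment(_vol(np.zeros((2, 2, 2))), 700, 400)


# -- mask subtraction -------------------------------------------------------

def _mask(arr):
    return RoiMask(np.asarray(arr, dtype=bool), (0.5, 0.5, 0.5))


def test_subtract_self_is_empty():
    rng = np.random.default_rng(3)
    a = _mask(rng.random((6, 6, 6)) > 0.5)
    assert mask_subtract(a, a).count == 0


def test_subtract_disjoint_keeps_a():
    a = np.zeros((4, 4, 4), bool)
    b = np.zeros((4, 4, 4), bool)
    a[:2] = True
    b[3:] = True
    out = mask_subtract(_mask(a), _mask(b))
    assert np.array_equal(out.mask, a)


def test_subtract_matches_logical_oracle():
    rng = np.random.default_rng(4)
    a = rng.random((8, 8, 8)) > 0.5
    b = rng.random((8, 8, 8)) > 0.5
    out = mask_subtract(_mask(a), _mask(b))
    for idx in np.ndindex(8, 8, 8):
        assert out.mask[idx] == (a[idx] and not b[idx])


# -- voxel counting ---------------------------------------------------------

def test_cube_removal_exact_arithmetic():
    """10^3 voxels at 0.3 mm isotropic -> exactly -27 mm^3 = -0.027 ml."""
    change = np.zeros((20, 20, 20), bool)
    change[5:15, 5:15, 5:15] = True
    mask = RoiMask(change, (0.3, 0.3, 0.3))
    box = SelectionBox([0, 0, 0], [6, 6, 6])
    assert htvc(mask, [box], direction="loss") == pytest.approx(-0.027)


def test_sphere_removal_matches_analytic_volume():
    spec = CbctPhantomSpec(seed=0)
    series = make_cbct_series(spec)
    roi0 = threshold_segment(series.t0, 550, 3300)
    roi2 = threshold_segment(series.t2, 550, 3300)
    lost = mask_subtract(roi0, roi2)
    got = htvc(lost, series.boxes, direction="loss")
    truth = series.truth["htvc_ml"]
    assert got == pytest.approx(truth, rel=0.01)
    assert got < 0  # tissue loss counts negative


def test_empty_change_mask_zero():
    mask = _mask(np.zeros((4, 4, 4)))
    assert htvc(mask, [SelectionBox([0, 0, 0], [2, 2, 2])],
                direction="loss") == 0.0


def test_box_outside_grid_warns_and_contributes_zero():
    mask = _mask(np.ones((4, 4, 4)))
    with pytest.warns(UserWarning, match="outside the grid"):
        out = htvc(mask, [SelectionBox([100, 100, 100], [110, 110, 110])],
                   direction="loss")
    assert out == 0.0


def test_htvc_additive_over_disjoint_boxes():
    rng = np.random.default_rng(5)
    mask = _mask(rng.random((16, 16, 16)) > 0.6)
    b1 = SelectionBox([0, 0, 0], [3.9, 7.9, 7.9])
    b2 = SelectionBox([4.1, 0, 0], [7.9, 7.9, 7.9])
    both = htvc(mask, [b1, b2], direction="gain")
    assert both == pytest.approx(htvc(mask, [b1], direction="gain")
                                 + htvc(mask, [b2], direction="gain"))


def test_voxel_count_converges_with_spacing():
    """Volume error is bounded by surface area x spacing."""
    r = 5.0
    for spacing in (0.5, 0.25):
        n = int(2 * (r + 2) / spacing)
        ax = (np.arange(n) + 0.5) * spacing - (r + 2)
        zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
        inside = xx ** 2 + yy ** 2 + zz ** 2 <= r ** 2
        vol = inside.sum() * spacing ** 3
        truth = 4 / 3 * np.pi * r ** 3
        assert abs(vol - truth) <= 4 * np.pi * r ** 2 * spacing


# -- alignment --------------------------------------------------------------

def test_align_identity(small_cbct_series):
    t = align_jaw(small_cbct_series.t0, small_cbct_series.t0)
    assert t.angle_deg < 0.01
    assert np.linalg.norm(t.translation) < 0.01


def test_align_recovers_known_shift(small_cbct_series):
    """Moving volume = fixed translated (1.5, 0, 0) mm, recovered < 0.1 mm."""
    fixed = small_cbct_series.t0
    shift = np.array([1.5, 0.0, 0.0])
    moving = VoxelVolume(fixed.data, fixed.spacing,
                         origin=fixed.origin + shift)
    t = align_jaw(moving, fixed)
    assert np.linalg.norm(t.translation + shift) < 0.1 or \
        np.linalg.norm(t.apply(fixed.origin + shift) - fixed.origin) < 0.1


def test_manual_mode_passes_through():
    vol = _vol(np.zeros((4, 4, 4)))
    t = RigidTransform.from_rotvec_deg([1, 2, 3], [4, 5, 6])
    out = align_jaw(vol, vol, init=t, mode="manual")
    assert out is t


def test_manual_mode_requires_transform():
    vol = _vol(np.zeros((4, 4, 4)))
    with pytest.raises(CbctError, match="manual"):
        align_jaw(vol, vol, mode="manual")
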
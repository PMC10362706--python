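"""Hard-tissue volume change from serial CBCT.

Pipeline: load the T0 and T2 DICOM series, rigidly align T2 to T0 (the
jaws separately, since occlusion varies between acquisitions), threshold
both volumes into bone+tooth masks, Boolean-subtract the masks, and count
change voxels inside per-jaw selection boxes. Volumes are voxel counts
times the voxel volume; tissue present at T0 and absent at T2 (extraction)
contributes *negatively* to HTVC.

The clinical threshold window is chosen per patient inside the printed
range (lower bound 400-700, upper bound 2000-4600); the defaults here are
the midpoints 550 and 3300.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .registration import RigidTransform

__all__ = ["VoxelVolume", "RoiMask", "SelectionBox", "load_dicom",
           "write_dicom", "align_jaw", "threshold_segment", "mask_subtract",
           "htvc", "CbctError", "DEFAULT_LOWER", "DEFAULT_UPPER"]

DEFAULT_LOWER = 550.0
DEFAULT_UPPER = 3300.0


class CbctError(ValueError):
    pass


@dataclass
class VoxelVolume:
    """3D intensity grid. ``data`` is indexed [z, y, x]; ``spacing`` is
    (dx, dy, dz) in mm/voxel; ``origin`` is the world position of the
    center of voxel (0, 0, 0)."""

    data: np.ndarray
    spacing: tuple
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.size == 0:
            raise CbctError("volume must be a non-empty 3D grid")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise CbctError("spacing must be positive componentwise")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.orientation = np.asarray(self.orientation, dtype=float).reshape(3, 3)

    @property
    def voxel_volume_mm3(self) -> float:
        return self.spacing[0] * self.spacing[1] * self.spacing[2]

    def index_to_world(self, idx_zyx: np.ndarray) -> np.ndarray:
        """World coordinates of voxel centers given [z, y, x] indices."""
        idx = np.atleast_2d(np.asarray(idx_zyx, dtype=float))
        ijk = idx[:, ::-1]  # -> x, y, z order
        local = ijk * np.array(self.spacing)
        return self.origin + local @ self.orientation.T


@dataclass
class RoiMask:
    """Boolean segmentation congruent with a :class:`VoxelVolume`."""

    mask: np.ndarray
    spacing: tuple
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    jaw: str = ""
    empty_warning: bool = False

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise CbctError("mask must be 3D")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def count(self) -> int:
        return int(self.mask.sum())


@dataclass
class SelectionBox:
    """Axis-aligned selection box in T0 world coordinates (mm)."""

    min_corner: np.ndarray
    max_corner: np.ndarray
    jaw: str = ""

    def __post_init__(self):
        self.min_corner = np.asarray(self.min_corner, dtype=float).reshape(3)
        self.max_corner = np.asarray(self.max_corner, dtype=float).reshape(3)
        if not np.all(self.min_corner < self.max_corner):
            raise CbctError("box min corner must be < max corner componentwise")


# ---------------------------------------------------------------------------
# DICOM I/O

def load_dicom(directory) -> VoxelVolume:
    """Read a single coherent DICOM series from ``directory``.

    Slices are reassembled by spatial position (file order on disk is
    irrelevant); missing or duplicated slices raise :class:`CbctError`.
    """
    import SimpleITK as sitk

    directory = str(directory)
    reader = sitk.ImageSeriesReader()
    series = reader.GetGDCMSeriesIDs(directory)
    if len(series) == 0:
        raise CbctError(f"no DICOM series found in {directory}")
    if len(series) > 1:
        raise CbctError(f"mixed series in {directory}: {list(series)}")
    files = reader.GetGDCMSeriesFileNames(directory, series[0])
    reader.SetFileNames(files)
    img = reader.Execute()
    data = sitk.GetArrayFromImage(img)  # [z, y, x]
    spacing = img.GetSpacing()  # (dx, dy, dz)
    origin = np.array(img.GetOrigin())
    direction = np.array(img.GetDirection()).reshape(3, 3)

    # uniform slice step check
    if data.shape[0] > 2:
        zs = np.array([float(sitk.ReadImage(f).GetOrigin()[2]) for f in files])
        steps = np.diff(np.sort(zs))
        if steps.size and (np.any(steps < 1e-9)
                           or np.ptp(steps) > 0.01 * np.median(steps)):
            raise CbctError("non-uniform slice spacing: missing or "
                            "duplicated slices in the series")
    return VoxelVolume(data=data, spacing=spacing, origin=origin,
                       orientation=direction)


def write_dicom(vol: VoxelVolume, directory, series_description="facevol phantom",
                seed: int = 0) -> None:
    """Write a volume as an explicit-VR little-endian CT series (one file
    per slice), readable by any GDCM-based reader."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, CTImageStorage

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    root = "1.2.826.0.1.3680043.8.498."
    study_uid = f"{root}{seed + 1}.1"
    series_uid = f"{root}{seed + 1}.2"
    frame_uid = f"{root}{seed + 1}.3"
    data = np.asarray(vol.data, dtype=np.int16)
    nz = data.shape[0]
    for k in range(nz):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = f"{root}{seed + 1}.4.{k + 1}"
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\x00" * 128)
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.Modality = "CT"
        ds.SeriesDescription = series_description
        ds.PatientName = "phantom"
        ds.PatientID = "phantom"
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [float(vol.origin[0]), float(vol.origin[1]),
                                   float(vol.origin[2] + k * vol.spacing[2])]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [float(vol.spacing[1]), float(vol.spacing[0])]
        ds.SliceThickness = float(vol.spacing[2])
        ds.Rows, ds.Columns = data.shape[1], data.shape[2]
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.RescaleIntercept = 0.0
        ds.RescaleSlope = 1.0
        ds.PixelData = data[k].tobytes()
        ds.save_as(directory / f"slice_{k:04d}.dcm", enforce_file_format=True)


# ---------------------------------------------------------------------------
# alignment

def _ncc(a, b):
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    return float((a * b).sum() / denom) if denom > 0 else 0.0


def align_jaw(moving: VoxelVolume, fixed: VoxelVolume, jaw: str = "",
              init: RigidTransform | None = None, mode: str = "auto",
              subbox: tuple | None = None, max_shift: float = 5.0) -> RigidTransform:
    """Rigid transform (moving -> fixed world) for one jaw.

    ``mode="manual"`` returns ``init`` unchanged (the operator's rotation
    and translation). ``mode="auto"`` refines ``init`` (or identity) by
    maximizing normalized cross-correlation over a jaw sub-box with a
    Powell local search on the six rigid parameters.

    ``subbox`` is ((zmin, zmax), (ymin, ymax), (xmin, xmax)) index ranges
    into the fixed grid; defaults to the central 80%.
    """
    if mode == "manual":
        if init is None:
            raise CbctError("manual alignment requires a supplied transform")
        return init
    if mode != "auto":
        raise CbctError(f"unknown alignment mode {mode!r}")
    t0 = init if init is not None else RigidTransform.identity()

    shape = fixed.data.shape
    if subbox is None:
        subbox = tuple((int(0.1 * s), int(0.9 * s)) for s in shape)
    sl = tuple(slice(lo, hi) for lo, hi in subbox)
    fsub = np.asarray(fixed.data[sl], dtype=float)
    zz, yy, xx = np.meshgrid(*[np.arange(lo, hi) for lo, hi in subbox],
                             indexing="ij")
    world = fixed.index_to_world(np.column_stack([zz.ravel(), yy.ravel(),
                                                  xx.ravel()]))
    center = world.mean(axis=0)
    msp = np.array(moving.spacing)

    def _resample(params):
        rot = Rotation.from_rotvec(params[:3]).as_matrix()
        t = params[3:]
        # fixed world -> moving world (inverse of moving->fixed about center)
        pts = (world - center - t) @ rot + center
        pts = t0.inverse().apply(pts)
        idx_xyz = (pts - moving.origin) @ moving.orientation / msp
        coords = idx_xyz[:, ::-1].T  # z, y, x
        return ndimage.map_coordinates(np.asarray(moving.data, dtype=float),
                                       coords, order=1, mode="constant",
                                       cval=float(np.min(moving.data)))

    from scipy.optimize import minimize

    def _cost(params):
        return -_ncc(fsub.ravel(), _resample(params))

    base_cost = _cost(np.zeros(6))
    res = minimize(_cost, np.zeros(6), method="Powell",
                   options={"xtol": 1e-4, "ftol": 1e-8, "maxiter": 2000})
    if res.fun > base_cost + 1e-12 and init is None:
        raise CbctError("similarity not improved and no initial transform "
                        "supplied")
    params = res.x if res.fun <= base_cost else np.zeros(6)
    rot = Rotation.from_rotvec(params[:3]).as_matrix()
    t = params[3:]
    # refine about center composed onto init: x -> rot(x - center) + center + t
    refine = RigidTransform(rot, center + t - rot @ center)
    return refine.compose(t0)


# ---------------------------------------------------------------------------
# segmentation and counting

def threshold_segment(vol: VoxelVolume, lower: float = DEFAULT_LOWER,
                      upper: float = DEFAULT_UPPER, jaw: str = "") -> RoiMask:
    """Inclusive window threshold ``lower <= I <= upper``; no morphological
    post-processing. An empty mask is flagged and warned, not fatal."""
    if lower >= upper:
        raise CbctError("threshold lower bound must be < upper bound")
    mask = (vol.data >= lower) & (vol.data <= upper)
    empty = not bool(mask.any())
    if empty:
        warnings.warn(f"threshold window [{lower}, {upper}] selects no "
                      "voxels", stacklevel=2)
    return RoiMask(mask=mask, spacing=vol.spacing, origin=vol.origin,
                   jaw=jaw, empty_warning=empty)


def resample_mask(b: RoiMask, onto: RoiMask,
                  transform: RigidTransform | None = None) -> np.ndarray:
    """Nearest-neighbour resample of mask ``b`` onto the grid of ``onto``,
    mapping through ``transform`` (b-grid world -> onto-grid world)."""
    if transform is None and b.mask.shape == onto.mask.shape \
            and np.allclose(b.origin, onto.origin) \
            and np.allclose(b.spacing, onto.spacing):
        return b.mask
    t = transform if transform is not None else RigidTransform.identity()
    shape = onto.mask.shape
    zz, yy, xx = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    world = onto.origin + np.column_stack(
        [xx.ravel(), yy.ravel(), zz.ravel()]) * np.array(onto.spacing)
    src = t.inverse().apply(world)
    idx_xyz = (src - b.origin) / np.array(b.spacing)
    coords = idx_xyz[:, ::-1].T
    out = ndimage.map_coordinates(b.mask.astype(np.uint8), coords, order=0,
                                  mode="constant", cval=0)
    return out.reshape(shape).astype(bool)


def mask_subtract(a: RoiMask, b: RoiMask,
                  transform: RigidTransform | None = None) -> RoiMask:
    """Voxels present in ``a`` and absent in ``b`` (after resampling ``b``
    onto ``a``'s grid through ``transform``)."""
    b_on_a = resample_mask(b, a, transform)
    if b_on_a.shape != a.mask.shape:
        raise CbctError("mask shape mismatch after resampling")
    return RoiMask(mask=a.mask & ~b_on_a, spacing=a.spacing, origin=a.origin,
                   jaw=a.jaw)


def htvc(change: RoiMask, boxes, spacing=None, direction: str = "loss") -> float:
    """Voxel-counted volume of the change mask inside the selection boxes,
    in ml.

    ``direction="loss"`` means ``change`` holds tissue present at the
    earlier time and absent at the later (the extraction case) and the
    result is negative; ``direction="gain"`` is the opposite subtraction
    and counts positive. Boxes entirely outside the grid contribute zero
    with a warning.
    """
    if direction not in ("loss", "gain"):
        raise CbctError("direction must be 'loss' or 'gain'")
    if isinstance(boxes, SelectionBox):
        boxes = [boxes]
    if len(boxes) == 0:
        raise CbctError("need at least one selection box")
    sp = np.array(spacing if spacing is not None else change.spacing,
                  dtype=float)
    shape = change.mask.shape  # (nz, ny, nx)
    selected = np.zeros(shape, dtype=bool)
    for box in boxes:
        lo_idx = np.ceil((box.min_corner - change.origin) / sp - 1e-9)
        hi_idx = np.floor((box.max_corner - change.origin) / sp + 1e-9)
        lo = np.maximum(lo_idx, 0).astype(int)
        hi = np.minimum(hi_idx, np.array(shape)[::-1] - 1).astype(int)
        if np.any(lo > hi):
            warnings.warn(f"selection box {box.jaw or '(unnamed)'} lies "
                          "outside the grid; zero contribution", stacklevel=2)
            continue
        selected[lo[2]:hi[2] + 1, lo[1]:hi[1] + 1, lo[0]:hi[0] + 1] = True
    count = int((change.mask & selected).sum())
    volume_ml = count * float(np.prod(sp)) / 1000.0
    return -volume_ml if direction == "loss" else volume_ml


def write_nifti(mask: RoiMask, path) -> None:
    """Optional NIfTI export of a mask."""
    import nibabel as nib
    affine = np.diag([mask.spacing[0], mask.spacing[1], mask.spacing[2], 1.0])
    affine[:3, 3] = mask.origin
    img = nib.Nifti1Image(mask.mask.transpose(2, 1, 0).astype(np.uint8), affine)
    nib.save(img, str(path))
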
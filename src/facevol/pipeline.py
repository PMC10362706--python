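"""End-to-end soft- and hard-tissue pipelines.

``soft_tissue_report`` composes the full projection-method chain on
in-memory objects: frame construction from the lasers, upper-third ICP
registration of the follow-up scans onto T0, buccal extraction on T0, ring
transfer and Boolean cut on every time point, projected-volume (STV/STVC)
and deviation summaries. ``hard_tissue_report`` runs the CBCT chain:
per-jaw alignment, window thresholding, mask subtraction in both
directions, and box-gated voxel counting. The CLI wraps these with file
I/O; reports are plain dicts, JSON-serializable, with the exact parameter
set echoed for audit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import cbct as cb
from .deviation import DEFAULT_MAX_DIST, compare
from .mesh_io import LandmarkSet, SurfaceScan, read_landmarks, read_lasers, read_obj
from .projection import DEFAULT_HALF_LENGTH, boolean_cut, extrude_ring, stv, stvc
from .region import extract_buccal
from .registration import RigidTransform, apply_transform, crop_upper_third, icp_register
from .sagittal_frame import build_frame

__all__ = ["RunConfig", "soft_tissue_report", "hard_tissue_report",
           "run_soft_pipeline", "run_hard_pipeline", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class RunConfig:
    """Pipeline parameters. Defaults follow the clinical protocol: 10 mm
    sweep half-length, upper third of the face for registration, threshold
    window midpoints 550/3300."""

    t0: str = ""
    scans: dict = field(default_factory=dict)      # label -> path
    lasers: str = ""
    landmarks: str = ""
    sides: tuple = ("R",)
    half_length: float = DEFAULT_HALF_LENGTH
    upper_fraction: float = 1.0 / 3.0
    landmark_tolerance: float = 1.0
    max_dist: float = DEFAULT_MAX_DIST
    icp_max_iter: int = 100
    icp_tol: float = 1e-4
    icp_samples: int = 5000
    seed: int = 0
    # CBCT
    cbct_t0: str = ""
    cbct_t2: str = ""
    lower: float = cb.DEFAULT_LOWER
    upper: float = cb.DEFAULT_UPPER
    boxes: list = field(default_factory=list)
    align_mode: str = "none"                       # none | auto | manual
    transforms: dict = field(default_factory=dict)  # jaw -> RigidTransform
    out_dir: str = "."

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key, val in data.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            setattr(cfg, key, val)
        return cfg

    def params_dict(self) -> dict:
        return {
            "half_length_mm": self.half_length,
            "upper_fraction": self.upper_fraction,
            "landmark_tolerance_mm": self.landmark_tolerance,
            "max_dist_mm": self.max_dist,
            "icp": {"max_iter": self.icp_max_iter, "tol": self.icp_tol,
                    "samples": self.icp_samples},
            "threshold": [self.lower, self.upper],
            "seed": self.seed,
        }


def _stage(name):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(name, exc) from exc
            return False
    return _Ctx()


def soft_tissue_report(t0: SurfaceScan, scans: dict, lasers: dict,
                       landmarks: LandmarkSet, config: RunConfig | None = None
                       ) -> dict:
    """Run the projection method on in-memory inputs.

    ``scans`` maps follow-up labels (e.g. "T1", "T2") to their (unaligned)
    scans; all are registered onto ``t0``. Returns a JSON-serializable
    report with per-side STVs (ml), pairwise STVCs, deviation summaries
    and QC flags.
    """
    cfg = config or RunConfig()
    report = {"parameters": cfg.params_dict(), "sides": {}, "qc": {}}

    with _stage("sagittal_frame"):
        frame = build_frame(lasers["horizontal-complete"], lasers["vertical"])
        report["frame"] = frame.to_dict()

    with _stage("registration"):
        upper = crop_upper_third(t0, frame, cfg.upper_fraction)
        registered = {"T0": t0}
        for label in sorted(scans):
            t = icp_register(scans[label], upper, max_iter=cfg.icp_max_iter,
                             tol=cfg.icp_tol, samples=cfg.icp_samples,
                             seed=cfg.seed)
            registered[label] = apply_transform(scans[label], t)
            report["qc"][f"icp_{label}"] = {
                "converged": bool(t.converged), "rms_mm": t.rms,
                "iterations": t.n_iter, "angle_deg": t.angle_deg,
                "translation_mm": t.translation.tolist(),
            }

    labels = ["T0"] + sorted(scans)
    for side in cfg.sides:
        side_rep = {"stv_ml": {}, "stvc_ml": {}, "deviation": {},
                    "area_mm2": {}}
        with _stage("region"):
            patch0 = extract_buccal(t0, landmarks, side=side)
        with _stage("projection"):
            ring = extrude_ring(patch0, frame.projection_direction,
                                cfg.half_length)
            patches = {}
            for label in labels:
                patch = boolean_cut(ring, registered[label])
                patch.side = side
                patch.label = label
                patches[label] = patch
                res = stv(patch, frame)
                side_rep["stv_ml"][label] = res.stv_ml
                side_rep["area_mm2"][label] = res.area_mm2
                side_rep.setdefault("_results", {})[label] = res
        with _stage("deviation"):
            for label in labels[1:]:
                dev = compare(patches["T0"], patches[label],
                              max_dist=cfg.max_dist)
                side_rep["deviation"][f"{label}-T0"] = {
                    "mu_mm": dev.mu, "sd_mm": dev.sd, "rms_mm": dev.rms,
                    "n": dev.n,
                }
        results = side_rep.pop("_results")
        for i, late in enumerate(labels):
            for early in labels[:i]:
                ch = stvc(results[late], results[early])
                side_rep["stvc_ml"][ch.period] = ch.value_ml
        report["sides"][side] = side_rep
    return report


def hard_tissue_report(vol_t0, vol_t2, boxes, config: RunConfig | None = None
                       ) -> dict:
    """Run the CBCT voxel-counting chain on in-memory volumes.

    Boxes are grouped by jaw tag; each jaw gets its own alignment
    (``align_mode``: "none" = identity, "manual" = supplied transform,
    "auto" = NCC refinement). HTVC per jaw is the gain-minus-loss voxel
    volume inside that jaw's boxes; total HTVC is the sum over jaws, in ml,
    negative for net tissue loss.
    """
    cfg = config or RunConfig()
    report = {"parameters": cfg.params_dict(), "jaws": {}, "warnings": []}
    jaws = sorted({b.jaw for b in boxes}) or [""]

    with _stage("segmentation"):
        roi_t0 = cb.threshold_segment(vol_t0, cfg.lower, cfg.upper)
        roi_t2 = cb.threshold_segment(vol_t2, cfg.lower, cfg.upper)
        if roi_t0.empty_warning or roi_t2.empty_warning:
            report["warnings"].append("empty threshold mask")

    total = 0.0
    for jaw in jaws:
        jaw_boxes = [b for b in boxes if b.jaw == jaw]
        with _stage("alignment"):
            if cfg.align_mode == "none":
                t = RigidTransform.identity()
            elif cfg.align_mode == "manual":
                t = cfg.transforms[jaw]
            else:
                t = cb.align_jaw(vol_t2, vol_t0, jaw=jaw,
                                 init=cfg.transforms.get(jaw), mode="auto")
        with _stage("subtraction"):
            lost = cb.mask_subtract(roi_t0, roi_t2, transform=t
                                    if cfg.align_mode != "none" else None)
            t2_on_t0 = cb.resample_mask(roi_t2, roi_t0,
                                        None if cfg.align_mode == "none" else t)
            gained = cb.RoiMask(mask=t2_on_t0 & ~roi_t0.mask,
                                spacing=roi_t0.spacing, origin=roi_t0.origin,
                                jaw=jaw)
        with _stage("voxel_count"):
            loss_ml = cb.htvc(lost, jaw_boxes, direction="loss")
            gain_ml = cb.htvc(gained, jaw_boxes, direction="gain")
        net = loss_ml + gain_ml
        report["jaws"][jaw or "all"] = {
            "loss_ml": loss_ml, "gain_ml": gain_ml, "htvc_ml": net,
            "transform": t.to_matrix().tolist(),
        }
        total += net
    report["htvc_total_ml"] = total
    return report


# ---------------------------------------------------------------------------
# file-level entry points

def run_soft_pipeline(config: RunConfig) -> dict:
    """Load inputs from the paths in ``config``, run
    :func:`soft_tissue_report`, and write JSON + CSV into
    ``config.out_dir``."""
    # input reading raises plain input errors (not stage failures)
    t0 = read_obj(config.t0, label="T0")
    scans = {label: read_obj(path, label=label)
             for label, path in config.scans.items()}
    lasers = read_lasers(config.lasers)
    landmarks = read_landmarks(config.landmarks, scan=t0,
                               tolerance=config.landmark_tolerance)
    report = soft_tissue_report(t0, scans, lasers, landmarks, config)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "soft_tissue_report.json").write_text(json.dumps(report, indent=2))
    rows = ["side,quantity,key,value"]
    for side, rep in report["sides"].items():
        for label, v in rep["stv_ml"].items():
            rows.append(f"{side},stv_ml,{label},{v:.6f}")
        for period, v in rep["stvc_ml"].items():
            rows.append(f"{side},stvc_ml,{period},{v:.6f}")
        for period, dev in rep["deviation"].items():
            for key in ("mu_mm", "sd_mm", "rms_mm"):
                rows.append(f"{side},{key},{period},{dev[key]:.6f}")
    (out / "soft_tissue_report.csv").write_text("\n".join(rows) + "\n")
    return report


def run_hard_pipeline(config: RunConfig) -> dict:
    """Load DICOM series and box definitions, run
    :func:`hard_tissue_report`, write JSON."""
    vol_t0 = cb.load_dicom(config.cbct_t0)
    vol_t2 = cb.load_dicom(config.cbct_t2)
    boxes = []
    for b in config.boxes:
        if isinstance(b, cb.SelectionBox):
            boxes.append(b)
        else:
            boxes.append(cb.SelectionBox(np.array(b["min"]),
                                         np.array(b["max"]),
                                         jaw=b.get("jaw", "")))
    report = hard_tissue_report(vol_t0, vol_t2, boxes, config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "hard_tissue_report.json").write_text(json.dumps(report, indent=2))
    return report
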
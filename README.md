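# facevol

Measurement of facial **soft-tissue volume change** from serial 3D surface
scans by the *projection method*, together with **hard-tissue volume
change** from serial CBCT by threshold segmentation and voxel counting.

The package is aimed at dento-maxillofacial researchers who follow a
patient across time points (e.g. before and after third-molar extraction)
with structured-light facial scans and cone-beam CT, and who need a
reproducible, operator-independent volumetric endpoint for the cheek
region.

## The measurement

**Soft tissue.** Facial scans at T0 (baseline), T1, T2 are OBJ triangle
meshes in mm. The chain is:

1. **Frame** — the orthogonal laser lines projected onto the face during
   acquisition are recorded with the T0 scan. Their intersection is the
   origin; the horizontal plane (Plane 1) is fit to the horizontal laser,
   Line 1 is its normal through the origin, Line 2 joins the origin to a
   far vertical-laser point, and the **mid-sagittal plane** (Plane 2) is
   spanned by Lines 1 and 2. Its normal, **Line 3**, is the projection
   direction.
2. **Registration** — T1/T2 are rigidly aligned to T0 by point-to-plane
   ICP restricted to the upper third of the face, which is unaffected by
   the measured region.
3. **Region** — the buccal (cheek) region is outlined on T0 by surface
   geodesics connecting the soft-tissue landmarks pt′ → al′ → ex′ → ch′ →
   cf′ → mandibular lower border → pt′ (cf′ is the perpendicular foot of
   ch′ on the border).
4. **Ring transfer** — the T0 boundary loop is swept ±10 mm along Line 3
   into an open "ring" band; cutting the registered T1/T2 scans with this
   band transfers *the same* region to every time point without
   re-drawing it.
5. **Volume** — the soft-tissue volume (STV) of a patch is the volume of
   the solid between the patch and its orthogonal projection onto the
   mid-sagittal plane, computed by signed-prism summation
   `STV = Σ_triangles h_c · A_proj` (centroid distance × projected area);
   STVC is the difference of STVs between time points (later − earlier),
   reported in ml (1 ml = 1000 mm³).
6. **Deviation** — per-vertex signed closest-point distances X_i between
   corresponding patches, summarized by the population formulas
   µ = mean(X), SD = √(1/N Σ(X_i−µ)²), RMS = √(1/N ΣX_i²), so
   RMS² = µ² + SD² identically.

**Hard tissue.** T0/T2 CBCT DICOM series are aligned per jaw, thresholded
with one inclusive window (defaults 550–3300, chosen per patient inside
400–700 / 2000–4600), Boolean-subtracted, and change voxels are counted
inside per-jaw selection boxes. HTVC = voxel count × voxel volume, with
tissue lost between T0 and T2 counting **negative**.

**Statistics.** ICC(2,1) — two-way random effects, absolute agreement,
single measure — with the McGraw–Wong F-based CI, and the pilot
sample-size rule n = ln(1−confidence)/ln(1−π) (0.90, 0.10 → 21.9).

Because no clinical scans ship with the package, everything is validated
on synthetic phantoms with closed-form ground truth (see
`facevol.synthetic` and `docs/methods.md`).

## Worked example

Generate a phantom face series carrying one Gaussian "swelling" of
amplitude 2 mm and width σ = 6 mm on the right cheek at T1 (analytic added
projected volume 2πAσ² = 452.39 mm³), then measure it:

```bash
facevol simulate --out demo --seed 7 --resolution 1.0 --bump "70,-45,2,6"
facevol stv --t0 demo/T0.obj --scan T1=demo/T1.obj \
            --landmarks demo/landmarks.csv --lasers demo/lasers.obj \
            --side R --out demo/out
```

prints

```
side R STVC T1-T0: +0.452 ml
```

and `demo/out/soft_tissue_report.json` contains (abridged):

```
stv_ml:   T0 580.377   T1 580.830        # projected cheek volumes
stvc_ml:  T1-T0 +0.4524                  # the measured change, ml
deviation T1-T0: mu 0.0281  SD 0.1452  RMS 0.1479 mm  (n = 9609)
```

The measured change 0.4524 ml is the analytic 452.39 mm³ to 0.01%; the
deviation map shows the sub-0.2 mm surface agreement everywhere outside
the bump. `demo/truth.json` records the generator's exact truth for
comparison.

The CBCT side works the same way
(`facevol simulate --cbct`, then `facevol htvc --t0 ... --t2 ...
--boxes boxes.json`), reporting HTVC in ml, negative for resorbed or
extracted tissue.

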
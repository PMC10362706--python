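# Methods

This note documents the models, algorithms, numerical choices and
limitations behind `facevol`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`; nothing is
asserted that the code does not measure.

## 1. Coordinate frame from the laser traces

The acquisition rig projects a horizontal and a vertical laser onto the
face; both curves are captured in the same coordinates as the T0 scan.
The frame construction is:

* **Origin** — each trace is reduced to a total-least-squares (TLS) 3D
  line and the origin is the midpoint of the common-perpendicular segment
  between the two lines. Recorded laser curves follow the facial surface,
  so a single global TLS line can miss the true crossing by centimetres;
  the fits are therefore refined twice using only points within 15 mm of
  the current crossing estimate (seeded at the closest pair of raw trace
  points). For straight traces this is exactly the single global fit. A
  residual closest approach ≥ 2 mm is an error ("traces do not cross").
* **Plane 1** (horizontal) — three-point plane through the origin and the
  two farthest-apart points of the *complete* horizontal trace (the
  mirror-reflected traces are rejected). **Line 1** is its normal through
  the origin, oriented along the vertical trace's ordering (inferior →
  superior).
* **Line 2** — origin to the vertical-trace point farthest from the
  origin. Degenerate if within 0.1° of Line 1, or if the vertical trace
  is coplanar with Plane 1.
* **Plane 2** (mid-sagittal) — spanned by Lines 1 and 2; its normal,
  **Line 3**, is the projection direction, oriented toward the subject's
  right. Orientation conventions are carried by the trace orderings:
  horizontal traces run subject-left → subject-right, vertical traces
  inferior → superior.

The frame is built once, on T0; follow-up scans are registered into it.
Frame construction is equivariant under rigid motions of all inputs
(tested to 1e-9).

## 2. Rigid registration

Point-to-plane ICP of the floating scan onto the T0 upper third
(height-quantile crop along the frame's vertical axis, default fraction
1/3). Details that matter:

* Uniform seeded subsampling of 5000 floating vertices restricted to the
  fixed-region bounding box padded by 10% + 10 mm (the pad keeps the true
  overlap inside the sample box for initial misalignments up to ~10 mm).
* Correspondences whose closest point lands on a border face of the fixed
  region are rejected (border rejection, not distance trimming): they
  belong to floating points outside the region and otherwise bias the
  fit. No other trimming is applied.
* Coarse initialization: translation aligning the floating sample
  centroid with the fixed-region centroid.
* The linearized rigid update is solved about the correspondence centroid
  (rotation/translation decouple there) with a 20 mm trust-region cap per
  iteration; convergence requires both the RMS improvement and the rigid
  step to fall below `tol` (default 1e-4 mm), guarding against transient
  correspondence plateaus. Non-convergence within `max_iter` (100)
  returns the transform flagged `converged=False`.

On the noiseless phantom, random perturbations up to 10°/10 mm are
recovered to ~1e-10; with 0.2 mm surface noise the pose error is a few
hundredths of a millimetre.

## 3. Buccal region and boundary transfer

The operator's freehand boundary is formalized as shortest edge-walks
(Dijkstra, Euclidean edge weights) between the mesh vertices nearest each
landmark, in the fixed order pt′ → al′ → ex′ → ch′ → cf′ → mandible
border → pt′. cf′ is computed as the closest point on the piecewise-linear
border polyline to ch′ unless supplied explicitly. Waypoints snapping to
the same mesh vertex are deduplicated; each successive segment is routed
on the graph minus vertices already used, so the assembled loop is simple
by construction (plain per-segment geodesics can share staircase vertices
near narrow corners). The enclosed patch is the flood fill of faces over
the face-adjacency graph blocked at loop edges, seeded at the face nearest
the loop centroid that projects inside the loop; a fill reaching an open
scan border that is not part of the loop is a leak error. The nasal-side
closure al′ → ex′ is configurable (`nasal_closure=False` drops ex′).

**Ring model.** The closed loop is swept ±`half_length` (default 10 mm)
along Line 3 as a triangulated quad strip; the interior is discarded. A
loop whose projection self-intersects is flagged.

**Boolean cut.** The cut of a registered scan with the ring is computed
in the projection plane: scan triangles are classified against the 2D
loop polygon; fully-inside triangles are kept, crossing triangles are
clipped exactly (shapely intersection, ear-clipping retriangulation) and
lifted back to 3D barycentrically. Numerical handling that the identity
and invariance properties rely on:

* Vertices within 1e-6 mm of the polygon boundary are treated as
  *on-boundary* (the self-cut case, where the polygon passes exactly
  through mesh vertices); boundary-touching faces are kept whole, and
  all-on-boundary corner faces are resolved by a centroid test. The
  on-boundary set is grown along chains of touching faces.
* Candidate faces are restricted to the height reach of the band
  (loop heights ± half_length): sheets that merely project into the loop
  — the opposite cheek, or a scan displaced beyond the sweep — are not
  cut by the ring.
* Connected components of candidate faces are validated: a component
  whose crossing faces all cross farther than half_length (+0.5 mm slack)
  from the T0 boundary height, or which contains reach-cropped content,
  is not a legitimate cut; components below 5% of the loop's own area are
  debris. No valid component → "no ring intersection" error; more than
  one → ambiguity error listing areas.

With these rules the self-cut reproduces the T0 patch area to float
precision, is stable under 1e-9 perturbations, is exactly invariant under
translation along the sweep direction, and a 15 mm displacement (beyond
the 10 mm band) raises the out-of-band error.

## 4. Projected volume (STV) and change (STVC)

STV is computed by signed-prism summation over triangles: (signed
centroid distance to the mid-sagittal plane, positive on the patch's
anatomical side) × (triangle area projected onto the plane). For a patch
projecting injectively this equals the closed-solid volume (the prism law
`area × distance` holds exactly for planar patches) and it is additive
over any face partition. Patches crossing the plane by more than 0.1% of
their area are rejected; smaller violations are clipped to zero height —
a policy choice, since cheeks never cross the mid-sagittal plane in
practice. STVC is the plain difference of STVs, later − earlier.

Because a Gaussian bump displaces the phantom surface purely along the
projection direction as a function of the projection-plane coordinates,
its added projected volume is exactly 2πAσ², and the centroid rule
integrates the piecewise-linear interpolant exactly, so the end-to-end
recovery error at 1 mm grid resolution is ~0.01% — far inside the 3%
validation band, whose width is dominated by registration residuals in
noisy conditions.

## 5. Deviation analysis

For each reference-patch vertex, the signed distance to the closest point
on the test surface (candidate triangles from twin KD-trees over
centroids and vertices; exact point-triangle projection). Sign is
positive when the test surface lies along the reference outward vertex
normal. Correspondences beyond `max_dist` (default 10 mm, matching the
sweep half-length) are excluded from N. SD uses the population (1/N)
formula, not the n−1 estimator, so RMS² = µ² + SD² holds identically;
signed distances are used since clinical tables report negative means.

## 6. CBCT chain

DICOM series are written per-slice (explicit VR little endian, CT storage)
and read with SimpleITK's GDCM series reader, which reconstructs by slice
position, so file order is irrelevant; non-uniform slice steps are
errors. Alignment is per jaw: either a user-supplied ("manual") rigid
transform, or NCC maximization over a jaw sub-box by Powell search on the
six rigid parameters about the sub-box center. Threshold segmentation is
one inclusive window with no morphological post-processing; empty masks
warn but do not abort. Mask subtraction resamples the second mask onto
the first grid by nearest neighbour through the jaw transform. HTVC
counts change-voxel centers inside axis-aligned selection boxes ×
voxel volume; loss (present at T0, absent at T2) is negative, gain
positive, and the report carries both plus their net, summed over jaws.
At 0.25 mm isotropic spacing the sphere-removal phantom (r = 8 mm,
2144.66 mm³) is recovered to ~0.14%, consistent with the surface-voxel
error bound (≤ surface area × spacing).

## 7. Statistics

ICC(2,1) from the two-way ANOVA mean squares,

    ICC = (MSR − MSE) / (MSR + (k−1) MSE + (k/n)(MSC − MSE)),

with the McGraw–Wong F-based 95% CI (cross-checked cell-for-cell against
pingouin's ICC(A,1) row in the tests). Zero between-subject variance is
an error. The pilot sample-size rule n = ln(1−confidence)/ln(1−π) is
returned raw and at one decimal (0.90, 0.10 → 21.9); ceil(n) is the least
integer achieving the stated confidence. Estimator validation averages
ICC over 10 seeded n = 100 tables because a single table's sampling SD
(~0.026 at k = 3, plus a ~−0.02 small-sample bias) is comparable to the
0.05 validation band. Shapiro–Wilk, paired t and Wilcoxon inside
`summarize_sides` are delegated to scipy.stats; only the pairing, the
normality gate (α = 0.05) and the table layout are implemented here.

## 8. The synthetic phantoms

The face phantom is a paraboloid shell x = depth − y²/c_y − z²/c_z plus
two Gaussian vertical relief ridges (brow ridge 6 mm at z = 18, frontal
eminence 5 mm at z = 55), sampled on a regular (y, z) grid (default
0.5 mm; the validation runs use 1 mm and state so). Design constraints
that make the phantom a *valid* test of the method, chosen to mirror the
clinical geometry:

* the buccal landmark loop tops out at z ≤ 14, below the upper-third crop
  line (z ≈ 15), so deformations never enter the registration support —
  as in real anatomy, where the measured cheek is disjoint from the
  registration third;
* the medial boundary stays ≥ 12 mm lateral of the mid-sagittal plane, so
  the ±10 mm ring sweep never reaches the opposite cheek;
* the upper third carries vertical relief, as real foreheads do — without
  it the ICP information matrix has a near-null z-slide mode and no
  registration method could locate the pose under noise;
* the cheek footprint is large and flat enough that a σ = 10 mm bump fits
  with ≥ 3.72σ clearance to the boundary (truncated mass < 0.1% of
  2πAσ²). This makes the phantom cheek larger than an anatomical cheek;
  absolute STV values (~580 ml) are phantom properties, not clinical
  ones. STVC, the quantity of interest, is unaffected.

Deformations displace vertices along +y by A·exp(−((x−x₀)²+(z−z₀)²)/2σ²)
(right side only), so the analytic projected-volume change is exact.
Noise is Gaussian along vertex normals, applied to follow-up scans only.
Laser traces are exact plane sections of the T0 shell (z = 0 horizontal,
y = 0 vertical), optionally perturbed. All randomness flows through one
integer seed; equal seeds give bit-identical outputs.

The CBCT phantom is a background (50) + bone plate (1500) + tooth-like
spherical blobs (2800) grid; T2 lacks the removed blobs. Intensities sit
inside/outside the default clinical threshold window by construction.

**What the phantoms do not model:** scanner texture and holes, non-rigid
facial expression changes, hair/eyebrow interference with the lasers,
CBCT beam hardening and metal artifacts, HU calibration differences, and
operator variability in landmarking. Passing the phantom suite therefore
demonstrates correctness of the geometry and the estimators, not clinical
robustness to those artifact classes.

## 9. Validation problem sizes

The standard validation runs use: face grid 1 mm (~34k vertices),
20 seeded bumps with A ∈ [0.5, 3] mm and σ ∈ [4, 10] mm placed uniformly
in the clearance-eroded footprint, 50 ICP trials with rotations ≤ 10° and
translations ≤ 10 mm, surface noise σ = 0.2 mm (the scanner's nominal
accuracy), CBCT grids 96³ at 0.25 mm, and n = 100, k = 3 rater tables.
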
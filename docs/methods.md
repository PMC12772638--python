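# Methods

`vsreport` computes standardized imaging biomarkers for vestibular
schwannoma (VS) surveillance from longitudinal segmentation masks and turns
them into the summary documents a skull-base multidisciplinary team (MDT)
reviews.  This note records the measurement model, the parameters that
matter, the synthetic phantom used for validation, and the design choices
made where the clinical conventions are underspecified.

## Measurement model

**Inputs.** Each session supplies a 3D label mask (NIfTI) with
0 = background, 1 = intrameatal tumor (inside the internal auditory
canal), 2 = extrameatal tumor (beyond the porus acusticus).  Volumes are
reoriented to the RAS+ canonical frame on load; "axial slice" always means
a section across the third (inferior–superior) axis afterwards.  Voxels
are never resampled: anisotropic spacing is carried through every formula,
because interpolation would silently change both volumes and diameters.

**Cleaning.** Segmentation outputs can contain spurious islands.
`clean_mask` keeps the largest 26-connected component of the whole-tumor
mask (labels preserved within it) and always discards components below
`min_voxels` (default 5, i.e. sub-millimetric debris at typical spacing).
Equal-size ties break to the component with the lexicographically smaller
centroid so the operation is deterministic.

**Diameters.** The primary linear measurement is the maximum in-plane
tumor diameter, the quantity a radiologist calipers on an axial slice.
Per slice, the maximum Euclidean distance between foreground pixel centers
is computed via convex hull (Andrew's monotone chain) plus rotating
calipers; the slice with the largest value defines the measurement (ties
to the smallest slice index).  This is exact — it equals the brute-force
O(n²) maximum, which the test suite asserts bitwise by maximizing squared
distances and applying a single final square root on both routes.  The
pixel-center convention (no half-pixel padding) is used everywhere: a
single pixel has diameter zero, and a w-pixel-wide rectangle has extent
(w−1)·spacing.  Users comparing against caliper-style readings on the
rendered overlay should expect up to one voxel of difference.  Diameters
are in-plane only; 3D oblique (Feret) diameters are out of scope because
clinical reporting is slice-based.

**Volumes.** Compartment volumes are voxel counts times the voxel volume,
in cm³.  V_whole = V_intra + V_extra holds exactly by construction from
the disjoint labels.

**Meatal axis.** The intrameatal/extrameatal boundary convention (2001
consensus) requires directions "parallel" and "perpendicular" relative to
the porus / petrous ridge, but no standard defines how to extract them
from a mask.  Here the porus interface is taken as the extrameatal voxels
6-adjacent to an intrameatal voxel; their in-plane coordinates, pooled
over all axial slices, are decomposed by the eigenvectors of their 2×2
covariance.  The dominant eigenvector `u_par` runs along the porus-plane
trace (ridge-parallel) since the interface patch is wide along the plane
and one voxel thin across it; `u_perp` then points along the canal, so
d(extra,⊥) measures how far the tumor protrudes out of the porus.  The
axis is undefined for fewer than two interface voxels or an isotropic
covariance (eigenvalue gap ≤ 1e-9); this is the single largest modelling
gap and is isolated in `meatal_axis` so an alternative (e.g. a
petrous-ridge landmark) can be swapped in.

**Directional extents.** d(intra,∥), d(extra,∥) and d(extra,⊥) are
pixel-center projection ranges of each compartment onto `u_par` / `u_perp`
on the reference axial slice — the slice of the whole-tumor maximum
diameter.  A compartment absent on that slice falls back to the slice with
the most interface voxels; a compartment absent everywhere contributes 0.

## Displayed diameter

Only one diameter is shown per session to keep the report legible:

* operated tumors (postoperative, post-SRS): whole-tumor diameter D_WT —
  postoperative remnants make the compartment split unreliable;
* preoperative, entirely intrameatal: D_WT (the intrameatal region *is*
  the tumor);
* preoperative with an extrameatal portion:
  `IF d(intra,∥) ≥ d(extra,∥) → D_WT; ELSE IF d(extra,⊥) > 2 mm → D_EM;
  ELSE → D_WT`.

The function is total: if the meatal axis is indeterminate despite an
extrameatal compartment, it falls back to D_WT and records
`axis_available=False` (branch `axis_unavailable`).  The 2 mm protrusion
cutoff is a parameter (`perp_cutoff_mm`) independent of the growth
thresholds, which merely share the number.

## Growth classification

Between two sessions, significant growth requires strictly exceeding one
of the EAONO criteria: ΔD > 2 mm on the displayed diameter, ΔV > 1.2 cm³,
or ΔV > 20 % on whole-tumor volume (compartment volumes are never used
for the criterion).  Mirrored decreases classify as *reduction*.  The
*equivocal* category — present in clinical reporting but nowhere defined
quantitatively — is implemented as a configurable band: any change whose
magnitude exceeds `equivocal_fraction` × threshold (default 0.5) without
any criterion being met.  Three corner cases:

* ΔV% is undefined for a zero baseline volume (e.g. after gross-total
  resection); the remaining criteria still apply.
* If the displayed diameter *type* differs between the two sessions (DEM
  then DWT), ΔD is computed on D_WT for both and the assessment is flagged
  `diameter_basis_switched`, because serial dimensions must be comparable.
* If growth and reduction criteria fire simultaneously (diameter up,
  volume down), the status is *equivocal* rather than an arbitrary winner.

Per timeline the package reports every consecutive-pair assessment (these
drive the per-session report colors) plus the two headline comparisons
used in MDT preparation: index → latest and second-most-recent → latest.
Reduction is rendered green like no-growth; the report uses exactly three
colors (red = growth, orange = equivocal, green otherwise).

## Reports

The summary report (HTML canonical; PDF rendered via matplotlib) shows one
panel per session — axial snapshot at the displayed diameter's slice with
the mask overlay and endpoints drawn, the diameter value, the volumes — a
stacked intra/extrameatal volume bar chart, a diameter line chart on a
continuous months axis (mean month = 30.44 days), decision markers with a
legend, and the headline change table.  Volumes are suppressed on panels
whose tumor occupies ≤ 1 axial slice, where voxel counts are dominated by
partial-volume effects; the toggle `suppress_single_slice` disables the
rule.  The extended report tabulates every measurement for every session
and adds three orthographic silhouettes plus an STL surface mesh
(marching cubes) per session.

Report building is a pure function of already-computed measurements;
rendering embeds no timestamps, and the style sheet is versioned, so
identical inputs give byte-identical documents — asserted by golden-file
and double-render tests.  HTML templating is deliberately plain string
composition; the report structure is fixed, so a template engine would add
a dependency without flexibility.

## The phantom

`make_phantom` voxelizes a two-compartment analytic shape: an intrameatal
capsule (cylinder radius r, length L, hemispherical medial cap, flat cut
at the porus plane) joined to an extrameatal ellipsoid (semi-axes a along
the canal, b along the ridge, c inferior–superior), with the canal axis at
a configurable in-plane angle.  Defaults — 0.5 mm isotropic spacing,
30° canal angle, L = 10 mm, r = 4 mm, ellipsoid (9, 6, 5) mm — represent a
moderate (Koos III-scale) VS: ≈ 0.64 cm³ intrameatal, ≈ 1.13 cm³
extrameatal, D_WT ≈ 31.5 mm.  The ellipsoid center sits one voxel inside
the porus plane so the voxelized compartments stay 26-connected; the
clipped cap lies inside the capsule and the ground-truth volumes account
for it in closed form.  Ground-truth diameters come from the analytic
midplane cross-section (boundary sampling, no voxelization); the true
meatal axis is the porus-plane trace; extents are 2r, 2b and 2a − δ.

Longitudinal series scale all linear dimensions per session, so a 30 %
linear growth yields a 2.2× volume — tripping both volume criteria — and a
post-SRS pseudoprogression pattern (up then down) exercises the
red-then-green coding.  Optional `boundary_jitter` adds seeded smooth
surface noise (sum of random sinusoids, amplitude-bounded) for robustness
tests; all randomness flows from the single seed.

What the phantom does *not* emulate: MR intensities and segmentation-model
failure modes (missing slices, leakage into the cochlea), inter-session
registration differences, partial-volume label mixing, and real porus
anatomy (the interface is perfectly planar).  Passing the recovery tests
therefore demonstrates correctness of the *measurement* pipeline on known
geometry, not robustness to segmentation error.

## Numerical choices and test scale

* Tie-breaks: smallest slice index for equal diameters; lexicographic
  centroid for equal-size components; deterministic eigenvector sign
  (first nonzero component positive).
* Voxelization tolerances: for radii ≥ 10× spacing, measured diameters and
  extents agree with truth within one voxel diagonal and volumes within
  5 %; the jitter-free meatal axis is recovered within 5°.
* Connectivity: 26 for 3D components, 6 for interface detection.
* Test problem sizes: pipeline-level fixtures use 0.8–1.0 mm phantoms
  (≈ 90³ voxels), recovery tests one 0.5 mm phantom (≈ 140³); the full
  suite runs in well under a minute.

## Known limitations

* D_EM is the unconstrained in-plane maximum of the extrameatal region,
  not a measurement constrained parallel to the petrous ridge; the
  directional extents are used only inside the selection rule.
* Sessions are measured independently; no common-space registration is
  attempted (or needed for the report's content).
* The equivocal band is a package convention, not a published criterion;
  results quoting it should state the fraction used.
* DICOM ingestion, segmentation inference, Koos grading and growth-rate
  modelling are out of scope.
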
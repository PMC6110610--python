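# Methods

`centriotome` is a desk-scale re-creation of the cryo-electron-tomography
workflow used to determine centriole microtubule-blade structure: it
generates synthetic centrioles with known ground truth, images them with
a single-axis tilt scheme, reconstructs tomograms, and then runs the
analysis pipeline — sub-volume extraction, missing-wedge-aware alignment
and averaging, classification, and geometric reconstruction — whose
purpose is to recover what the generator put in.  Every quantitative
claim the package makes is a parameter-recovery statement on this
synthetic data, plus the geometric constants the model itself encodes.

## The centriole model

A centriole is nine rigid *blades* in 9-fold rotational symmetry about a
straight axis.  Each blade is one, two or three tubules:

* **A-tubule** — complete, 13 protofilaments on a 12.5 nm wall-centre
  radius, with the lattice seam between protofilaments A09 and A10
  modelled as an enlarged angular gap (default +5°).
* **B- and C-tubules** — 10 protofilaments on an 11.5 nm radius,
  attached to their parent tubule at a named protofilament pair (B to
  A10/A11, C to B06/B07), with a 3.5 nm wall overlap.  Partial tubules
  (the distal C01–C08, the incomplete B restricted to the B01–B02 and
  B07–B10 stubs) keep the complete lattice radius, so stub curvature
  equals complete-tubule curvature.

Each protofilament contributes two Gaussian blobs (σ = 1.5 nm) per 8 nm
tubulin dimer, with a 3-start helical rise (`3 × 4 nm / n_pf` per
protofilament); density is the analytic sum of blobs.  Non-tubulin
decorations — pinhead (on A03), the two A-C linker halves (A09 and
C08/C09), the fly A-A hinge (A05/A06) and wishbone (A08), the distal
L-shaped inner-junction linker (A01/A02) and A09 foot, and the luminal
MIPs (A09/A10 seam, A11, B01/B02, C01/C02) — are 1–4 blobs per instance
anchored to their protofilaments, replicated axially with a 4/8/16/24 nm
period and kept independently with their occupancy (0.5–0.95; the A09/A10
seam MIP is the most occupied at 0.95, matching its role as the only
decoration present at full contour).  The A11 MIP is proximal-only by
default; a preset flag moves it to the distal domain instead.

### Presets and calibration

Two shipped presets define the study systems:

| preset | blades | length | domains | blade radius (A-centre) | blade tilt |
|---|---|---|---|---|---|
| `cho` | triplet | 440 nm | proximal `[0, 200)`, distal `[200, 440)` | 67 / 63 nm | 50° / 35° |
| `s2` | doublet | 176 nm | single | 74 nm | 50° |

Blade tilt is the angle between the blade long axis (A→C) and the local
tangent, outward-positive.  The distal CHO blade is the proximal tilt
rotated 15° inward plus a 4 nm inward radial shift; the tilt difference
is the quantity the pipeline must recover, and the shift reflects that a
pure rotation of this blade geometry changes the envelope less than the
observed 15 nm.  The absolute tilt (50°) is a free choice — only the
proximal→distal change is constrained — and the radii are calibrated
once so that the *measurement convention* (outer envelope of the
symmetrized ensemble at 20% of maximum density) returns 235, 220 and
210 nm diameters on the ideal rasterized models.  Because 9 is odd, no
diameter chord joins two blade tips; the envelope diameter is defined as
twice the maximal above-threshold radial extent (circumscribing circle),
measured on the axially averaged, lightly smoothed section.

### Flattening

Ice-sheet flattening remaps the blade-centre circle onto an
area-preserving ellipse (semi-axis ratio `(1+e)`, `a·b = R²`); blades
stay rigid and are re-tangented to the ellipse.  The largest-to-smallest
centre-to-axis ratio is then `(1+e)²` — the quantity the refitting stage
recovers.  No target flattening value exists; flattening checks are pure
parameter recovery (default study condition e = 0.2).

### Ground truth

The generator emits a segment table: per rod and 24 nm axial position,
the segment centre, its reference-frame orientation (intrinsic ZYZ
Euler angles, reference→world; z along the rod, x along the outward
radial), the domain label and the partial-B flag.  The reference frame
is the *radial* frame, not the blade frame: the 50° blade tilt lives in
the density, exactly as a picking scheme that knows only rod geometry
would see it.

## Imaging model

Volumes are voxelized at 2 nm (whole tomograms) or 1.6–1.75 nm
(segment-level studies); the model is mounted with its axis along the
tilt axis (ice-sheet geometry).  Tilt series run +60°…−60° at 1°
(121 projections), each the linear-interpolation line integral of the
rotated volume.  White Gaussian noise is added per stack so that the
masked signal variance over noise variance equals the stated SNR
(default study condition SNR 0.5).  Reconstruction is weighted
back-projection with an exact |f| ramp filter.  No CTF, dose weighting
or alignment errors are simulated: the synthetic tilt series are ideally
aligned, so passing tests demonstrate the correctness of the analysis
chain under the missing wedge and noise, not robustness to the
calibration errors of real acquisitions.

The missing wedge is handled analytically throughout: a frequency
direction passes if its Friedel-folded (fx, fz) angle lies inside the
tilt range, and a particle's wedge in any frame is obtained by rotating
the frequency directions — no mask resampling, hence no interpolation
error on the constraint region.

## Alignment and averaging

A particle's pose is its extraction rotation/centre plus a residual
rotation and particle-frame shift.  Alignment is an exhaustive local
grid search: candidate reference rotations are precomputed and shared
across particles, shifts are scored for all offsets at once through the
FFT cross-correlation theorem, and the score is the normalized
correlation restricted to the particle's wedge ∩ low-pass band with the
DC term removed.  Ties break deterministically (smallest total angular
offset, then smallest shift, then lexicographic).  Two refinements keep
the averages sharp at these voxel sizes: cubic-spline (not trilinear)
resampling wherever content is rotated, and parabolic sub-voxel
interpolation of the shift optimum.  Defaults: ±8° at 2° per angle and
±6 nm shifts for isolated refinements; the pipeline schedule is one
wide in-plane pass (±12° at 3°, absorbing the flattening-induced offset
between the radial picking frame and the blade) followed by two ±4° at
2° passes, with a 4–5 nm low-pass during alignment only.

Averaging accumulates each sub-volume's Fourier transform at its refined
pose together with its analytically re-oriented wedge mask and divides
by accumulated coverage with a 1%-of-maximum floor.  Because rods sit at
all azimuths around the centriole, per-particle wedges are rotated
in-plane relative to the blade and their union fills Fourier space —
the property that makes the 13/10/10 protofilament architecture
countable in the average but not in any single wedge-limited segment.
Gold-standard halves are assigned by seeded shuffle then parity and are
refined independently against their own half-maps after the first
iteration; FSC uses integer-radius shells with linear interpolation at
the 0.143 crossing.

Reference-free alignment has an in-plane gauge freedom: the data-derived
reference can drift coherently by a few degrees.  All geometric
measurements are therefore made in the map's own frame — the blade axis
direction and the A-tubule centre are *measured from the average* by
matching a rigid two-ring (A+B wall) template over centre offsets and
blade angles — which makes tilt and diameter measurements invariant to
the gauge.

## Classification

Masked classification is hard-assignment EM with fixed poses: k-means on
the top principal components of wedge-filled masked voxel vectors (the
missing wedge of each particle is filled from the global average so
wedge orientation cannot drive clusters), then up to 100 rounds of
re-averaging and reassignment by masked constrained correlation, with
early exit on stable assignments and re-seeding of emptied classes from
the worst-explained particle.  This replaces a marginalized-likelihood
classifier deliberately: it is deterministic under a seed and reaches the
same qualitative endpoint (stable classes under a tight mask, no
alignment).  The partial-B class is then selected as the class with
minimal mean density inside the B03–B06 mask, and a composite centriole
is rebuilt by resampling each particle's class map at its refined pose,
averaging overlaps, and reporting runs of consecutive same-class
segments per rod.

## Geometry measurements

* **Cross-section refit** — the axis is the mean of per-rod line
  directions (a global principal component would tip into the plane when
  the 9-fold ring is wider than the sampled length); points are the
  measured A-tubule centres (segment centre + rotated map-measured
  offset); the in-plane blade angle is the rotated map-measured A→B
  direction.
* **Blade tilt** — angle between the in-plane blade direction and the
  tangent of an ellipse fitted to the rod-mean points; the
  proximal→distal change is reported inward-positive.  Evaluating the
  tangent at the A-centre ring (not the segment centre) makes the two
  domains' azimuthal offsets cancel.
* **Ellipse fits** — direct least-squares conic fits (scikit-image's
  ellipse estimator) with degeneracy guards; ellipticity is
  `100·(a−b)/a` (the alternative `100·(a/b−1)` is exposed as a second
  accessor).  Map-based wall ellipticity excludes the shared-wall sector
  toward the attached tubule, refines the wall radius sub-sample by
  parabolic interpolation, pre-filters radii to ±1.8 nm of the median
  (luminal MIP tails), and trims the worst 15% of residuals before the
  final fit.
* **Protofilament counting** — wall-maximum density per degree on an
  annulus hugging the wall radius, circular smoothing (σ = 2°), removal
  of a circular local baseline (25° minimum filter, smoothed), and peak
  counting by prominence (25% of the detrended range, ≥8° spacing).
  Detrending plus prominence rather than a global threshold keeps the
  count correct where a neighbouring tubule's shared wall raises the
  profile over whole sectors; the combination returns 13/10/10 on ideal
  triplet maps at every in-plane orientation.
* **Decoration periodicity** — the tubulin-only model is least-squares
  scaled and subtracted from a 5-heterodimer (40 nm) average; the
  residual is integrated per axial slice over a 6 nm shell around the
  tubulin envelope (central 40 nm window only, since box-edge slices
  carry extraction artefacts), and its normalized autocorrelation is
  evaluated at the 4/8/16/24 nm candidates.  The *smallest* candidate
  within 5% of the maximum is returned: a true 8 nm repeat also
  correlates at 16 and 24 nm, so the fundamental period is the shortest
  near-maximal lag.

## Study conditions (problem sizes)

The quantitative studies in `centriotome.studies` fix their conditions
once:

* Protofilament / ellipticity studies: 200 proximal-triplet segments,
  SNR 0.5, ±60° wedge with azimuth-distributed orientations, pose jitter
  uniform ±(3°, 2°, 3°) and ±2 nm, 1.75 nm voxels in 48³ boxes,
  data-derived reference, three alignment passes.
* Whole-centriole pipelines: full-length models at 2 nm voxels
  (≈ 130×230×130 voxel tomograms for CHO), ground-truth-seeded rod
  picking, 162 (CHO) / 63 (S2) particles, geometry measured per domain.
  Initial orientations are flattening-aware: the per-segment x axis
  follows the outward normal of an ellipse fitted to the traced rod
  centroids, which keeps the residual in-plane error inside the local
  search range even at strong flattening (axis-radial frames would be up
  to ~20° off at e = 0.2).  The S2 run uses the unflattened (end-on)
  geometry, since that is the configuration in which doublet-centriole
  geometry is measurable.
* Periodicity: 100 forty-nanometre segments of a bare A-tubule plus one
  16 nm-periodic surface decoration, SNR 1.
* Rod tracing: noiseless, unflattened CHO tomogram; slab-wise blade-peak
  linking after an 8 nm low-pass and mean + 2 SD threshold.

These sizes are an order of magnitude below the real datasets (~2100 CHO
and ~3000 S2 sub-volumes); they are chosen so each study completes in
minutes on one CPU while leaving the recovered quantities comfortably
inside their tolerances.

## Known limitations

* Projections are CTF-free and ideally aligned; resolutions quoted from
  synthetic FSCs are not comparable to experimental values.
* The seam is geometric only (wider A09/A10 gap plus the straddling
  MIP); α/β-tubulin identity, lattice defects and inter-dimer curvature
  are not modelled.
* Decorations are blob clusters with hand-set offsets anchored to their
  protofilaments.  Blade-to-blade linkers (A-C, A-A, the distal foot)
  are modelled as short appendages on their anchor tubules only: with
  the preset radii/tilts calibrated to the printed ensemble diameters,
  adjacent blades' anchor protofilaments sit ~50 nm apart, so full
  linker *closure* across the gap is not modelled and no measurement
  depends on it.
* The classifier is hard-assignment; class occupancy probabilities are
  not estimated.
* Flattening acts on blade centres and orientations only; real
  centrioles may deform internally at higher flattening than modelled.
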
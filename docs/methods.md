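# Methods

## Model

The package treats intrafraction prostate motion as a rigid translation of
the whole anatomy through a *static* planned dose distribution. For an OAR
voxelized as a binary mask, the constraint metric after a shift `t·d̂` is
computed by sampling the dose field trilinearly at the translated voxel
centers and counting voxels at or above the constraint's dose level
(closed `≥` bound). This equals the Boolean-AND overlap volume between the
translated structure and the isodose region on a common grid, and it is the
quantity a planning-system script computes when it converts an isodose line
to a structure and intersects it with a translated contour.

Two engines expose the same crossing:

* **contour translation** — metric evaluated at 0, 1, 2, … mm up to the
  5 mm cap; the first interval whose upper sample reaches the limit is
  linearly interpolated to the boundary point `metric = limit`;
* **dose shift** — the dose grid's origin is displaced by `−t·d̂`
  (no resampling) and the untranslated structure is evaluated at
  t ∈ {0, 2, 4, 5} mm, then interpolated identically. The unshifted
  baseline is always included so crossings below 2 mm remain bracketable.

On a static dose the two sample identical dose values, so with matched
shift grids they agree to floating-point precision ("static-dose duality"
— a test asserts < 1e−9 mm over random cases). A clinical isocentre-shift
workflow recalculates dose at each position; changes in source-to-surface
distance, attenuation and scatter are therefore *not* captured by either
engine here. Any systematic contour-vs-isocentre bias observed clinically
arises from that recalculation, which is deliberately out of scope; this
package's dose-shift engine exists to validate the geometry and the
interpolation protocol, not the beam model.

### Conventions that matter

* Coordinates: DICOM patient LPS, mm; 0-based voxel indices; voxel-center
  convention. Oblique grids are rejected at read time.
* Direction labels name the **anatomy-motion** direction (what a fiducial
  monitor displays). Planning-system shift tools label the same scenario by
  the dose/isocentre displacement, which is the negation — e.g. anatomy
  drifting anterior ≡ isocentre shifted posterior. Reports that must match
  a TPS convention should flip labels accordingly.
* Tie rule: `V_D` counts dose exactly `D` (closed bound) everywhere,
  including thresholding and the hot-spot metric.
* `D_v < d` constraints are normalized to `V_d < v cc`; the two are
  violation-equivalent, and the crossing search needs only the latter form.
* First-crossing rule: if a metric-vs-shift series is non-monotone, the
  smallest crossing is reported (conservative).
* Baseline violations return 0 mm with an explicit flag rather than an
  error: real plans may start over a limit.
* Dose outside the grid samples 0 Gy and increments a visible counter
  rather than raising — synthetic grids can be tight, clinical ones rarely
  are.

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| step | 1 mm | contour-translation increment |
| cap | 5 mm | CTV-to-PTV margin; tolerances never exceed it |
| magnitudes | 2, 4, 5 mm | dose-shift sampling (19 plan variants with baseline) |
| margin | ±0.5 mm | TOST equivalence bound (≈ half an in-plane imaging pixel) |
| α | 0.05 | significance level for both tests |
| constraint set | bladder/rectum V60<3%, V57<15% (+V54/V46/V38 parseable but excluded); urethra D0.3cc<61.8 Gy | planning protocol; the three low-dose levels are rarely approached and are excluded from tolerance derivation by default |

## Statistics

Per-cell differences (contour minus dose-shift crossing, mm) are pooled per
organ across patients, directions and constraints (urethra: 6 cells per
patient; bladder/rectum: 12, two constraints). The paired t-test reports
mean ± SD, t(df), two-sided p and 95% CI; TOST computes
`t_lower = (m + margin)/SE` against the upper tail and
`t_upper = (m − margin)/SE` against the lower tail, concluding equivalence
only when both one-sided p < α. Cells present in only one table are dropped
pairwise-complete and listed. Equivalence within the margin and a
statistically significant (tiny) bias can coexist; the TOST-CI duality
(equivalence ⟺ the 90% CI lies inside the margin) is property-tested.
Degenerate zero-variance samples are flagged and reported as limit cases.

## Synthetic phantoms

The generator emulates the *conditions* of a DIL-boost planning study, not
any patient:

* prostate: ellipsoid (22, 20, 20) mm semi-axes at the origin; dose model
  is a 60 Gy plateau over the prostate expanded by the 5 mm planning
  margin, with a Gaussian penumbra (σ = 3 mm default) outside — gradients
  similar in scale to a VMAT plan edge, with no beam physics;
* DIL: sphere (radius 5–7 mm) at a random transverse offset inside the
  prostate, boost plateau with a gentler falloff (σ = 5 mm default); the
  boost amplitude is solved so the urethra D0.3cc lands 0.3 Gy under its
  61.8 Gy limit (ceiling 66 Gy), emulating plans pushed to the constraint;
* urethra: central z-cylinder, radius 3 mm;
* bladder (anterior-superior ellipsoid) and rectum (posterior z-cylinder)
  are slid along their approach axes by bisection until baseline V60 sits
  at a drawn fraction (0.3–0.8) of the 3% limit. Percentage constraints on
  whole organs only move within 5 mm when the planning margin already
  overlaps the organ, which is exactly the near-limit situation the method
  targets; organs placed with a clearance gap never cross and produce an
  all-5 mm table.
* structures are voxelized at imaging-like resolution (1 mm in-plane, 2 mm
  slices) on their own grid; dose uses a 1.5 mm isotropic grid.

Every phantom satisfies all included constraints at baseline (asserted),
and all randomness flows from one explicit seed (bit-identical regeneration
is tested). What the phantoms do **not** model: deformable motion, organ
filling changes, VMAT deliverability, CT/PET appearance, interfraction
accumulation, and dose recalculation under shifts. Passing cohort tests
therefore demonstrates the *geometric* directional logic — posterior rectum
endangered only by motion toward the dose, urethral sensitivity oriented
toward the DIL — not clinical violation rates; cohort violation fractions
are emergent from the generator's distributions and are not calibrated to
any clinical cohort.

## Numerical choices

* Trilinear sampling is exact for affine fields; the closed-form slab
  oracle (box organ in a 1 Gy/mm gradient, crossing 3.8 mm for
  V61.8 < 0.3 cc with the posterior face at y = 3 mm) is reproduced exactly
  when the organ is supersampled (0.1 mm) along the motion axis, and the
  error decreases monotonically under refinement. With coarse organ
  voxelization the metric-vs-shift series is a staircase and the
  interpolated crossing carries an O(voxel) quantization error — the reason
  the engine samples organ voxel centers rather than re-rasterizing per
  shift, and the reason tests that need sub-0.1 mm accuracy refine the
  organ grid, not the dose grid.
* Contour rasterization uses even-odd polygon fill at voxel centers (holes
  supported); contours attach to the nearest slice within half a slice
  spacing, else they are dropped with a warning.
* Fixture bundles store dose as little-endian float64 and masks as uint8,
  one geometry per structure, so write→read round-trips are bit-exact.
* Problem sizes: the shipped cohort uses 20 phantoms on 61×71×71 dose
  grids; the full suite and the acceptance script each complete in well
  under a minute on one CPU, so the study conditions are run unreduced.

## Known limitations

Rotations and deformations are out of scope (cardinal translations only).
Equivalence with any specific TPS's DVH values is not claimed: the
voxel-sampling rule of commercial DVH engines (supersampling, partial
volumes) is vendor-specific, and the package standardizes on trilinear
sampling at voxel centers instead. The dose-shift engine validates geometry
and interpolation, not beam-model effects of a true isocentre shift.
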
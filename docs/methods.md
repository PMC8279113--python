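# Methods

This note documents the measurement model, the statistical toolkit, the
synthetic-data generator, and the numerical and design choices behind
`orthotrig`.

## Measurement model

**Input.** Five landmarks per tooth (lingual gingival, mesial, distal,
occlusal, vestibular gingival), as 3D coordinates in millimetres, for one
arch at one or two timepoints. Landmarks may come from a landmark CSV or
from an IGES export of picked points (Type-116 entities plus an identity
manifest).

**Reference frame.** The occlusal reference plane (Plane 1) is the
orthogonal-distance (total-least-squares) plane through the
lingual-gingival landmarks of all teeth except second molars: gingival
points move less with inclination changes and with the curves of Spee and
Wilson than incisal edges or cusp tips, and second molars are the noisiest
and most frequently absent units. The normal is oriented towards the mean
occlusal landmark (occlusal = +Z). The median plane (Plane 2) is
perpendicular to Plane 1; two constructions are offered:

* `incisor_midpoint` (default): Plane 2 contains the Plane-1 projections
  of (a) the midpoint of the central incisors' mesial landmarks and (b)
  the lingual-gingival centroid. This is intrinsic to the dentition and
  reproducible across scanners, so it is the default.
* `native_xz`: Plane 2 is perpendicular to Plane 1 and to the scanner's
  native XZ plane. This matches a common convention in mesh-inspection
  software but inherits the export orientation; offered for comparability.

The frame is right-handed: Z = Plane-1 normal, Y = in-plane anterior
direction (towards the incisors), X = Y × Z (lateral). The origin is the
lingual-gingival centroid. Whether +X is the patient's right or left
depends on the arch; all reported angles are geometric, and movement
deltas are invariant to these sign choices up to a global sign.

**Angles.** With (x_m, y_m), (x_d, y_d) the frame-XY coordinates of the
mesial and distal landmarks:

* rotation α = atan2(x_m − x_d, y_m − y_d) ∈ (−180°, 180°] — the signed
  angle from +Y to the distal→mesial direction, positive towards +X.
* Before the tipping angles are read, the tooth's five landmarks are
  rotated about Z by the matrix that maps the distal→mesial direction onto
  +Y (the per-tooth "rotational reset"). This makes inclination and
  angulation exactly invariant under any rotation of the tooth about the
  frame Z axis through any pivot — a property the test suite asserts at
  1e-9°.
* With v = occlusal − vestibular gingival in realigned coordinates:
  inclination = atan2(v_x, v_z) and angulation = atan2(v_y, v_z). A full-
  quadrant arctangent is used throughout (a plain arctangent of coordinate
  ratios is sign-ambiguous). If v_z ≤ 0 (crown vector not pointing
  occlusally) a warning is logged and the angles are still returned, since
  this almost always indicates swapped landmark identities.

**Deltas.** Δ = final − initial per tooth and movement. Both models are
measured in the single frame built on the initial model. When the two
models live in different coordinate systems, the final model is first
carried into the initial model's space by a whole-arch rigid best fit
(`align=True`): exact-correspondence Kabsch over the concatenated
landmarks of all shared teeth except second molars. This landmark Kabsch
substitutes the dense-surface best fit of mesh-processing suites; on
landmark data with true rigid motion the substitution is exact, and the
tests construct exactly that situation. Δrotation is wrapped to
(−180°, 180°]; the tipping deltas are plain differences (their magnitudes
stay below 90° for anatomically oriented teeth). Synthetic paired models
are generated in one common space, so the recovery and invariance checks
use `align=False`; with per-tooth movements present, a whole-arch fit
would redistribute a small part of each tooth's movement into a global
motion, which is a property of the alignment step, not of the trigonometry.

## Agreement statistics

For paired series a (reference) and b (method), d = a − b:

* **Bland-Altman**: bias = mean(d); SD with n−1 denominator; limits of
  agreement = bias ± 1.96·SD (the conventional normal multiplier, not a
  t-quantile — this choice reproduces published tables exactly); 95% CI of
  the bias uses the Student t quantile with n−1 df; one-sample t-test of
  the bias against zero (NaN when SD = 0).
* **Dahlberg index** D = √(Σd²/2n), the standard random-error magnitude
  for duplicate measurements.
* **ICC(A,1)** — single measurement, absolute agreement — from the two-way
  ANOVA mean squares: (MSR − MSE)/(MSR + (k−1)MSE + (k/n)(MSC − MSE)).
  The point estimate is identical for the two-way random and two-way mixed
  models; the model is recorded for reporting. Confidence intervals use
  the McGraw-Wong F-based procedure with a Satterthwaite df for the
  denominator. The implementation is from the definitional formulas; the
  test suite cross-checks it against an independently assembled
  brute-force ANOVA (1e-10) and against `pingouin`'s ICC(A,1).
  Degenerate inputs: constant data → NaN (undefined); perfect agreement
  with subject variance → ICC = 1 with a collapsed CI.

Report tables round half-even to 2 decimals; all internal computation is
at full precision.

## Synthetic cohort generator

The generator emulates the study design of an aligner cohort: paired
initial/final-planned arch models with known per-tooth movements.

* **Arch form**: a parabola (default 60 × 45 mm upper, 54 × 40 mm lower —
  typical adult dimensions; configuration, not claims). 14 teeth per arch
  (central/lateral incisors, canines, two premolars, two molars per side);
  a 14-patient, two-arch cohort gives 392 teeth, the scale of a real
  ~386-tooth sample with a few missing units.
* **Crown templates** per tooth type (mesiodistal width, crown height,
  gingival offset; mm): incisor 7.0/9.0/3.0, canine 7.5/9.5/3.5, premolar
  7.0/8.0/3.5, molar 10.0/7.5/4.5. Teeth stand upright: the
  lingual-gingival points lie exactly in z = 0 (so the fitted occlusal
  plane is exact at zero noise) and the occlusal landmark sits
  crown-height directly above the vestibular-gingival one, so an unmoved
  tooth measures inclination = angulation = 0. The occlusal point is
  therefore an on-buccal-cusp pick rather than a crown-centre pick — a
  deliberate template choice that pins the zero of both tipping angles.
* **Movements** are applied per tooth about its landmark centroid in frame
  coordinates: buccolingual tip about the local mesiodistal axis, then
  mesiodistal tip about the local buccolingual axis, then rotation about
  frame Z, then translation. Measured tipping angles are projection
  angles, not Euler components, so the applied buccolingual tip is
  pre-compensated (θ_applied = atan(tan θ · cos φ)); `PlannedMovement`
  angles then sit exactly on the measurement scale for upright template
  teeth, and zero-noise recovery of combined movements is exact. For teeth
  that are already tipped the compensation is approximate and small
  cross-terms remain.
* **Noise**: isotropic Gaussian per landmark coordinate, default
  σ = 0.05 mm, emulating point-picking error; drawn independently for the
  two timepoints (two picking sessions). Default random movement
  distribution per tooth: rotation ~ N(0, 5°), tipping ~ N(0, 3°),
  translation ~ N(0, 0.3 mm) per axis — mild-crowding setup magnitudes.
  All generation is reproducible from (spec, seed); per-replicate streams
  are derived with `numpy.random.SeedSequence`.

**What passing tests show — and don't.** The generator produces landmarks
that move exactly rigidly per tooth, with ideal correspondence and
isotropic noise. Real digitised models add surface-pick ambiguity
(landmarks re-picked on a surface, not transported), anatomical variation
of crown shape, reference-plane instability between timepoints when the
treatment changes the gingival architecture, and operator bias. The
recovery and invariance results therefore validate the trigonometry and
the software, not the clinical accuracy of the method; clinical validity
requires comparison against an external standard, which is what the
agreement toolkit is for.

## Numerical choices

* Collinearity/rank tests use a relative second-singular-value threshold
  of 1e-9 (plane fitting, Kabsch cross-covariance).
* Kabsch excludes reflections by sign-flipping the smallest singular
  direction.
* Frame invariants are enforced at construction: orthonormal rows to
  1e-9, det = +1.
* Angle wrapping maps to (−180°, 180°], with −180° normalised to +180°.
* Degenerate teeth (mesiodistal XY projection or crown vector < 1e-9 mm)
  raise an error naming the tooth; batch measurement can optionally skip
  and log them instead.

## Problem sizes

The test suite and the acceptance script run at desk scale by design: the
oracle comparisons use 100-1000 random candidates, the invariance checks
100 rigid transforms, and the noise-ladder ICC a 36-patient, two-arch
cohort (1008 teeth) at σ = 0.05 mm. Published headline ICC/Dahlberg values
from clinical cohorts depend on the patients' actual movement
distributions and cannot be recomputed without that data; the
reproductions here therefore target the arithmetic of the published
agreement tables (which is fully determined by printed mean, SD and n)
plus the constructive properties above.

## Known limitations

* The median-plane construction is under-determined by common verbal
  descriptions ("a median reference plane"); both offered modes are
  documented, and results that depend on X/Y axis placement (inclination
  vs angulation split) should state the mode used.
* Landmark-based Kabsch requires the same five landmarks on both models;
  there is no surface re-projection.
* Clinical sign conventions (mesial tip positive, buccal torque positive,
  etc.) depend on arch side and are intentionally not encoded; users map
  geometric signs to clinical ones per quadrant if needed.
* IGES support is read-only and limited to Type-116 point entities.
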
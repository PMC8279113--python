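# orthotrig

Trigonometry-based measurement of **tooth rotation, inclination and
angulation** on digital dental models, for longitudinal comparisons
(initial vs planned/achieved setups) in orthodontic research — plus the
agreement statistics used to validate such measurements (Bland-Altman,
Dahlberg, ICC).

Five landmarks are picked per tooth — *lingual gingival, mesial, distal,
occlusal, vestibular gingival* — and everything else is computed from their
3D coordinates (mm):

1. **Reference frame.** Plane 1 (occlusal reference) is the total-least-
   squares plane through the lingual-gingival landmarks of all teeth
   except second molars; Plane 2 (median plane) is perpendicular to it.
   The Cartesian space is reoriented so XY ≡ Plane 1 and YZ ≡ Plane 2.
2. **Rotation.** α = atan2(x_m − x_d, y_m − y_d): the signed angle between
   the distal→mesial line (projected on XY) and the anteroposterior Y axis.
3. **Rotational reset.** Each tooth is realigned about Z so its mesiodistal
   line coincides with Y — this removes the influence of rotation on the
   tipping angles.
4. **Inclination & angulation.** With **v** the vestibular-gingival →
   occlusal crown vector in realigned coordinates:
   inclination = atan2(v_x, v_z) (buccolingual tip, XZ projection vs Z) and
   angulation = atan2(v_y, v_z) (mesiodistal tip, YZ projection vs Z).
5. **Deltas.** Δ = final − initial per tooth and movement, both models
   measured in the single frame built on the initial model (the final
   model is first carried into that space by landmark-based rigid best fit,
   Kabsch).

Sign conventions (all signs depend on them; they are geometric, not
clinical): Z points towards the occlusal surfaces, Y anteriorly, X = Y × Z
(right-handed); rotation is positive from +Y towards +X, so a right-handed
rotation about +Z *decreases* α. Δs are convention-independent up to a
global sign.

## Worked example

```python
import orthotrig as ot

spec = ot.ArchSpec(arch="upper", noise_sd_mm=0.05, seed=11)
initial = ot.generate_arch(spec)
frame = ot.build_reference_frame(initial)
moves = [ot.PlannedMovement(13, rotation_deg=8.0),
         ot.PlannedMovement(24, inclination_deg=-4.0, angulation_deg=2.0)]
final = ot.apply_movements(initial, moves, frame)
_, mi, mf, deltas = ot.measure_pair(initial, final, align=False)
```

prints, for the moved teeth (degrees):

```
tooth  d_rot    d_inc    d_ang
13     8.000    0.000    0.000
11     0.000    0.000    0.000
24     0.010   -4.000    1.999
```

Tooth 13's planned 8° rotation is recovered exactly; tooth 24's combined
tip comes back to within ~0.01° (landmark noise makes the tooth slightly
non-upright, leaving a small projection cross-term).

Agreement statistics reproduce published Bland-Altman arithmetic from a
sample's mean/SD — e.g. differences with mean 0.98°, SD 2.27°, n = 28
(a maxillary-canine rotation validity row):

```python
s = ot.bland_altman(ot.PairedSample.from_diffs(d))
# bias=0.98  CI=(0.10, 1.86)  LoA=(-3.47, 5.43)  p=0.03
```

## Command line

```bash
orthotrig simulate --out sim --patients 14                      # synthetic cohort
orthotrig measure sim/landmarks_initial.csv mi.csv              # per-model angles
orthotrig measure sim/landmarks_final.csv mf.csv \
    --frame-from sim/landmarks_initial.csv                      # same frame
orthotrig delta mi.csv mf.csv deltas.csv                        # final - initial
orthotrig agreement deltas.csv sim/planned_movements.csv stats.csv
orthotrig icc ratings.csv icc.csv --model two_way_mixed
orthotrig extract-iges scan.igs manifest.csv landmarks.csv      # IGES import
```

IGES import reads Type-116 (point) entities only; a sidecar manifest CSV
maps point order to (patient, arch, timepoint, tooth, landmark), because
IGES labels do not reliably carry identity. All other tables are plain CSV
with documented headers (`orthotrig.model_io`).

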
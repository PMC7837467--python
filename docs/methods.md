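# Methods

`jawmotion` quantifies how accurately a planned bimaxillary operation with
genioplasty was executed: for each osteotomized segment — maxilla,
mandible, osseous chin, left and right ramus — it compares the rigid
motion prescribed by the virtual surgical plan with the motion actually
realized between the pre- and post-operative (CB)CT scans, and reports
both as six clinical parameters per segment.

## Coordinate conventions and the 6-DOF readout

All motions are expressed in the natural head position (NHP) frame with
the upper incisor point at the origin: `+x` patient-left (RL), `+y`
anterior (AP), `+z` superior (SI), world coordinates in mm (DICOM LPS
convention internally; NIfTI RAS affines are converted at load). A
segment's motion is parameterized about its anatomical rotation point `p`
as

```
x  ->  R (x - p) + p + t
```

with `t = (t_rl, t_ap, t_si)` in mm and `R = R_roll · R_pitch · R_yaw`
(fixed-axes composition; pitch about `x`, roll about `y`, yaw about `z`,
right-hand rule, degrees). Rotation points: upper incisor for the
maxilla, pogonion for mandible and chin, the most cranial condylar point
for each ramus. The decomposition is the exact inverse of the
parameterization away from gimbal lock; |pitch| ≥ 89.9° raises an error
rather than returning meaningless yaw/roll (such a motion is far outside
surgical range). The Euler order and signs are a documented convention:
any fixed order is internally consistent as long as composition and
decomposition share it.

Reported *difference* is the parameter-wise `achieved − planned`,
matching the three-column clinical report; decomposing the residual
transform instead would mix rotation-point effects into translations and
is not the default.

## Pipeline

1. **NHP alignment.** The planning export's 4×4 matrix (XML) maps the
   scanner frame to NHP; composed with the incisor shift it defines the
   analysis frame. Volumes are re-expressed by metadata transform only —
   no resampling.
2. **Planned motion.** Planning software moves segments rigidly, so the
   original and planned STL of a segment usually share vertex topology;
   the planned transform is then the closed-form orthogonal Procrustes
   solution (exact to machine precision). Mismatched topology falls back
   to trimmed ICP.
3. **Global alignment.** The post-operative scan is rigidly registered to
   the pre-operative scan on the cranial-base ROI (anterior cranial base,
   forehead, zygomatic region) — the anatomy surgery does not touch.
4. **Achieved motion, bony segments.** For maxilla, mandible and both
   rami, voxel-based matching (VBM) registers the pre-operative scan onto
   the globally aligned post-operative scan inside a per-segment ROI box
   placed around the segment's planned position, initialized at the
   planned transform. Rami report rotations only (autorotation =
   pitch-axis, flare = yaw-axis, roll), decomposed about the condylar
   point, under the assumption that the condylar heads do not translate.
5. **Achieved motion, chin.** Surface-based matching (SBM): bone
   isosurfaces are extracted from both scans inside chin ROI boxes, the
   matching region is selected (below), vertices near high-density
   fixation material are excluded, and a trimmed point-to-plane ICP
   aligns the pre-operative chin surface to the post-operative one.
6. **Chin correction.** The genioplasty segment is plated to the distal
   mandible, so mandibular execution error carries over to the chin. With
   `E_m = achieved_mandible ∘ planned_mandible⁻¹`, the corrected chin
   transform `E_m⁻¹ ∘ achieved_chin` isolates the chin's own error; the
   two algebraic identities (exact mandible execution leaves the chin
   untouched; a chin rigidly carrying `E_m` shows zero difference) hold to
   machine precision and are tested at 1e-12.

## Voxel-based matching

Mattes mutual information (50 bins) over a 3-level pyramid (shrink 4/2/1,
smoothing 2/1/0 voxels), regular-step gradient descent on a 6-parameter
rigid transform, scales from physical shift, ≤200 iterations per level.
MI is used because pre- and post-operative scans routinely come from
different scanners and protocols, so grey values need not correspond —
CBCT grey values are treated as uncalibrated throughout and every
intensity threshold is configuration. Metric samples are drawn randomly
(default 10 % of ROI voxels, seeded for bit-reproducibility) with a
minimum-sample floor (default 5000) so the coarse pyramid levels of small
segment ROIs keep a stable MI estimate. The ROI restricts the *fixed*
image through an exact box mask; plain index-space cropping of a box that
is oblique to the voxel grid would silently include out-of-box voxels,
which measurably biases small-segment registrations.

## Surface-based matching

The chin match uses trimmed ICP (default trim fraction 0.9, 10 mm
correspondence gate). The default variant is **point-to-plane**: on two
independently triangulated (marching-cubes) surfaces there are no true
point correspondences, and point-to-point ICP both slides tangentially on
the smooth caudal surface and snaps to the voxel-edge vertex lattice —
errors above 1 mm / 3° on the phantom, against < 0.1 mm / 0.1° for
point-to-plane. Convergence and pose ranking use the point-to-plane
residual RMS for the same reason; iterations stop on a plateau of the
best residual (re-trimming makes the raw sequence limit-cycle at
sub-micrometre amplitude). Point-to-point (Kabsch) remains available and
is the right tool when exact correspondences exist.

The matching region emulates the interactive painting step
non-interactively and reproducibly: a lateral `|x|` band keeps mandible
wall fragments inside the chin ROI box out of the search; adaptive bands
then select the lowest few mm of the remaining surface (the unaltered
under-side of the chin) plus the most anterior few mm within a fixed
depth of the bottom (the anterior cortex below the plate). The bands are
measured on the surface itself, so they follow the segment wherever the
operation put it; the anterior patch is what constrains pitch, clinically
the most observer-dependent chin parameter. Plate exclusion (vertices
whose 2 mm neighbourhood contains voxels above 75 % of the plate
intensity) runs before the bands so they are measured on bone, not on the
isosurface bump over the plate.

## The synthetic skull phantom

The phantom provides every input of a case with the full ground truth on
record. It is stylized, not anatomical: a cranial vault shell with
forehead block and zygomatic bars (static reference), a maxillary block
with a tooth ridge carrying the incisor landmark, a mandibular horseshoe,
a rounded chin wedge (an ellipsoid cut by the horizontal genioplasty
plane — the curvature is what makes a surface match well-posed), and two
rami (slab + condylar sphere + coronoid-like process; the asymmetric
process anchors all three rotation axes). A high-density plate sits on
the anterior chin in the post-operative volume only. A wide soft-tissue
ellipsoid surrounds everything; it is deliberately wide enough that its
static air boundary stays out of the moving-segment ROI boxes, because a
static high-contrast edge inside a segment ROI measurably pulls that
segment's registration (up to ~0.5° on the rami before the change).

Intensity classes air 0, soft tissue 60, bone 700, teeth 1400, plate
3000 (HU-like but uncalibrated); solids are voxelized at 2× supersampling
and average-pooled (partial volume), blurred with a 0.6-voxel Gaussian,
and corrupted with seeded additive Gaussian noise (σ = 20). The same
spec reproduces bit-identical volumes. Transformed segments are checked
for mutual overlap at supersample resolution; a collision raises rather
than producing an ambiguous phantom.

The canonical validation case (`default_validation_case`) is 160³ voxels
at 0.5 mm with clinically typical planned moves — maxilla AP +4 mm,
SI −2 mm, yaw +2°; mandible AP −3 mm, pitch +3°; chin AP +5 mm, SI −1 mm;
ramus rotations ≤ 3° — executed with per-parameter errors drawn uniformly
within ±1.5 mm / ±1.5°. The chin's executed motion additionally rides on
the mandibular execution error, as a plated genioplasty segment does, so
its corrected difference equals its own injected error exactly. The scan
pose (what the NHP matrix undoes) is a seeded small rigid offset (≤3°,
≤4 mm).

What the phantom does *not* emulate: real cranial anatomy, scanner
physics (beam hardening, scatter, rings), motion artifacts, occlusion
errors, metal streaks beyond a bright block, or soft tissue that deforms
with surgery. Passing tests therefore demonstrate the correctness and
stability of the measurement chain under known rigid ground truth with
CT-like contrast, noise and partial volume — not clinical accuracy on
patient data, which is bounded instead by the observer-variability scale
used for the tolerances below.

## Reliability statistics

Observer studies are summarized by single-measure intraclass correlation
coefficients computed from the two-way ANOVA mean squares of the
subjects × raters table: ICC(2,1) (two-way random, absolute agreement)
for inter-observer comparisons, ICC(3,1) (two-way mixed, consistency) for
intra-observer repeats, plus the mean (±SD) absolute difference between
two raters. Single-measure forms are used because individual observers'
single runs are compared. Degenerate tables (zero variance) raise rather
than returning a conventional value.

## Tolerances and problem sizes

End-to-end recovery on the canonical phantom is required within 0.3 mm
and 0.5° (0.7° for chin rotations) — the scale of inter-observer
variability reported for this class of tool, i.e. the pipeline is held to
be as accurate against ground truth as trained observers are consistent
with each other. Routine tests run a reduced 112³ / 0.7 mm phantom with
voxel-scaled bounds (the ~20 mm chin is too coarsely resolved below that
for surface matching to be meaningful); the full 160³ / 0.5 mm case is
exercised by the acceptance suite and `scripts/acceptance.py`. The
miniature reproducibility study (10 phantom cases × 2
registration-sampling seeds, reduced size) mirrors the design of a
two-rater validation study and is required to give ICC > 0.92 on every
parameter.

## Known limitations

* Rigid motions only; segment remodelling/relapse between scans violates
  the model and surfaces as residual RMS / metric degradation, not as an
  explicit warning.
* The chin matching bands assume the caudal and anterior chin cortex are
  unaltered; an unusual plate covering most of the anterior cortex would
  shrink the selection (an error is raised below 100 vertices).
* ROI boxes are user (or phantom) supplied, not proposed automatically;
  a box that includes structure moving with a different segment degrades
  that segment's VBM.
* The vendor XML schema is a minimal own dialect (16 row-major floats
  under `<transform>`); planning-software exports need a registered
  parser hook.
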
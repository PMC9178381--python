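# Methods

This note documents the conventions, models and numerical choices behind
`archopose`, and what the synthetic test fixtures do and do not
establish.

## Scope and assumptions

The package quantifies poses *between* the four major hindlimb segments
(pelvis, femur, crus, pes) of archosaur-grade bodyplans. It assumes:

* **Static morphology.** Coordinate systems derive from a single scanned
  configuration of the bony skeleton; no motion data are needed to build
  them, so fossils, mounts and cadavers are all admissible inputs.
  Methods that need movement (helical/instantaneous axes) are out of
  scope by design.
* **Bone, not cartilage.** Patches are selected on the ossified surfaces.
  Cartilage-inflated models would flow through the same code path with
  different patches but are not treated here.
* **Rigid segments.** Each segment is one rigid body per frame. The one
  deliberate exception is the unfused crocodylian-style foot, where the
  pedal coordinate system is recomputed each frame from tracked
  metatarsal condylar landmarks (see below); intra-segment motions
  (patella, fibula–tibia, individual metatarsal LAR) are not measured.

Units are millimetres and degrees throughout; configs may declare cm/m
inputs, converted on read. Transforms map segment-local to world
coordinates, rotation before translation. Meshes and patch files are
0-based internally; OBJ's 1-based indices are converted at the file
boundary only.

## Primitive fitting

Spheres, cylinders and planes are fitted to patch vertices by minimising
squared orthogonal distance to the surface:

* **Sphere** — algebraic (Coope) linear solve, then Gauss–Newton/LM
  refinement of `Σ(|p−c|−r)²` (scipy `least_squares`, xtol/ftol 1e-12,
  ≤1000 evaluations). Requires ≥4 non-coplanar points.
* **Cylinder** — parameterised by axis direction (two spherical angles),
  a 2-D point in the axis-normal plane, and radius. Each of the three
  principal directions of the patch seeds a candidate (algebraic circle
  fit in its normal plane) and each candidate is refined to convergence;
  the lowest-residual solution wins. Refining all three candidates
  instead of trusting the algebraic score keeps short, noisy
  condyle-like patches out of perpendicular-axis local minima while
  staying fully deterministic (no random restarts). The reported
  *centroid* is the midpoint of the extremal projections of the patch
  vertices onto the fitted axis line — a reproducible, mesh-extent-aware
  stand-in for the loosely defined "centroid of the cylinder". A warning
  is raised when the patch subtends <30° of arc about the axis, where
  the radius/axis trade-off becomes weakly identified.
* **Plane** — total least squares (smallest principal direction). The
  origin is the *area-weighted* face centroid projected onto the plane,
  so sliver triangles cannot bias it; vertex mean is the fallback when
  no faces are given.

Fitted axes and normals are direction-ambiguous. All anatomical signs
("axis positive laterally", "positive cranially") are resolved by
per-patch unit `reference_direction` vectors carried in the patch file:
the fitted axis is flipped to positive dot product. Reference directions
are used *only* for sign resolution and sanity assertions, never for
axis geometry, keeping the axes purely morphology-derived.

## ACS construction

Each segment reduces to a T-shaped pair of principal vectors: an
intercentroid long axis and a transverse axis. The two are *not*
re-orthogonalised against each other; orthogonality enters only through
cross products. The pattern for femur and crus (identical code path):

```
right: X_prox = unit(origin_dist − origin_prox)      (left: reversed)
       Z_dist = fitted cylinder axis                 (sign per side)
       Y      = unit(X_prox × Z_dist)                (shared by both ACSs)
       X_dist = Y × Z_dist
       Z_prox = X_prox × Y
```

The pelvis uses the interacetabular vector as `pelvicACSm_Y` (positive
to the right), `Z = Y × sacral axis` (dorsal), `X = Y × Z` (caudal);
both `hipACSf_Z` point to the animal's left, with the crossing order
against the sacral axis reversed between sides. The pes builds a single
`ankleACSm` from the proximal plane centroid, a distal point, and a
transverse axis; `Y = X × transverse`, `Z = X × Y`.

Left-side recipes reverse every subtraction/crossing order the standard
specifies, so that anatomically equivalent *rotations* measure with
equal magnitude and sign on both sides. A corollary worth knowing: the
fixed-ACS axes then point in opposite anatomical directions on the two
sides, so mirrored *translations* measure negated.

Construction fails loudly when the two principal vectors are within 5°
of parallel — below that the cross products are numerically unstable,
and no anatomically sensible T is that degenerate.

### Pedal variants

* **Static** (fused or tightly bound metatarsals, e.g. the avian
  tarsometatarsus): distal point and transverse axis come from a
  cylinder fitted to the condyle of metatarsal III. The standard leaves
  the MT-III axis sign unstated; this package resolves it
  right-positive-laterally / left-positive-medially, matching the rule
  given for the dynamic transverse axis, so the two variants coincide
  when the foot does not spread.
* **Dynamic** (unfused metatarsals): the distal point is the midpoint of
  the outermost metatarsal condylar landmarks and the transverse axis
  runs medial→lateral on the right (reversed on the left), recomputed
  every frame from tracked world positions. Any consistently trackable
  landmark pair on the outermost metatarsals is accepted; the pose
  output records which pair was used via the landmark file.

## JCS decomposition

With `F`, `M` the world frames of ACSf and ACSm, `R_rel = Fᵀ M` is
decomposed as intrinsic Z-Y-X: `R_rel = Rz(FE)·Ry(ABAD)·Rx(LAR)`.
ABAD is extracted as `atan2(−R₃₁, √(R₃₂²+R₃₃²))` — the atan2 form stays
well-conditioned as |ABAD| → 90° where asin loses half its digits — and
FE/LAR by two-argument arctangents. Translations are `Fᵀ(o_M − o_F)`,
i.e. components along the fixed ACS axes (the JCS axes themselves need
not stay mutually orthogonal, so they are not used for translations).

* **Gimbal lock.** When `|cos ABAD| < 1e-8` the Z and X axes are
  collinear and only FE+LAR is determined. The decomposition reports FE
  carrying the determined sum, sets LAR to 0 (a convention, since the
  standard prescribes no tie-break) and raises `gimbal_flag`. Poses are
  flagged, never re-parameterised.
* **Forward kinematics.** `compose_pose` inverts the decomposition for
  |ABAD| < 90° and rejects poses at or beyond the principal range. The
  reference pose is assembled proximal-to-distal by registering each
  ACSm exactly onto its parent's world ACSf (pelvis onto the ground
  ACS); bone interpenetration in this collapsed configuration is
  expected and permitted.
* **Ground ACS.** Z is exactly world-up; the horizontal heading is
  user-defined. The pipeline default is the *negated* mean horizontal
  travel direction of the pelvis over the trial: `pelvicACSm_X` points
  caudally, so with this default a level, forward-travelling pelvis
  reads near-zero yaw. The heading used is recorded in the reference
  report.
* **Angle continuity.** `unwrap_deg` removes ±360° jumps for plotting;
  principal values are always what is stored.
* **Singularity location.** `find_singularity_angle` sweeps ABAD upward
  through `compose_pose`, brackets the first angle where the world-frame
  angle between JCS_Z and JCS_X (folded to [0°, 90°]) drops below
  1e-6 rad, then polishes with secant iteration. The misalignment is
  exactly 90°−|ABAD| for a ZYX JCS, so the iteration converges to the
  singular angle to ~1e-9°.

## Synthetic limbs: what they emulate, and what they do not

`LimbBlueprint` builds bones as unions of primitive-capped surfaces —
sphere caps, partial cylinders, planar disks, connecting tubes — so
every labelled patch lies *exactly* on a known primitive before noise.
Defaults are guineafowl-scale study conditions, chosen once:

| parameter | default | why |
|---|---|---|
| femur / crus / pes length | 80 / 90 / 55 mm | adult *Numida* proportions |
| head sphere radius | 10 mm | ~1/8 femur length |
| condylar cylinder radius / half-length | 8 / 11 mm | roller-like distal femur |
| condylar skew | 15° | visibly skewed avian condyles; drives the non-parallel dorsal-view reference pose |
| metatarsal condyle radius / half-length | 4 / 4.5 mm | smallest primitive in the chain |
| outermost-metatarsal half-span | 12 mm | sets the dynamic transverse baseline |
| mesh resolution | 96 subdivisions | ≈10³ vertices per patch — the conservative low end of microCT-derived patch selections, which run to many thousands of polygons |
| noise | Gaussian, per-vertex, isotropic | `noise_sd` in mm, 0 by default |

Right-side bones live in local frames with +x cranial, +y medial,
+z proximal (pelvis: +y left, +z dorsal); left bones are sagittal mirror
images with winding flipped and reference directions re-derived, which
is what drives the left/right convention tests. Gait scripts are
sinusoidal per-joint six-DOF trajectories capped at |ABAD| ≤ 85° (the
singularity stress flag lifts the cap); animation is plain forward
kinematics through `compose_pose`, with optional per-frame rotation of
the outermost condylar pair about the pedal long axis to emulate
intermetatarsal spread.

What passing tests on these fixtures shows: the geometry, conventions
and kinematic machinery are internally consistent and invert each other
at tight tolerance, and primitive recovery behaves as theory predicts
under isotropic noise at realistic patch density. What they do **not**
show: robustness to the failure modes of real data — subjective patch
selection, segmentation artefacts, anisotropic scan noise, cartilage,
taphonomic deformation, soft-tissue tracking error. The bones are
unions of primitives, not statistical shape models; a patch that is
exactly cylindrical is the best case for a cylinder fit.

## Numerical choices

* Orthonormality/right-handedness of every ACS asserted at 1e-9;
  rotation validity (orthogonal, det +1) at 1e-8 on input transforms.
* Fits refine to relative tolerance ~1e-12 with ≤1000 residual
  evaluations, deterministic initialisation only.
* Pose CSVs are written at 17 significant digits, so write→read round
  trips are lossless to well below 1e-9.
* Quaternions (w, x, y, z; scalar first, w ≥ 0) are the on-disk rotation
  dialect: unlike raw matrices they cannot drift off the rotation
  manifold through text round trips. A row-major matrix dialect is
  accepted on read.
* Degenerate inputs (coplanar sphere patches, collinear plane patches,
  coincident centroids, near-parallel principal vectors) raise typed
  errors rather than returning garbage; narrow cylinder arcs warn.

## Known limitations

* No arbitration between alternative condyle-homology patch sets: the
  pipeline accepts whichever patch file it is given; run it once per
  hypothesis and compare.
* FE/LAR at gimbal lock carry only their sum; downstream statistics on
  flagged frames must respect that.
* The end-to-end recovery bound (0.5° at ≤0.5% bone-length mesh noise)
  is demonstrated at the default patch density; much sparser patches
  degrade cylinder-axis estimates first, on the smallest condyles.
* Metatarsophalangeal joints, distal tarsals and intra-segment DOFs are
  out of scope; the pedal ACS summarises the whole foot segment.
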
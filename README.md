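# archopose

Quantifying 3-D hindlimb joint poses in archosaurs (birds, crocodylians
and their extinct relatives) requires a shared convention: without one,
"45° of hip flexion" means something different in every lab. `archopose`
implements a standardised, morphology-derived workflow for turning bone
surface models plus rigid-body tracking data (e.g. XROMM output) into
comparable six-degree-of-freedom joint pose tables for the pelvis, femur,
crus (shank) and pes (foot).

The workflow, in the field's standard notation:

1. **Primitive fitting.** Articular surface patches — subsets of a bone
   model's polygons — are fitted with geometric primitives by least
   squares: spheres (femoral head, acetabula), cylinders (femoral and
   distal crural condyles, sacral centra, metatarsal condyles) and planes
   (proximal crural and pedal articular surfaces).
2. **Anatomical coordinate systems (ACSs).** Each segment is reduced to a
   T-shaped pair of principal vectors — an intercentroid long axis and a
   transverse axis (a fitted cylinder axis, the interacetabular vector,
   or the outermost metatarsal condyle pair) — which need not be
   perpendicular. A fixed sequence of cross products turns the T into two
   right-handed triads per segment (e.g. `hipACSm` and `kneeACSf` on the
   femur). Left-side recipes deliberately reverse the subtraction and
   crossing orders, so equivalent motions of either limb measure with
   equal sign.
3. **Joint coordinate systems (JCSs).** At each joint the proximal ACS is
   *fixed* (ACSf) and the distal ACS *mobile* (ACSm), in the Grood–Suntay
   style: flexion–extension (FE) about JCS_Z = ACSf_Z, long-axis rotation
   (LAR) about JCS_X = ACSm_X, abduction–adduction (ABAD) about a
   floating Y orthogonal to both. Rotations are intrinsic Z-Y-X
   Euler/Tait–Bryan angles of `R_rel = Fᵀ M`; translations are the
   intercentroid vector expressed along the *fixed ACS* axes. A
   ground-anchored pseudo-joint measures pelvic yaw/pitch/roll.
4. **Reference pose.** Registering every ACSm exactly onto its ACSf
   collapses the limb into the zero pose (all 24 DOF = 0), the
   configuration all poses are measured from and a built-in consistency
   check. At |ABAD| = 90° the Z and X axes become collinear (gimbal
   lock); decompositions there are flagged, not hidden.

A parametric synthetic-limb generator (`archopose.synthetic`) produces
archosaur-like bone meshes whose labelled patches lie exactly on known
primitives, plus gait-like transform sequences with known joint
trajectories — so the entire pipeline is testable end to end with no
external data, including fused (avian tarsometatarsus) and unfused
(crocodylian, per-frame dynamic pedal ACS) foot morphologies.

## Worked example

```python
import numpy as np
from archopose import (LimbBlueprint, GaitScript, generate_limb, animate,
                       JCS, decompose_pose, label_pose)

blueprint = LimbBlueprint(sides=("right",), condylar_skew_deg=15.0, seed=1)
limb = generate_limb(blueprint)                  # meshes + known ACSs
script = GaitScript.walking(n_frames=30)         # one sinusoidal stride
sequences, _ = animate(limb, script, side="right")

acs = limb.truth_acs["right"]
hip = JCS("hip", "right", acs["pelvis"]["hipACSf"], acs["femur"]["hipACSm"])
frame = 10
pose = label_pose(decompose_pose(hip, sequences["pelvis"].transform(frame),
                                 sequences["femur"].transform(frame), frame))
print(f"hip FE   = {pose.fe_deg:8.3f} deg ({pose.labels['FE']})")
print(f"hip ABAD = {pose.abad_deg:8.3f} deg ({pose.labels['ABAD']})")
print(f"hip LAR  = {pose.lar_deg:8.3f} deg ({pose.labels['LAR']})")
```

prints

```
hip FE   =   52.415 deg (extension 52.4153 deg)
hip ABAD =    9.086 deg (abduction 9.0861 deg)
hip LAR  =   -0.748 deg (internal 0.748185 deg)
```

i.e. at frame 10 the femur is extended 52.4° from the fully collapsed
reference pose, abducted 9.1° and internally rotated 0.7° — exactly the
values the gait script prescribed, recovered through the full
decomposition machinery. Positive FE is extension at every joint,
positive ABAD is abduction at hip and ankle but *adduction* at the knee
(the reversed sign the right-handed knee ACSs impose), and positive LAR
is external rotation.

## Command line

The same pipeline is scriptable from a shell over a declarative YAML
config; flags only pick the command and output directory:

```sh
archopose synth blueprint.yaml -o trial/    # synthetic fixture bundle
archopose fit trial/config.yaml -o out/     # primitives.json + residuals
archopose build trial/config.yaml -o out/   # acs.json + direction checks
archopose refpose trial/config.yaml -o out/ # zeroed pose + zero-check report
archopose pose trial/config.yaml -o out/    # per-frame poses.csv
```

Meshes are triangles-only Wavefront OBJ; patches are JSON face-index
selections; transforms are CSV (frame + translation + unit quaternion,
with a row-major rotation-matrix dialect also accepted); poses are CSV
with one row per joint per frame.

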
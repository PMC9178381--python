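"""Parametric synthetic limbs with exactly known ground truth.

The generator builds archosaur-like bone "meshes" as unions of
primitive-capped surfaces (sphere caps, cylinder strips, planar disks,
connecting tubes), so every labelled articular patch lies exactly on a
known primitive before optional noise.  It is not an anatomical shape
model: realism is limited to the features the pose standard consumes —
articular primitives, condylar skew, left/right asymmetry, fused
(mesotarsal, tarsometatarsus-like) versus unfused (crocodylian-like,
spreading metatarsals) feet.

Right-side bones are built in local frames with +x cranial, +y medial,
+z proximal (pelvis: +x cranial, +y left, +z dorsal); left-side bones are
sagittal mirror images (y negated, winding flipped), which together with
the standard's reversed left-side cross products drives the left/right
convention tests.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import yaml

from .acs import (build_crural_acs, build_femoral_acs, build_pedal_acs_dynamic,
                  build_pedal_acs_static, build_pelvic_acs)
from .errors import ConfigError
from .fitting import CylinderFit, PlaneFit, SphereFit
from .geometry import ACS, RigidTransform, unit
from .jcs import CHAIN, JCS, JointPoseRecord, compose_pose, make_ground_acs
from .io import TransformSequence, write_landmarks, write_transforms
from .mesh import SurfacePatch, TriMesh, write_mesh, write_patches

__all__ = ["LimbBlueprint", "GaitScript", "SyntheticLimb", "generate_limb",
           "animate"]


# ---------------------------------------------------------------------------
# blueprint

@dataclass(frozen=True)
class LimbBlueprint:
    """Ground-truth parameters of a synthetic limb (lengths in mm).

    Defaults are guineafowl-scale: an adult Numida hindlimb has a femur of
    roughly 80 mm with a ~10 mm head sphere and visibly skewed femoral
    condyles; the ~15 deg default skew reproduces the non-parallel
    reference-pose geometry that distinguishes this standard from naive
    long-axis conventions.
    """

    sides: tuple = ("right",)
    femur_length: float = 80.0
    crus_length: float = 90.0
    pes_length: float = 55.0
    acetabular_radius: float = 11.0
    acetabular_halfspan: float = 30.0
    sacral_radius: float = 8.0
    sacral_halflength: float = 27.0
    sacral_height: float = 22.0
    head_radius: float = 10.0
    condyle_radius: float = 8.0
    condyle_halflength: float = 11.0
    condylar_skew_deg: float = 15.0
    crus_plane_radius: float = 9.0
    crus_cyl_radius: float = 6.5
    crus_cyl_halflength: float = 8.0
    pes_plane_radius: float = 7.0
    mt_condyle_radius: float = 4.0
    mt_condyle_halflength: float = 4.5
    mt_halfspan: float = 12.0
    metatarsals_fused: bool = True
    #: subdivision level; the default puts roughly a thousand vertices on
    #: each articular patch — still conservative next to microCT-derived
    #: models, whose patch selections run to many thousands of polygons
    mesh_resolution: int = 96
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for name in ("femur_length", "crus_length", "pes_length",
                     "acetabular_radius", "head_radius", "condyle_radius",
                     "mt_halfspan"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"blueprint: {name} must be positive")
        if self.mesh_resolution < 8:
            raise ConfigError("blueprint: mesh_resolution must be >= 8")
        if self.condyle_radius > self.femur_length / 2:
            raise ConfigError(
                "blueprint: condyle radius exceeds half the femur length")
        if self.mt_condyle_radius > self.pes_length / 2:
            raise ConfigError(
                "blueprint: metatarsal condyle radius exceeds half the pes length")
        for s in self.sides:
            if s not in ("right", "left"):
                raise ConfigError(f"blueprint: unknown side '{s}'")


# ---------------------------------------------------------------------------
# primitive surface patches (exact geometry)

def _frame_from_pole(pole: np.ndarray):
    pole = unit(pole)
    h = np.array([1.0, 0.0, 0.0]) if abs(pole[0]) < 0.9 else np.array([0.0, 0.0, 1.0])
    u = unit(np.cross(pole, h))
    v = np.cross(pole, u)
    return u, v, pole


def _grid_faces(nu: int, nv: int, offset: int) -> np.ndarray:
    """Triangulate an (nu+1) x (nv+1) vertex grid laid out row-major."""
    faces = []
    for i in range(nu):
        for j in range(nv):
            a = offset + i * (nv + 1) + j
            b = a + 1
            c = a + (nv + 1)
            d = c + 1
            faces.append([a, b, d])
            faces.append([a, d, c])
    return np.array(faces, dtype=np.int64)


def _sphere_cap(center, pole, radius, cap_deg, n):
    """Spherical cap around ``pole``; every vertex exactly on the sphere."""
    u, v, w = _frame_from_pole(pole)
    nr = max(3, n // 3)
    polar = np.radians(np.linspace(cap_deg / nr, cap_deg, nr))
    azim = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    verts = [np.asarray(center, float) + radius * w]
    for th in polar:
        ring = (radius * np.sin(th) * (np.outer(np.cos(azim), u)
                                       + np.outer(np.sin(azim), v))
                + radius * np.cos(th) * w + np.asarray(center, float))
        verts.append(ring)
    V = np.vstack([verts[0][None, :], *verts[1:]])
    faces = []
    for k in range(n):  # pole fan
        faces.append([0, 1 + k, 1 + (k + 1) % n])
    for r in range(nr - 1):  # ring strips
        base = 1 + r * n
        nxt = base + n
        for k in range(n):
            k2 = (k + 1) % n
            faces.append([base + k, nxt + k, nxt + k2])
            faces.append([base + k, nxt + k2, base + k2])
    return V, np.array(faces, dtype=np.int64)


def _cylinder_strip(center, axis, radius, halflength, arc_deg, arc_center, n):
    """Partial cylinder surface; every vertex exactly on the cylinder."""
    a = unit(axis)
    u = np.asarray(arc_center, float)
    u = unit(u - (u @ a) * a)
    v = np.cross(a, u)
    na = max(4, n // 2)
    nl = max(4, n // 3)
    ang = np.radians(np.linspace(-arc_deg / 2, arc_deg / 2, na + 1))
    along = np.linspace(-halflength, halflength, nl + 1)
    V = np.empty(((nl + 1) * (na + 1), 3))
    k = 0
    for t in along:
        for th in ang:
            V[k] = (np.asarray(center, float) + t * a
                    + radius * (np.cos(th) * u + np.sin(th) * v))
            k += 1
    return V, _grid_faces(nl, na, 0)


def _disk(center, normal, radius, n):
    """Planar disk; every vertex exactly on the plane."""
    u, v, w = _frame_from_pole(normal)
    nr = max(2, n // 6)
    azim = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    verts = [np.asarray(center, float)]
    for r in np.linspace(radius / nr, radius, nr):
        ring = (r * (np.outer(np.cos(azim), u) + np.outer(np.sin(azim), v))
                + np.asarray(center, float))
        verts.append(ring)
    V = np.vstack([verts[0][None, :], *verts[1:]])
    faces = []
    for k in range(n):
        faces.append([0, 1 + k, 1 + (k + 1) % n])
    for r in range(nr - 1):
        base = 1 + r * n
        nxt = base + n
        for k in range(n):
            k2 = (k + 1) % n
            faces.append([base + k, nxt + k, nxt + k2])
            faces.append([base + k, nxt + k2, base + k2])
    return V, np.array(faces, dtype=np.int64)


def _tube(p0, p1, radius, n):
    """Open connecting tube (unlabelled filler geometry)."""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    axis = unit(p1 - p0)
    mid = 0.5 * (p0 + p1)
    halflength = 0.5 * np.linalg.norm(p1 - p0)
    return _cylinder_strip(mid, axis, radius, halflength, 360.0,
                           _frame_from_pole(axis)[0], n)


class _BoneBuilder:
    """Accumulates patch surfaces into one mesh, tracking face ranges."""

    def __init__(self):
        self._verts: list[np.ndarray] = []
        self._faces: list[np.ndarray] = []
        self._labels: dict[str, list[int]] = {}
        self._nv = 0
        self._nf = 0

    def add(self, V, F, label: str | None = None):
        self._verts.append(V)
        self._faces.append(F + self._nv)
        if label is not None:
            self._labels[label] = list(range(self._nf, self._nf + len(F)))
        self._nv += len(V)
        self._nf += len(F)

    def build(self, ref_dirs: dict) -> tuple[TriMesh, list[SurfacePatch]]:
        mesh = TriMesh(np.vstack(self._verts), np.vstack(self._faces))
        patches = [SurfacePatch(name, np.array(idx), ref_dirs.get(name))
                   for name, idx in self._labels.items()]
        return mesh, patches


def _mirror_mesh(mesh: TriMesh) -> TriMesh:
    v = mesh.vertices.copy()
    v[:, 1] *= -1.0
    f = mesh.faces[:, [0, 2, 1]].copy()  # flip winding to keep orientation
    return TriMesh(v, f)


def _mirror_vec(v):
    out = np.asarray(v, float).copy()
    out[1] *= -1.0
    return out


# ---------------------------------------------------------------------------
# bones

def _build_pelvis(bp: LimbBlueprint):
    n = bp.mesh_resolution
    b = _BoneBuilder()
    w = bp.acetabular_halfspan
    b.add(*_sphere_cap([0, -w, 0], [0, -1, 0], bp.acetabular_radius, 70, n),
          "acetabulum_right")
    b.add(*_sphere_cap([0, w, 0], [0, 1, 0], bp.acetabular_radius, 70, n),
          "acetabulum_left")
    b.add(*_cylinder_strip([0, 0, bp.sacral_height], [1, 0, 0],
                           bp.sacral_radius, bp.sacral_halflength, 180.0,
                           [0, 0, 1], n), "sacral_centra")
    b.add(*_tube([0, -w * 0.8, 2], [0, w * 0.8, 2], 3.0, n))
    mesh, patches = b.build({"sacral_centra": np.array([1.0, 0, 0])})
    truth = {
        "acetabulum_right": SphereFit([0, -w, 0], bp.acetabular_radius, 0.0),
        "acetabulum_left": SphereFit([0, w, 0], bp.acetabular_radius, 0.0),
        "sacral_centra": CylinderFit([0, 0, bp.sacral_height], [1, 0, 0],
                                     bp.sacral_radius, 0.0, 180.0),
    }
    return mesh, patches, truth


def _condyle_axis(skew_deg: float) -> np.ndarray:
    s = np.radians(skew_deg)
    # lateral (-y) base direction tipped distally about the cranial axis
    return np.array([0.0, -np.cos(s), -np.sin(s)])


def _build_femur(bp: LimbBlueprint):
    n = bp.mesh_resolution
    b = _BoneBuilder()
    head = np.array([0.0, 0.0, bp.femur_length])
    b.add(*_sphere_cap(head, [0, 0.6, 0.8], bp.head_radius, 75, n),
          "femoral_head")
    axis = _condyle_axis(bp.condylar_skew_deg)
    arc_center = unit(np.array([-0.6, 0.0, -0.8])
                      - (np.array([-0.6, 0.0, -0.8]) @ axis) * axis)
    b.add(*_cylinder_strip([0, 0, 0], axis, bp.condyle_radius,
                           bp.condyle_halflength, 150.0, arc_center, n),
          "femoral_condyles")
    b.add(*_tube([0, 0, bp.condyle_radius * 0.8],
                 [0, 0, bp.femur_length - bp.head_radius * 0.6], 4.0, n))
    mesh, patches = b.build({"femoral_condyles": np.array([0.0, -1.0, 0.0])})
    truth = {
        "femoral_head": SphereFit(head, bp.head_radius, 0.0),
        "femoral_condyles": CylinderFit([0, 0, 0], axis, bp.condyle_radius,
                                        0.0, 150.0),
    }
    return mesh, patches, truth


def _build_crus(bp: LimbBlueprint):
    n = bp.mesh_resolution
    b = _BoneBuilder()
    prox = np.array([0.0, 0.0, bp.crus_length])
    b.add(*_disk(prox, [0, 0, 1], bp.crus_plane_radius, n), "crus_proximal")
    b.add(*_cylinder_strip([0, 0, 0], [0, 1, 0], bp.crus_cyl_radius,
                           bp.crus_cyl_halflength, 160.0, [0, 0, -1], n),
          "crus_distal")
    b.add(*_tube([0, 0, bp.crus_cyl_radius * 0.8],
                 [0, 0, bp.crus_length - 2.0], 3.5, n))
    mesh, patches = b.build({"crus_proximal": np.array([0.0, 0.0, 1.0]),
                             "crus_distal": np.array([0.0, 1.0, 0.0])})
    truth = {
        "crus_proximal": PlaneFit(prox, [0, 0, 1], 0.0),
        "crus_distal": CylinderFit([0, 0, 0], [0, 1, 0], bp.crus_cyl_radius,
                                   0.0, 160.0),
    }
    return mesh, patches, truth


def _build_pes(bp: LimbBlueprint):
    n = bp.mesh_resolution
    b = _BoneBuilder()
    prox = np.array([0.0, 0.0, bp.pes_length])
    b.add(*_disk(prox, [0, 0, 1], bp.pes_plane_radius, n), "pes_proximal")
    axis_lat = np.array([0.0, -1.0, 0.0])
    d = bp.mt_halfspan
    b.add(*_cylinder_strip([0, 0, 0], axis_lat, bp.mt_condyle_radius,
                           bp.mt_condyle_halflength, 160.0, [0, 0, -1], n),
          "pes_distal")
    b.add(*_cylinder_strip([0, d, 0], axis_lat, bp.mt_condyle_radius,
                           bp.mt_condyle_halflength, 160.0, [0, 0, -1], n),
          "pes_distal_medial")
    b.add(*_cylinder_strip([0, -d, 0], axis_lat, bp.mt_condyle_radius,
                           bp.mt_condyle_halflength, 160.0, [0, 0, -1], n),
          "pes_distal_lateral")
    b.add(*_tube([0, 0, bp.mt_condyle_radius], [0, 0, bp.pes_length - 1.0],
                 3.0, n))
    ref = {"pes_proximal": np.array([0.0, 0.0, 1.0]),
           "pes_distal": np.array([0.0, -1.0, 0.0]),
           "pes_distal_medial": np.array([0.0, -1.0, 0.0]),
           "pes_distal_lateral": np.array([0.0, -1.0, 0.0])}
    mesh, patches = b.build(ref)
    truth = {
        "pes_proximal": PlaneFit(prox, [0, 0, 1], 0.0),
        "pes_distal": CylinderFit([0, 0, 0], axis_lat, bp.mt_condyle_radius,
                                  0.0, 160.0),
        "pes_distal_medial": CylinderFit([0, d, 0], axis_lat,
                                         bp.mt_condyle_radius, 0.0, 160.0),
        "pes_distal_lateral": CylinderFit([0, -d, 0], axis_lat,
                                          bp.mt_condyle_radius, 0.0, 160.0),
    }
    return mesh, patches, truth


def _mirror_fit(fit):
    if isinstance(fit, SphereFit):
        return SphereFit(_mirror_vec(fit.centroid), fit.radius, fit.rms_residual)
    if isinstance(fit, CylinderFit):
        return CylinderFit(_mirror_vec(fit.centroid), _mirror_vec(fit.axis),
                           fit.radius, fit.rms_residual, fit.arc_deg)
    return PlaneFit(_mirror_vec(fit.centroid), _mirror_vec(fit.normal),
                    fit.rms_residual)


def _resolve_sign(fit, reference):
    """Flip a mirrored cylinder axis / plane normal onto its reference."""
    if isinstance(fit, CylinderFit) and fit.axis @ reference < 0:
        return replace(fit, axis=-fit.axis)
    if isinstance(fit, PlaneFit) and fit.normal @ reference < 0:
        return replace(fit, normal=-fit.normal)
    return fit


# anatomical proxy directions in the generator's local frames, used only
# for sign assertions and reporting, never for axis geometry
_PROXIES_RIGHT = {"cranial": [1, 0, 0], "medial": [0, 1, 0],
                  "lateral": [0, -1, 0], "proximal": [0, 0, 1]}
_PROXIES_LEFT = {"cranial": [1, 0, 0], "medial": [0, -1, 0],
                 "lateral": [0, 1, 0], "proximal": [0, 0, 1]}
_PROXIES_PELVIS = {"cranial": [1, 0, 0], "left": [0, 1, 0],
                   "dorsal": [0, 0, 1]}


@dataclass
class SyntheticLimb:
    """Generated meshes, patches, ground truth and derived truth ACSs."""

    blueprint: LimbBlueprint
    meshes: dict            # (segment, side) -> TriMesh
    patches: dict           # (segment, side) -> list[SurfacePatch]
    truth: dict             # (segment, side) -> {role: fit}
    truth_acs: dict         # side -> {segment: {acs name: ACS}}
    landmarks_local: dict   # side -> {"medial"/"lateral"/"plane_centroid": (3,)}

    def segment_keys(self):
        return list(self.meshes)

    def write_bundle(self, outdir) -> dict:
        """Emit the OBJ/JSON/YAML bundle the main pipeline reads.

        Returns the paths written.  Deterministic given the blueprint.
        """
        from pathlib import Path
        outdir = Path(outdir)
        (outdir / "meshes").mkdir(parents=True, exist_ok=True)
        (outdir / "patches").mkdir(parents=True, exist_ok=True)
        paths = {}
        segments_cfg = {}
        for (segment, side), mesh in self.meshes.items():
            key = segment if side == "midline" else f"{segment}_{side}"
            mp = outdir / "meshes" / f"{key}.obj"
            pp = outdir / "patches" / f"{key}.json"
            write_mesh(mesh, mp)
            write_patches(self.patches[(segment, side)], pp)
            segments_cfg[key] = {"mesh": f"meshes/{key}.obj",
                                 "patches": f"patches/{key}.json",
                                 "segment": segment, "side": side}
            paths[key] = (mp, pp)
        config = {
            "units": "mm",
            "sides": list(self.blueprint.sides),
            "pes_mode": "static" if self.blueprint.metatarsals_fused else "dynamic",
            "segments": segments_cfg,
            "seed": self.blueprint.seed,
            "anatomical_proxies": {
                "pelvis": _PROXIES_PELVIS,
                "right": _PROXIES_RIGHT,
                "left": _PROXIES_LEFT,
            },
        }
        cfg_path = outdir / "config.yaml"
        with open(cfg_path, "w") as fh:
            yaml.safe_dump(config, fh, sort_keys=True)
        paths["config"] = cfg_path
        return paths


def generate_limb(blueprint: LimbBlueprint) -> SyntheticLimb:
    """Generate a synthetic limb from its blueprint (deterministic by seed)."""
    bp = blueprint
    rng = np.random.default_rng(bp.seed)
    meshes, patches, truth = {}, {}, {}

    mesh, pat, tr = _build_pelvis(bp)
    meshes[("pelvis", "midline")] = mesh
    patches[("pelvis", "midline")] = pat
    truth[("pelvis", "midline")] = tr

    builders = {"femur": _build_femur, "crus": _build_crus, "pes": _build_pes}
    right_parts = {seg: fn(bp) for seg, fn in builders.items()}
    for side in bp.sides:
        for seg, (mesh_r, pat_r, tr_r) in right_parts.items():
            if side == "right":
                meshes[(seg, side)] = TriMesh(mesh_r.vertices.copy(),
                                              mesh_r.faces.copy())
                patches[(seg, side)] = [SurfacePatch(p.name, p.face_indices.copy(),
                                                     None if p.reference_direction is None
                                                     else p.reference_direction.copy())
                                        for p in pat_r]
                truth[(seg, side)] = dict(tr_r)
            else:
                meshes[(seg, side)] = _mirror_mesh(mesh_r)
                new_pat = []
                new_truth = {}
                for p in pat_r:
                    # numeric reference directions are side-invariant in these
                    # mirrored local frames (the anatomical meaning flips)
                    new_pat.append(SurfacePatch(p.name, p.face_indices.copy(),
                                                None if p.reference_direction is None
                                                else p.reference_direction.copy()))
                for role, fit in tr_r.items():
                    m = _mirror_fit(fit)
                    ref = next((p.reference_direction for p in new_pat
                                if p.name == role and p.reference_direction is not None),
                               None)
                    new_truth[role] = _resolve_sign(m, ref) if ref is not None else m
                patches[(seg, side)] = new_pat
                truth[(seg, side)] = new_truth

    if bp.noise_sd > 0:
        for key in meshes:
            m = meshes[key]
            meshes[key] = TriMesh(
                m.vertices + rng.normal(0.0, bp.noise_sd, m.vertices.shape),
                m.faces)

    truth_acs: dict = {}
    landmarks_local: dict = {}
    ptruth = truth[("pelvis", "midline")]
    pelvic_m, hip_f_r, hip_f_l = build_pelvic_acs(
        ptruth["acetabulum_right"], ptruth["acetabulum_left"],
        ptruth["sacral_centra"])
    for side in bp.sides:
        ft = truth[("femur", side)]
        hip_m, knee_f = build_femoral_acs(ft["femoral_head"],
                                          ft["femoral_condyles"], side)
        ct = truth[("crus", side)]
        knee_m, ankle_f = build_crural_acs(ct["crus_proximal"],
                                           ct["crus_distal"], side)
        pt = truth[("pes", side)]
        ankle_m = build_pedal_acs_static(pt["pes_proximal"], pt["pes_distal"],
                                         side)
        truth_acs[side] = {
            "pelvis": {"pelvicACSm": pelvic_m,
                       "hipACSf": hip_f_r if side == "right" else hip_f_l},
            "femur": {"hipACSm": hip_m, "kneeACSf": knee_f},
            "crus": {"kneeACSm": knee_m, "ankleACSf": ankle_f},
            "pes": {"ankleACSm": ankle_m},
        }
        landmarks_local[side] = {
            "medial": pt["pes_distal_medial"].centroid.copy(),
            "lateral": pt["pes_distal_lateral"].centroid.copy(),
            "plane_centroid": pt["pes_proximal"].centroid.copy(),
        }
    return SyntheticLimb(bp, meshes, patches, truth, truth_acs, landmarks_local)


# ---------------------------------------------------------------------------
# gait scripting and animation

_JOINT_DOFS = ("fe", "abad", "lar", "tx", "ty", "tz")

#: |ABAD| bound for regular trials; the ZYX singularity lives at 90 deg
ABAD_LIMIT_DEG = 85.0


@dataclass
class GaitScript:
    """Scripted per-joint six-DOF trajectories over ``n_frames``.

    ``joints`` maps 'hip'/'knee'/'ankle' to per-DOF arrays; ``pelvis``
    holds the yaw/pitch/roll + path of the pelvis pseudo-joint;
    ``spread_deg`` (unfused feet) rotates the outermost metatarsal
    condylar pair about the pedal long axis, per frame.
    """

    n_frames: int
    joints: dict
    pelvis: dict
    spread_deg: np.ndarray | None = None
    allow_singular: bool = False

    def __post_init__(self):
        for joint, dofs in self.joints.items():
            for name in _JOINT_DOFS:
                arr = np.asarray(dofs.get(name, np.zeros(self.n_frames)), float)
                if arr.shape != (self.n_frames,):
                    raise ConfigError(
                        f"script: {joint}.{name} must have {self.n_frames} frames")
                dofs[name] = arr
            if (not self.allow_singular
                    and np.abs(dofs["abad"]).max() > ABAD_LIMIT_DEG):
                raise ConfigError(
                    f"script: |ABAD| at {joint} exceeds {ABAD_LIMIT_DEG} deg; "
                    "pass allow_singular=True for a singularity-stress trial")
        for name in _JOINT_DOFS:
            arr = np.asarray(self.pelvis.get(name, np.zeros(self.n_frames)), float)
            self.pelvis[name] = arr
        if (not self.allow_singular
                and np.abs(self.pelvis["abad"]).max() > ABAD_LIMIT_DEG):
            raise ConfigError("script: pelvic pitch exceeds the singularity bound")
        if self.spread_deg is not None:
            self.spread_deg = np.asarray(self.spread_deg, float)

    @classmethod
    def zeros(cls, n_frames: int) -> "GaitScript":
        return cls(n_frames, {j: {} for j in ("hip", "knee", "ankle")}, {})

    @classmethod
    def walking(cls, n_frames: int = 30, stride_mm: float = 150.0,
                hip_height_mm: float = 120.0,
                spread_amplitude_deg: float = 0.0) -> "GaitScript":
        """A smooth, gait-like trial (one stride of sinusoidal joint motion).

        Amplitudes are loosely modelled on avian terrestrial locomotion:
        large knee/ankle FE excursions, moderate hip FE, small ABAD/LAR.
        """
        t = np.linspace(0.0, 1.0, n_frames)
        w = 2 * np.pi * t
        joints = {
            "hip": {"fe": 40 + 15 * np.sin(w),
                    "abad": 8 + 4 * np.sin(w + 0.7),
                    "lar": 6 * np.sin(w + 1.1),
                    "ty": 0.5 + 0.2 * np.sin(w)},
            "knee": {"fe": 65 + 25 * np.sin(w + np.pi),
                     "abad": 5 * np.sin(w + 0.3),
                     "lar": 4 * np.sin(w + 2.0),
                     "tx": 0.4 * np.sin(w)},
            "ankle": {"fe": 55 + 30 * np.sin(w + 0.5 * np.pi),
                      "abad": 3 * np.sin(w),
                      "lar": 2 * np.sin(w + 0.9)},
        }
        pelvis = {
            "fe": 4 * np.sin(w),              # yaw
            "abad": 6 + 2 * np.sin(w + 0.4),  # pitch
            "lar": 3 * np.sin(w + 1.3),       # roll
            "tx": -stride_mm * t,             # travel along -ground X (cranial)
            "tz": hip_height_mm + 5 * np.sin(2 * w),
        }
        spread = (spread_amplitude_deg * np.sin(w)
                  if spread_amplitude_deg else None)
        return cls(n_frames, joints, pelvis, spread_deg=spread)

    def joint_record(self, joint: str, side: str, i: int) -> JointPoseRecord:
        d = self.joints[joint]
        return JointPoseRecord(joint, side, i, d["fe"][i], d["abad"][i],
                               d["lar"][i], d["tx"][i], d["ty"][i], d["tz"][i])

    def pelvis_record(self, i: int) -> JointPoseRecord:
        d = self.pelvis
        return JointPoseRecord("pelvis", "midline", i, d["fe"][i], d["abad"][i],
                               d["lar"][i], d["tx"][i], d["ty"][i], d["tz"][i])


def _spread_points(landmarks: dict, theta_deg: float):
    """Rotate the condylar landmark pair about the pedal long axis (local z)."""
    th = np.radians(theta_deg)
    R = np.array([[np.cos(th), -np.sin(th), 0.0],
                  [np.sin(th), np.cos(th), 0.0],
                  [0.0, 0.0, 1.0]])
    return R @ landmarks["medial"], R @ landmarks["lateral"]


def animate(limb: SyntheticLimb, script: GaitScript, side: str = "right",
            ground: ACS | None = None):
    """Drive the limb chain through a gait script (forward kinematics).

    Returns ``(sequences, landmark_rows)`` where ``sequences`` maps segment
    name to a :class:`TransformSequence` and ``landmark_rows`` carries the
    per-frame world positions of the outermost metatarsal condylar
    landmarks (the dynamic pedal ACS inputs).  Decomposing the returned
    transforms reproduces the script exactly (round trip through
    compose/decompose).
    """
    if side not in limb.truth_acs:
        raise ConfigError(f"limb was not generated with side '{side}'")
    if ground is None:
        ground = make_ground_acs()
    acs = limb.truth_acs[side]
    pelvic_jcs = JCS("pelvis", "midline", ground, acs["pelvis"]["pelvicACSm"])
    frames: dict[str, list] = {s: [] for s in ("pelvis", "femur", "crus", "pes")}
    landmark_rows = []
    dynamic = script.spread_deg is not None
    for i in range(script.n_frames):
        T_pelvis = compose_pose(pelvic_jcs, script.pelvis_record(i),
                                RigidTransform.identity())
        frames["pelvis"].append((i, T_pelvis))
        T_parent = {"pelvis": T_pelvis}
        for parent, child, acsf, acsm, joint in CHAIN:
            if child == "pes" and dynamic:
                med, lat = _spread_points(limb.landmarks_local[side],
                                          float(script.spread_deg[i]))
                mobile = build_pedal_acs_dynamic(
                    limb.landmarks_local[side]["plane_centroid"], med, lat, side)
            else:
                mobile = acs[child][acsm]
            jcs = JCS(joint, side, acs[parent][acsf], mobile)
            T_child = compose_pose(jcs, script.joint_record(joint, side, i),
                                   T_parent[parent])
            frames[child].append((i, T_child))
            T_parent[child] = T_child
            if child == "pes":
                if dynamic:
                    med_l, lat_l = med, lat
                else:
                    med_l = limb.landmarks_local[side]["medial"]
                    lat_l = limb.landmarks_local[side]["lateral"]
                for name, p in (("mt_medial", med_l), ("mt_lateral", lat_l),
                                ("pes_plane",
                                 limb.landmarks_local[side]["plane_centroid"])):
                    wp = T_child.apply(p)
                    landmark_rows.append({"frame": i, "side": side, "name": name,
                                          "x": wp[0], "y": wp[1], "z": wp[2]})
    sequences = {seg: TransformSequence(seg, "midline" if seg == "pelvis" else side,
                                        frames[seg])
                 for seg in frames}
    return sequences, landmark_rows


def write_trial(limb: SyntheticLimb, script: GaitScript, outdir,
                sides=None) -> dict:
    """Bundle + animated transforms + landmarks, ready for the CLI pipeline."""
    from pathlib import Path
    outdir = Path(outdir)
    paths = limb.write_bundle(outdir)
    all_seqs: list[TransformSequence] = []
    all_landmarks: list[dict] = []
    for i, side in enumerate(sides or limb.blueprint.sides):
        sequences, landmark_rows = animate(limb, script, side=side)
        if i > 0:
            sequences.pop("pelvis")  # pelvis trajectory is shared
        all_seqs.extend(sequences.values())
        all_landmarks.extend(landmark_rows)
    tpath = outdir / "transforms.csv"
    write_transforms(all_seqs, tpath)
    paths["transforms"] = tpath
    lpath = outdir / "landmarks.csv"
    write_landmarks(all_landmarks, lpath)
    paths["landmarks"] = lpath
    # record the file references in the emitted config
    cfg_path = paths["config"]
    with open(cfg_path) as fh:
        cfg = yaml.safe_load(fh)
    cfg["transforms"] = "transforms.csv"
    cfg["landmarks"] = "landmarks.csv"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return paths
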
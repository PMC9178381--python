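"""Joint coordinate systems and six-DOF pose decomposition.

A JCS pairs the fixed (proximal, ACSf) and mobile (distal, ACSm) anatomical
coordinate systems of a joint.  Rotations are intrinsic Z-Y-X Euler/
Tait-Bryan angles of the mobile frame relative to the fixed frame:
flexion-extension (FE) about JCS_Z = ACSf_Z, abduction-adduction (ABAD)
about the floating Y, and long-axis rotation (LAR) about JCS_X = ACSm_X.
Translations are the components of the intercentroid vector measured along
the fixed ACS's axes (not along the JCS axes, which need not stay mutually
orthogonal).

At |ABAD| = 90 deg the Z and X axes become collinear and FE/LAR are no
longer unique (gimbal lock); only their sum is determined.  The
decomposition then reports FE with LAR set to 0 and raises the gimbal
flag — a convention, flagged rather than hidden.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ArchoposeError, ConfigError
from .geometry import ACS, RigidTransform, register_transform, unit

__all__ = [
    "JointPoseRecord", "JCS", "make_ground_acs",
    "euler_zyx_from_matrix", "matrix_from_euler_zyx",
    "decompose_frames", "decompose_pose", "compose_pose",
    "assemble_reference_pose", "pelvic_pose", "label_pose",
    "find_singularity_angle", "unwrap_deg",
]

#: gimbal flag threshold on |cos(ABAD)|
GIMBAL_COS_TOL = 1e-8

#: joint chain of the standard, proximal to distal
CHAIN = (
    ("pelvis", "femur", "hipACSf", "hipACSm", "hip"),
    ("femur", "crus", "kneeACSf", "kneeACSm", "knee"),
    ("crus", "pes", "ankleACSf", "ankleACSm", "ankle"),
)


@dataclass(frozen=True)
class JointPoseRecord:
    """Six degrees of freedom of one joint at one frame.

    Angles in degrees, translations in mm along the fixed ACS's axes.
    When ``gimbal_flag`` is true, FE and LAR are reported but only their
    sum is unique.
    """

    joint: str
    side: str
    frame_index: int
    fe_deg: float
    abad_deg: float
    lar_deg: float
    t_x_mm: float
    t_y_mm: float
    t_z_mm: float
    gimbal_flag: bool = False
    labels: dict = field(default_factory=dict, compare=False)

    @property
    def rotations(self) -> np.ndarray:
        return np.array([self.fe_deg, self.abad_deg, self.lar_deg])

    @property
    def translations(self) -> np.ndarray:
        return np.array([self.t_x_mm, self.t_y_mm, self.t_z_mm])


@dataclass(frozen=True)
class JCS:
    """A joint coordinate system: fixed and mobile ACSs of adjacent segments.

    The ACSs are expressed in their own segments' local frames; world
    placement comes from the per-frame segment transforms.
    """

    joint: str
    side: str
    fixed: ACS
    mobile: ACS


def make_ground_acs(origin=(0.0, 0.0, 0.0), heading=(1.0, 0.0, 0.0),
                    name: str = "pelvicACSf") -> ACS:
    """Ground-anchored fixed ACS of the pelvic pseudo-joint.

    Z is exactly world-up; X is the horizontal projection of ``heading``
    (user-defined; the pipeline defaults to the negated mean travel
    direction so a forward-travelling, level pelvis reads near-zero yaw);
    Y completes the right-handed triad.
    """
    z = np.array([0.0, 0.0, 1.0])
    h = np.asarray(heading, dtype=float)
    h = h - (h @ z) * z
    x = unit(h)
    y = np.cross(z, x)
    return ACS(name, "midline", np.asarray(origin, float), x, y, z)


def matrix_from_euler_zyx(fe_deg: float, abad_deg: float, lar_deg: float) -> np.ndarray:
    """Rotation matrix of intrinsic Z-Y-X angles: Rz(FE) @ Ry(ABAD) @ Rx(LAR)."""
    a, b, c = np.radians([fe_deg, abad_deg, lar_deg])
    ca, sa = math.cos(a), math.sin(a)
    cb, sb = math.cos(b), math.sin(b)
    cc, sc = math.cos(c), math.sin(c)
    return np.array([
        [ca * cb, ca * sb * sc - sa * cc, ca * sb * cc + sa * sc],
        [sa * cb, sa * sb * sc + ca * cc, sa * sb * cc - ca * sc],
        [-sb, cb * sc, cb * cc],
    ])


def euler_zyx_from_matrix(R: np.ndarray) -> tuple[float, float, float, bool]:
    """Intrinsic Z-Y-X Euler angles (degrees) of a rotation matrix.

    Returns ``(fe, abad, lar, gimbal_flag)`` with ABAD in [-90, 90].
    At gimbal lock (|cos ABAD| < 1e-8) LAR is set to 0 and FE carries the
    determined FE+LAR sum.
    """
    R = np.asarray(R, dtype=float)
    sb = min(1.0, max(-1.0, -R[2, 0]))
    cb = math.hypot(R[2, 1], R[2, 2])
    # atan2 rather than asin: well-conditioned as |ABAD| approaches 90
    abad = math.degrees(math.atan2(sb, cb))
    if cb < GIMBAL_COS_TOL:
        # Z and X rotation axes collinear: only FE +/- LAR determined
        fe = math.degrees(math.atan2(-R[0, 1], R[1, 1]))
        return fe, abad, 0.0, True
    fe = math.degrees(math.atan2(R[1, 0], R[0, 0]))
    lar = math.degrees(math.atan2(R[2, 1], R[2, 2]))
    return fe, abad, lar, False


def decompose_frames(fixed_world: ACS, mobile_world: ACS, joint: str = "",
                     side: str = "", frame_index: int = 0) -> JointPoseRecord:
    """Six-DOF pose of a mobile ACS relative to a fixed ACS, both in world.

    Rotation: R_rel = F^T M decomposed as intrinsic Z-Y-X.  Translation:
    the world intercentroid vector expressed along the fixed ACS's axes.
    """
    F = fixed_world.rotation
    M = mobile_world.rotation
    R_rel = F.T @ M
    fe, abad, lar, gimbal = euler_zyx_from_matrix(R_rel)
    t = F.T @ (mobile_world.origin - fixed_world.origin)
    return JointPoseRecord(joint, side, frame_index, fe, abad, lar,
                           float(t[0]), float(t[1]), float(t[2]), gimbal)


def decompose_pose(jcs: JCS, T_fixed_segment: RigidTransform,
                   T_mobile_segment: RigidTransform,
                   frame_index: int = 0) -> JointPoseRecord:
    """Decompose a joint pose from the two segments' rigid transforms."""
    F = jcs.fixed.transformed(T_fixed_segment)
    M = jcs.mobile.transformed(T_mobile_segment)
    return decompose_frames(F, M, jcs.joint, jcs.side, frame_index)


def compose_pose(jcs: JCS, pose: JointPoseRecord,
                 T_fixed_segment: RigidTransform) -> RigidTransform:
    """Forward kinematics: mobile segment transform realising ``pose``.

    Inverse of :func:`decompose_pose` for |ABAD| < 90 deg; poses at or
    beyond the principal range of the second rotation are rejected.
    """
    if not np.all(np.isfinite(pose.rotations)) or not np.all(np.isfinite(pose.translations)):
        raise ArchoposeError("non-finite pose")
    if abs(pose.abad_deg) >= 90.0:
        raise ArchoposeError(
            f"|ABAD| = {abs(pose.abad_deg):g} deg is outside the principal "
            "range (-90, 90); the ZYX parameterisation is singular there")
    F = jcs.fixed.transformed(T_fixed_segment)
    R_rel = matrix_from_euler_zyx(pose.fe_deg, pose.abad_deg, pose.lar_deg)
    M_rot = F.rotation @ R_rel
    M_origin = F.origin + F.rotation @ pose.translations
    R_seg = M_rot @ jcs.mobile.rotation.T
    t_seg = M_origin - R_seg @ jcs.mobile.origin
    return RigidTransform(R_seg, t_seg)


def assemble_reference_pose(segment_acs: dict, ground: ACS,
                            side: str) -> dict:
    """Zeroed reference pose of one limb: segment name -> RigidTransform.

    ``segment_acs`` maps segment name (pelvis, femur, crus, pes) to a dict
    of its local ACSs keyed by ACS name.  Proximal to distal, each
    segment's mobile ACS is registered exactly onto the parent's
    world-frame fixed ACS (the pelvis onto the ground ACS), so every JCS
    decomposes to six zeros.  Bone interpenetration in this collapsed
    configuration is expected.
    """
    for seg in ("pelvis", "femur", "crus", "pes"):
        if seg not in segment_acs:
            raise ConfigError(f"reference pose: missing segment '{seg}'")
    transforms: dict[str, RigidTransform] = {}
    transforms["pelvis"] = register_transform(segment_acs["pelvis"]["pelvicACSm"],
                                              ground)
    for parent, child, acsf_name, acsm_name, _joint in CHAIN:
        fixed_world = segment_acs[parent][acsf_name].transformed(transforms[parent])
        transforms[child] = register_transform(segment_acs[child][acsm_name],
                                               fixed_world)
    return transforms


def pelvic_pose(ground: ACS, pelvic_acs_world: ACS,
                frame_index: int = 0) -> JointPoseRecord:
    """Pelvis pose relative to the ground pseudo-joint (yaw/pitch/roll)."""
    rec = decompose_frames(ground, pelvic_acs_world, "pelvis", "midline",
                           frame_index)
    return label_pose(rec)


# sign-convention labels per joint: (positive label, negative label) for
# each of FE, ABAD, LAR.  Knee ABAD is deliberately reversed relative to
# hip/ankle so the knee ACSs stay right-handed.
_LABELS = {
    "hip": {"FE": ("extension", "flexion"),
            "ABAD": ("abduction", "adduction"),
            "LAR": ("external", "internal")},
    "knee": {"FE": ("extension", "flexion"),
             "ABAD": ("adduction", "abduction"),
             "LAR": ("external", "internal")},
    "ankle": {"FE": ("extension", "flexion"),
              "ABAD": ("abduction", "adduction"),
              "LAR": ("external", "internal")},
    "pelvis": {"FE": ("yaw left", "yaw right"),
               "ABAD": ("pitch up", "pitch down"),
               "LAR": ("roll right-side-up", "roll left-side-up")},
}


def label_pose(record: JointPoseRecord) -> JointPoseRecord:
    """Attach anatomical direction labels to a pose record.

    Raw numbers are unchanged; e.g. ABAD = +5 at a knee is labelled
    "adduction 5.0 deg" (the knee's ABAD sign convention is reversed
    relative to hip and ankle), and exact zeros are "neutral".
    """
    if record.joint not in _LABELS:
        raise ConfigError(f"unknown joint '{record.joint}'")
    table = _LABELS[record.joint]
    labels = {}
    for key, value in (("FE", record.fe_deg), ("ABAD", record.abad_deg),
                       ("LAR", record.lar_deg)):
        pos, neg = table[key]
        if value == 0.0:
            labels[key] = "neutral"
        else:
            labels[key] = f"{pos if value > 0 else neg} {abs(value):g} deg"
    return replace(record, labels=labels)


def jcs_world_axes(jcs: JCS, T_fixed: RigidTransform,
                   T_mobile: RigidTransform) -> dict:
    """World directions of the three JCS axes (Z fixed, X mobile, Y floating)."""
    F = jcs.fixed.transformed(T_fixed)
    M = jcs.mobile.transformed(T_mobile)
    z = F.Z
    x = M.X
    y = unit(np.cross(z, x))
    return {"Z": z, "X": x, "Y": y}


def find_singularity_angle(jcs: JCS, T_fixed: RigidTransform | None = None,
                           threshold_rad: float = 1e-6,
                           step_deg: float = 1.0) -> float:
    """Locate the |ABAD| at which JCS_Z and JCS_X become collinear.

    Sweeps the second rotation upward from 0 deg through compose_pose,
    finds the first angle at which the world-frame angle between JCS_Z and
    JCS_X (folded to [0, 90]) drops below ``threshold_rad``, then polishes
    the collinearity point by secant iteration on the misalignment (which
    is exactly pi/2 - |ABAD| for a ZYX JCS, so the iteration converges
    immediately).  Expected 90 deg for any valid JCS.
    """
    if T_fixed is None:
        T_fixed = RigidTransform.identity()

    def misalignment(abad: float) -> float:
        # collinearity measure: angle between axes folded to [0, pi/2]
        pose = JointPoseRecord(jcs.joint, jcs.side, 0, 0.0, abad, 0.0,
                               0.0, 0.0, 0.0)
        T_mobile = compose_pose(jcs, pose, T_fixed)
        ax = jcs_world_axes(jcs, T_fixed, T_mobile)
        c = abs(float(np.clip(ax["Z"] @ ax["X"], -1.0, 1.0)))
        return math.acos(c)

    lo = 0.0
    abad = step_deg
    while abad < 90.0 and misalignment(abad) > threshold_rad:
        lo = abad
        abad += step_deg
    hi = min(abad, 90.0 - 1e-9)
    # secant root-find on the (linear) misalignment, staying inside the
    # principal range where compose_pose is defined
    x0, x1 = lo, hi
    f0, f1 = misalignment(x0), misalignment(x1)
    for _ in range(60):
        if f1 < 1e-12 or abs(f1 - f0) < 1e-300:
            break
        x2 = x1 + f1 * (x1 - x0) / (f0 - f1)
        x2 = min(max(x2, 0.0), 90.0 - 1e-9)
        x0, f0 = x1, f1
        x1, f1 = x2, misalignment(x2)
    return float(x1)


def unwrap_deg(angles_deg) -> np.ndarray:
    """Remove +/-360 deg jumps from an angle time series.

    Principal values should be stored alongside; this is for plotting and
    continuity only.
    """
    return np.degrees(np.unwrap(np.radians(np.asarray(angles_deg, float))))
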
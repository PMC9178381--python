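"""JCS engine: Euler decomposition against an independent library oracle,
compose/decompose round trips, reference-pose zeroing, gimbal handling,
hierarchy behaviour, labelling, and left/right motion equivalence."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from archopose import (ACS, JCS, JointPoseRecord, RigidTransform,
                       assemble_reference_pose, compose_pose,
                       decompose_frames, decompose_pose,
                       euler_zyx_from_matrix, find_singularity_angle,
                       label_pose, make_ground_acs, matrix_from_euler_zyx,
                       pelvic_pose, unwrap_deg)
from archopose.errors import ArchoposeError, ConfigError
from archopose.jcs import CHAIN, jcs_world_axes
from archopose import synthetic

from conftest import random_rigid_transform


def _identity_acs(name="acs", side="right", origin=(0, 0, 0)):
    return ACS(name, side, origin, (1, 0, 0), (0, 1, 0), (0, 0, 1))


def _toy_jcs(joint="hip", side="right"):
    fixed = _identity_acs("hipACSf", side, origin=(0, 0, 0))
    mobile = _identity_acs("hipACSm", side, origin=(0, 0, 0))
    return JCS(joint, side, fixed, mobile)


class TestEuler:
    def test_matches_scipy_oracle(self, rng):
        """Dual route: our closed-form ZYX extraction against scipy's."""
        for _ in range(500):
            ang = rng.uniform(-179, 179, 3)
            ang[1] = rng.uniform(-89, 89)
            R = Rotation.from_euler("ZYX", ang, degrees=True).as_matrix()
            fe, abad, lar, gimbal = euler_zyx_from_matrix(R)
            assert not gimbal
            assert np.allclose([fe, abad, lar], ang, atol=1e-9)
            assert np.allclose(matrix_from_euler_zyx(fe, abad, lar), R,
                               atol=1e-12)

    def test_gimbal_lock_flag_and_tiebreak(self):
        """At |ABAD| = 90 only FE+LAR is determined: LAR is zeroed, the
        flag raised, and the FE value carries the determined sum."""
        R = (Rotation.from_euler("ZYX", [40, 90, 25], degrees=True)
             .as_matrix())
        fe, abad, lar, gimbal = euler_zyx_from_matrix(R)
        assert gimbal
        assert lar == 0.0
        assert abs(abad - 90.0) < 1e-9
        # for b=+90: Rz(a)Ry(90)Rx(c) = Rz(a-c)Ry(90), so FE carries a-c
        assert abs(fe - (40 - 25)) < 1e-9

    def test_aligned_frames_are_all_zero(self):
        jcs = _toy_jcs()
        T = RigidTransform.identity()
        rec = decompose_pose(jcs, T, T)
        assert np.allclose(rec.rotations, 0, atol=1e-12)
        assert np.allclose(rec.translations, 0, atol=1e-12)
        assert not rec.gimbal_flag

    def test_pure_z_rotation_is_fe_only(self):
        jcs = _toy_jcs()
        Rz = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        rec = decompose_pose(jcs, RigidTransform.identity(),
                             RigidTransform(Rz, np.zeros(3)))
        assert np.allclose([rec.fe_deg, rec.abad_deg, rec.lar_deg],
                           [30, 0, 0], atol=1e-10)


class TestRoundTrip:
    def test_compose_decompose_identity(self, rng):
        """compose then decompose reproduces 1000 random poses with
        |ABAD| <= 85 deg to better than 1e-9 deg / 1e-9 mm."""
        fixed = ACS("kneeACSf", "right", (3, -2, 1),
                    *Rotation.from_euler("ZYX", [20, -35, 60],
                                         degrees=True).as_matrix().T)
        mobile = ACS("kneeACSm", "right", (-1, 4, 2),
                     *Rotation.from_euler("ZYX", [-50, 10, 5],
                                          degrees=True).as_matrix().T)
        jcs = JCS("knee", "right", fixed, mobile)
        max_rot = max_tr = 0.0
        for _ in range(1000):
            T_fixed = random_rigid_transform(rng)
            pose = JointPoseRecord("knee", "right", 0,
                                   rng.uniform(-180, 180),
                                   rng.uniform(-85, 85),
                                   rng.uniform(-180, 180),
                                   *rng.uniform(-20, 20, 3))
            T_mobile = compose_pose(jcs, pose, T_fixed)
            back = decompose_pose(jcs, T_fixed, T_mobile)
            dr = np.abs(back.rotations - pose.rotations)
            dr = np.minimum(dr, 360 - dr)  # FE/LAR wrap at +/-180
            max_rot = max(max_rot, dr.max())
            max_tr = max(max_tr, np.abs(back.translations
                                        - pose.translations).max())
        assert max_rot < 1e-9
        assert max_tr < 1e-9

    def test_compose_rejects_principal_range_violation(self):
        jcs = _toy_jcs()
        pose = JointPoseRecord("hip", "right", 0, 0, 95.0, 0, 0, 0, 0)
        with pytest.raises(ArchoposeError, match="principal range"):
            compose_pose(jcs, pose, RigidTransform.identity())


class TestHierarchy:
    """The nested-gimbal hierarchy: LAR moves nothing above it; FE moves
    everything below it but not JCS_Z."""

    def _axes(self, jcs, fe, abad, lar):
        pose = JointPoseRecord(jcs.joint, jcs.side, 0, fe, abad, lar, 0, 0, 0)
        T_m = compose_pose(jcs, pose, RigidTransform.identity())
        return jcs_world_axes(jcs, RigidTransform.identity(), T_m)

    def test_lar_leaves_all_jcs_axes_moves_distal_segment(self):
        jcs = _toy_jcs()
        a0 = self._axes(jcs, 25, 10, 0)
        a1 = self._axes(jcs, 25, 10, 40)
        # LAR spins the distal segment about JCS_X itself: no JCS axis moves
        for ax in "XYZ":
            assert np.allclose(a0[ax], a1[ax], atol=1e-12)
        # ... but the distal segment does (its mobile Y axis rotates)
        p0 = JointPoseRecord("hip", "right", 0, 25, 10, 0, 0, 0, 0)
        p1 = JointPoseRecord("hip", "right", 0, 25, 10, 40, 0, 0, 0)
        T0 = compose_pose(jcs, p0, RigidTransform.identity())
        T1 = compose_pose(jcs, p1, RigidTransform.identity())
        y0 = jcs.mobile.transformed(T0).Y
        y1 = jcs.mobile.transformed(T1).Y
        assert not np.allclose(y0, y1, atol=1e-3)

    def test_fe_moves_y_x_but_not_z(self):
        jcs = _toy_jcs()
        a0 = self._axes(jcs, 0, 10, 15)
        a1 = self._axes(jcs, 50, 10, 15)
        assert np.allclose(a0["Z"], a1["Z"], atol=1e-12)
        assert not np.allclose(a0["Y"], a1["Y"], atol=1e-3)
        assert not np.allclose(a0["X"], a1["X"], atol=1e-3)


class TestReferencePose:
    def test_chain_decomposes_to_zero(self, limb):
        ground = make_ground_acs()
        for side in ("right", "left"):
            segs = limb.truth_acs[side]
            transforms = assemble_reference_pose(segs, ground, side)
            recs = [pelvic_pose(ground,
                                segs["pelvis"]["pelvicACSm"].transformed(
                                    transforms["pelvis"]))]
            for parent, child, acsf, acsm, joint in CHAIN:
                jcs = JCS(joint, side, segs[parent][acsf], segs[child][acsm])
                recs.append(decompose_pose(jcs, transforms[parent],
                                           transforms[child]))
            for rec in recs:
                assert np.abs(rec.rotations).max() < 1e-9
                assert np.abs(rec.translations).max() < 1e-9

    def test_skewed_condyles_make_crus_nonparallel_in_dorsal_view(self, limb):
        """Because the femoral condylar axis is skewed, the crus is not
        parallel to the femur in dorsal view of the reference pose."""
        ground = make_ground_acs()
        segs = limb.truth_acs["right"]
        transforms = assemble_reference_pose(segs, ground, "right")
        femur_x = segs["femur"]["hipACSm"].transformed(transforms["femur"]).X
        crus_x = segs["crus"]["kneeACSm"].transformed(transforms["crus"]).X
        fa = femur_x[:2] / np.linalg.norm(femur_x[:2])
        ca = crus_x[:2] / np.linalg.norm(crus_x[:2])
        dorsal_angle = np.degrees(np.arccos(np.clip(abs(fa @ ca), -1, 1)))
        skew = limb.blueprint.condylar_skew_deg
        assert dorsal_angle > 1.0
        assert abs(dorsal_angle - skew) < 1.0

    def test_mirrored_limbs_mirror_reference_poses(self, limb):
        ground = make_ground_acs()
        M = np.diag([1.0, -1.0, 1.0])
        tr_r = assemble_reference_pose(limb.truth_acs["right"], ground, "right")
        tr_l = assemble_reference_pose(limb.truth_acs["left"], ground, "left")
        for seg in ("femur", "crus", "pes"):
            # left bone meshes are the mirrored right meshes, so world
            # vertex positions must mirror: T_l = M T_r M
            R_expect = M @ tr_r[seg].rotation @ M
            t_expect = M @ tr_r[seg].translation
            assert np.allclose(tr_l[seg].rotation, R_expect, atol=1e-9), seg
            assert np.allclose(tr_l[seg].translation, t_expect, atol=1e-9), seg

    def test_missing_segment_rejected(self, limb):
        segs = dict(limb.truth_acs["right"])
        segs.pop("crus")
        with pytest.raises(ConfigError, match="missing segment"):
            assemble_reference_pose(segs, make_ground_acs(), "right")


class TestPelvicPseudoJoint:
    def test_level_pelvis_is_zero(self):
        ground = make_ground_acs()
        rec = pelvic_pose(ground, ground)
        assert np.allclose(rec.rotations, 0, atol=1e-12)

    def test_pitch_sign_nose_up_positive(self):
        """Pitching the pelvis 20 deg about the ground Y axis raises the
        cranial (-X, since pelvicACSm_X is caudal) end: pitch = +20."""
        ground = make_ground_acs()
        jcs = JCS("pelvis", "midline", ground, ground)
        pose = JointPoseRecord("pelvis", "midline", 0, 0, 20, 0, 0, 0, 0)
        T = compose_pose(jcs, pose, RigidTransform.identity())
        rec = pelvic_pose(ground, ground.transformed(T))
        assert abs(rec.abad_deg - 20) < 1e-9
        # and the (caudal) X axis now points downward
        assert ground.transformed(T).X[2] < 0

    def test_extreme_pitch_sets_gimbal_flag(self):
        ground = make_ground_acs()
        R = Rotation.from_euler("ZYX", [10, 90, 0], degrees=True).as_matrix()
        tipped = ACS("pelvicACSm", "midline", (0, 0, 0),
                     *(R @ ground.rotation).T)
        rec = pelvic_pose(ground, tipped)
        assert rec.gimbal_flag


class TestLabels:
    @pytest.mark.parametrize("joint,abad,expect", [
        ("hip", 10.0, "abduction"),
        ("ankle", 10.0, "abduction"),
        ("knee", 10.0, "adduction"),   # knee ABAD sign is reversed
        ("knee", -10.0, "abduction"),
        ("hip", 0.0, "neutral"),
    ])
    def test_abad_labels(self, joint, abad, expect):
        rec = JointPoseRecord(joint, "right", 0, 0.0, abad, 0.0, 0, 0, 0)
        lab = label_pose(rec).labels["ABAD"]
        assert lab.startswith(expect)

    def test_fe_and_lar_labels(self):
        rec = JointPoseRecord("hip", "left", 0, 15.0, 0.0, -5.0, 0, 0, 0)
        lab = label_pose(rec).labels
        assert lab["FE"].startswith("extension")
        assert lab["LAR"].startswith("internal")

    def test_unknown_joint_rejected(self):
        rec = JointPoseRecord("elbow", "right", 0, 0, 0, 0, 0, 0, 0)
        with pytest.raises(ConfigError, match="unknown joint"):
            label_pose(rec)


class TestSingularity:
    def test_located_at_90deg(self, limb):
        """The smallest |ABAD| at which JCS_Z and JCS_X become collinear
        is 90 deg (to 1e-6 deg)."""
        segs = limb.truth_acs["right"]
        jcs = JCS("hip", "right", segs["pelvis"]["hipACSf"],
                  segs["femur"]["hipACSm"])
        ang = find_singularity_angle(jcs)
        assert abs(ang - 90.0) < 1e-6

    def test_no_collinearity_below_85(self, limb):
        segs = limb.truth_acs["right"]
        jcs = JCS("knee", "right", segs["femur"]["kneeACSf"],
                  segs["crus"]["kneeACSm"])
        T = RigidTransform.identity()
        for abad in np.linspace(0, 85, 18):
            pose = JointPoseRecord("knee", "right", 0, 12.0, abad, -7.0,
                                   0, 0, 0)
            ax = jcs_world_axes(jcs, T, compose_pose(jcs, pose, T))
            angle = np.degrees(np.arccos(abs(np.clip(ax["Z"] @ ax["X"],
                                                     -1, 1))))
            assert angle > 4.9  # 90 - 85, within rounding


class TestLeftRightEquivalence:
    def test_mirrored_motion_same_signs_and_magnitudes(self, limb):
        """Equivalent (mirrored) anatomical motions measure identically on
        both sides: equal FE/ABAD/LAR signs and magnitudes at hip, knee and
        ankle; the knee's reversed ABAD convention is a labelling matter."""
        script = synthetic.GaitScript.walking(8)
        M = np.diag([1.0, -1.0, 1.0])
        seqs_r, _ = synthetic.animate(limb, script, "right")
        # mirror the right-side world motion onto the left-side limb:
        # left local meshes are y-mirrored right meshes, so the mirrored
        # trial has T_l = M T_r M
        segs_l = limb.truth_acs["left"]
        for parent, child, acsf, acsm, joint in CHAIN:
            jcs_l = JCS(joint, "left", segs_l[parent][acsf],
                        segs_l[child][acsm])
            for (f, Tp), (_, Tc) in zip(seqs_r[parent].frames,
                                        seqs_r[child].frames):
                Tp_l = RigidTransform(M @ Tp.rotation @ M, M @ Tp.translation)
                Tc_l = RigidTransform(M @ Tc.rotation @ M, M @ Tc.translation)
                rec_l = decompose_pose(jcs_l, Tp_l, Tc_l, f)
                want = script.joint_record(joint, "right", f)
                assert np.allclose(rec_l.rotations, want.rotations,
                                   atol=1e-9), (joint, f)
                # left fixed-ACS axes point in the opposite anatomical
                # directions, so mirrored displacements measure negated
                assert np.allclose(rec_l.translations, -want.translations,
                                   atol=1e-9), (joint, f)


def test_unwrap_makes_series_continuous():
    raw = np.array([170.0, 179.0, -178.0, -170.0, -179.0, 178.0])
    unwrapped = unwrap_deg(raw)
    assert np.abs(np.diff(unwrapped)).max() < 30
    assert np.allclose((unwrapped - raw + 180) % 360 - 180, 0, atol=1e-9)
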
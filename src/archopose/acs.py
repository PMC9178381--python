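"""Anatomical coordinate system construction.

Each hindlimb segment is reduced to a T-shaped pair of principal vectors —
an intercentroid long axis and a transverse axis (a fitted cylinder axis,
the interacetabular vector, or the pedal condylar pair) — from which all
ACS axes follow by a fixed sequence of cross products.  The two principal
vectors need not be perpendicular: orthogonality enters only through the
cross products, and the long axis is never re-orthogonalised against the
transverse axis.

The constructions are deliberately asymmetric between right and left
sides (reversed subtraction and crossing orders) so that equivalent
anatomical motions of either limb are later measured with equal sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateGeometryError
from .fitting import CylinderFit, PlaneFit, SphereFit
from .geometry import ACS, angle_between_deg, unit

__all__ = [
    "PrincipalVectors",
    "build_pelvic_acs",
    "build_femoral_acs",
    "build_crural_acs",
    "build_pedal_acs_static",
    "build_pedal_acs_dynamic",
    "check_anatomical_directions",
]

#: principal vectors closer to parallel than this are rejected: the cross
#: products that build the ACS axes become numerically unstable
MIN_T_ANGLE_DEG = 5.0


def _check_not_parallel(long_axis, transverse, what: str) -> None:
    ang = angle_between_deg(long_axis, transverse)
    if min(ang, 180.0 - ang) < MIN_T_ANGLE_DEG:
        raise DegenerateGeometryError(
            f"{what}: long and transverse principal vectors are within "
            f"{MIN_T_ANGLE_DEG} deg of parallel (angle {ang:.2f} deg)")


@dataclass(frozen=True)
class PrincipalVectors:
    """The T-shaped pair a segment is reduced to."""

    long_axis: np.ndarray
    transverse_axis: np.ndarray
    proximal_point: np.ndarray
    distal_point: np.ndarray

    def __post_init__(self):
        la = unit(self.long_axis)
        ta = unit(self.transverse_axis)
        _check_not_parallel(la, ta, "principal vectors")
        object.__setattr__(self, "long_axis", la)
        object.__setattr__(self, "transverse_axis", ta)
        object.__setattr__(self, "proximal_point",
                           np.asarray(self.proximal_point, float).reshape(3))
        object.__setattr__(self, "distal_point",
                           np.asarray(self.distal_point, float).reshape(3))


def build_pelvic_acs(acet_R: SphereFit, acet_L: SphereFit,
                     sacral: CylinderFit) -> tuple[ACS, ACS, ACS]:
    """Pelvic ACSs from the two acetabular spheres and the sacral cylinder.

    Returns ``(pelvicACSm, hipACSf_right, hipACSf_left)``.

    pelvicACSm: origin midway between the acetabular centroids; Y from
    left to right centroid (positive to the right); Z = Y x sacral axis
    (positive dorsally); X = Y x Z (positive caudally).

    hipACSf (both sides): origin at the own acetabular centroid; Z from
    right to left centroid (positive to the left on both sides); right
    Y = Z x sacral (ventral), left Y = sacral x Z (dorsal); X = Y x Z
    (right cranial, left caudal).

    The sacral axis sign must already be resolved positive cranially.
    """
    cr = np.asarray(acet_R.centroid, float)
    cl = np.asarray(acet_L.centroid, float)
    if np.linalg.norm(cr - cl) < 1e-9:
        raise DegenerateGeometryError("acetabular centroids coincide")
    sac = unit(sacral.axis)
    inter = cr - cl
    _check_not_parallel(inter, sac, "pelvis (interacetabular vs sacral axis)")

    y_m = unit(inter)
    z_m = unit(np.cross(y_m, sac))
    x_m = np.cross(y_m, z_m)
    pelvic_m = ACS("pelvicACSm", "midline", 0.5 * (cr + cl), x_m, y_m, z_m)

    z_f = unit(cl - cr)
    y_r = unit(np.cross(z_f, sac))
    x_r = np.cross(y_r, z_f)
    hip_f_r = ACS("hipACSf", "right", cr, x_r, y_r, z_f)
    y_l = unit(np.cross(sac, z_f))
    x_l = np.cross(y_l, z_f)
    hip_f_l = ACS("hipACSf", "left", cl, x_l, y_l, z_f)
    return pelvic_m, hip_f_r, hip_f_l


def _t_pair_segment(prox_origin, dist_origin, transverse_axis, side: str,
                    prox_name: str, dist_name: str,
                    what: str) -> tuple[ACS, ACS]:
    """Shared femoral/crural pattern.

    Right side: proximal X = unit(distal origin - proximal origin)
    (positive distally); left side reverses the subtraction (positive
    proximally).  The transverse (cylinder) axis is the distal ACS Z, its
    sign already resolved anatomically.  Shared Y = unit(X x Z); distal
    X = Y x Z; proximal Z = X x Y.
    """
    prox_origin = np.asarray(prox_origin, float)
    dist_origin = np.asarray(dist_origin, float)
    long_vec = dist_origin - prox_origin
    if np.linalg.norm(long_vec) < 1e-9:
        raise DegenerateGeometryError(f"{what}: proximal and distal origins coincide")
    if side == "left":
        long_vec = -long_vec
    x_prox = unit(long_vec)
    z_dist = unit(transverse_axis)
    _check_not_parallel(x_prox, z_dist, what)
    y = unit(np.cross(x_prox, z_dist))
    x_dist = np.cross(y, z_dist)
    z_prox = np.cross(x_prox, y)
    prox = ACS(prox_name, side, prox_origin, x_prox, y, z_prox)
    dist = ACS(dist_name, side, dist_origin, x_dist, y, z_dist)
    return prox, dist


def build_femoral_acs(head: SphereFit, condyles: CylinderFit,
                      side: str) -> tuple[ACS, ACS]:
    """Femoral ACSs: ``(hipACSm, kneeACSf)``.

    Origins are at the head-sphere and condylar-cylinder centroids.  The
    condylar axis sign must be resolved right-positive-laterally /
    left-positive-medially before the call (reference direction).
    """
    return _t_pair_segment(head.centroid, condyles.centroid, condyles.axis,
                           side, "hipACSm", "kneeACSf", f"femur ({side})")


def build_crural_acs(prox_plane: PlaneFit, distal_cyl: CylinderFit,
                     side: str) -> tuple[ACS, ACS]:
    """Crural ACSs: ``(kneeACSm, ankleACSf)``.

    Same pattern as the femur with the crural conventions: distal cylinder
    axis right-positive-medially / left-positive-laterally.  The mesotarsal
    (avian tibiotarsal condyles) and crurotarsal (astragalo-calcaneal
    roller) morphologies use this same code path with different patches.
    """
    return _t_pair_segment(prox_plane.centroid, distal_cyl.centroid,
                           distal_cyl.axis, side, "kneeACSm", "ankleACSf",
                           f"crus ({side})")


def _pedal_acs(plane_centroid, distal_point, transverse, side: str) -> ACS:
    plane_centroid = np.asarray(plane_centroid, float)
    distal_point = np.asarray(distal_point, float)
    long_vec = distal_point - plane_centroid
    if np.linalg.norm(long_vec) < 1e-9:
        raise DegenerateGeometryError("pes: proximal and distal points coincide")
    if side == "left":
        long_vec = -long_vec
    x = unit(long_vec)
    t = unit(transverse)
    _check_not_parallel(x, t, f"pes ({side})")
    y = unit(np.cross(x, t))
    z = np.cross(x, y)
    return ACS("ankleACSm", side, plane_centroid, x, y, z)


def build_pedal_acs_static(prox_plane: PlaneFit, mtIII_condyle: CylinderFit,
                           side: str) -> ACS:
    """Pedal ACS for a fused/tightly bound metatarsus (e.g. tarsometatarsus).

    Origin at the proximal-plane centroid; long axis to the condylar
    cylinder centroid of metatarsal III (right positive distally, left
    reversed); transverse axis = the condylar cylinder axis, sign resolved
    right-positive-laterally / left-positive-medially; Y = X x transverse
    (right caudal, left cranial); Z = X x Y (right medial, left lateral).
    """
    return _pedal_acs(prox_plane.centroid, mtIII_condyle.centroid,
                      mtIII_condyle.axis, side)


def build_pedal_acs_dynamic(prox_plane_centroid, medial_pt, lateral_pt,
                            side: str) -> ACS:
    """Per-pose pedal ACS for unfused, spreading metatarsals.

    The distal point is the midpoint of the outermost metatarsal condylar
    landmarks; the transverse axis runs from the medial to the lateral
    landmark on the right (reversed on the left).  Recompute every frame.
    """
    m = np.asarray(medial_pt, float)
    l = np.asarray(lateral_pt, float)
    if np.linalg.norm(l - m) < 1e-9:
        raise DegenerateGeometryError("pes: medial and lateral landmarks coincide")
    transverse = (l - m) if side == "right" else (m - l)
    return _pedal_acs(prox_plane_centroid, 0.5 * (m + l), transverse, side)


def check_anatomical_directions(acs: ACS, proxies: dict) -> dict:
    """Signed agreement between ACS axes and anatomical proxy directions.

    ``proxies`` maps axis name to ``(direction_vector, expected_sign)``,
    e.g. ``{"Z": ([0, -1, 0], +1)}`` to assert kneeACSf_Z points laterally
    on the right.  Returns ``{axis: (dot, ok)}`` for reporting.
    """
    out = {}
    for axis_name, (direction, expected) in proxies.items():
        axis = getattr(acs, axis_name)
        d = float(axis @ unit(np.asarray(direction, float)))
        out[axis_name] = (d, d * expected > 0)
    return out
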
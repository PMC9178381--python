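"""Least-squares fitting of geometric primitives to articular surface patches.

Spheres, cylinders and planes are fitted to patch vertices by minimising
squared orthogonal distance to the primitive surface.  Fitted axes and
normals are direction-ambiguous; anatomical sign ("axis positive
laterally", ...) is resolved by dotting with a per-patch reference
direction supplied in the configuration.

All fits are deterministic: algebraic or PCA initialisation followed by
Gauss-Newton/Levenberg-Marquardt refinement (scipy.optimize.least_squares),
no random restarts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import ConvergenceError, DegenerateGeometryError
from .geometry import unit

__all__ = ["SphereFit", "CylinderFit", "PlaneFit",
           "fit_sphere", "fit_cylinder", "fit_plane", "fit_patch"]

_XTOL = 1e-12
_FTOL = 1e-12
_GTOL = 1e-14
_MAX_ITER = 200

#: warn when a cylinder patch subtends less than this arc about the axis
MIN_ARC_DEG = 30.0


@dataclass(frozen=True)
class SphereFit:
    centroid: np.ndarray
    radius: float
    rms_residual: float

    def __post_init__(self):
        object.__setattr__(self, "centroid",
                           np.asarray(self.centroid, float).reshape(3))
        if self.radius <= 0:
            raise DegenerateGeometryError("sphere fit with non-positive radius")


@dataclass(frozen=True)
class CylinderFit:
    centroid: np.ndarray
    axis: np.ndarray
    radius: float
    rms_residual: float
    arc_deg: float = float("nan")

    def __post_init__(self):
        object.__setattr__(self, "centroid",
                           np.asarray(self.centroid, float).reshape(3))
        object.__setattr__(self, "axis", unit(self.axis))
        if self.radius <= 0:
            raise DegenerateGeometryError("cylinder fit with non-positive radius")


@dataclass(frozen=True)
class PlaneFit:
    centroid: np.ndarray
    normal: np.ndarray
    rms_residual: float

    def __post_init__(self):
        object.__setattr__(self, "centroid",
                           np.asarray(self.centroid, float).reshape(3))
        object.__setattr__(self, "normal", unit(self.normal))


def _as_points(points) -> np.ndarray:
    p = np.asarray(points, dtype=float).reshape(-1, 3)
    if not np.all(np.isfinite(p)):
        raise DegenerateGeometryError("non-finite point coordinates")
    return p


def _pca(points: np.ndarray):
    """Centered principal directions, largest variance first."""
    c = points.mean(axis=0)
    u, s, vt = np.linalg.svd(points - c, full_matrices=False)
    return c, s, vt


def fit_sphere(patch_vertices) -> SphereFit:
    """Least-squares sphere through >= 4 non-coplanar points.

    Algebraic (Coope) linear solve for initialisation, then geometric
    refinement of sum((|p - c| - r)^2).
    """
    p = _as_points(patch_vertices)
    if len(p) < 4:
        raise DegenerateGeometryError("sphere fit needs at least 4 points")
    c0, s, _ = _pca(p)
    scale = max(s[0] / np.sqrt(len(p)), 1e-9)
    if s[2] < 1e-9 * max(s[0], 1.0):
        raise DegenerateGeometryError("sphere fit: points are coplanar")

    # algebraic: |p|^2 = 2 p.c + (r^2 - |c|^2)
    A = np.column_stack([2.0 * p, np.ones(len(p))])
    b = (p ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    c = sol[:3]
    r2 = sol[3] + c @ c
    r = float(np.sqrt(max(r2, (1e-6 * scale) ** 2)))

    def resid(x):
        return np.linalg.norm(p - x[:3], axis=1) - x[3]

    res = least_squares(resid, np.r_[c, r], xtol=_XTOL, ftol=_FTOL, gtol=_GTOL,
                        max_nfev=_MAX_ITER * 5)
    c, r = res.x[:3], float(res.x[3])
    rms = float(np.sqrt(np.mean(resid(res.x) ** 2)))
    return SphereFit(c, abs(r), rms)


def _cylinder_frame(axis: np.ndarray):
    """Two unit vectors spanning the plane orthogonal to ``axis``."""
    a = unit(axis)
    h = np.array([1.0, 0.0, 0.0]) if abs(a[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = unit(np.cross(a, h))
    e2 = np.cross(a, e1)
    return e1, e2


def _circle_fit_2d(xy: np.ndarray):
    """Algebraic (Coope) circle fit; returns (center(2,), radius, rms)."""
    A = np.column_stack([2.0 * xy, np.ones(len(xy))])
    b = (xy ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    c = sol[:2]
    r = float(np.sqrt(max(sol[2] + c @ c, 1e-18)))
    rms = float(np.sqrt(np.mean((np.linalg.norm(xy - c, axis=1) - r) ** 2)))
    return c, r, rms


def _axis_from_angles(theta: float, phi: float) -> np.ndarray:
    st = np.sin(theta)
    return np.array([st * np.cos(phi), st * np.sin(phi), np.cos(theta)])


def fit_cylinder(patch_vertices, reference_direction=None) -> CylinderFit:
    """Least-squares circular cylinder through >= 6 points.

    The axis is initialised from the principal directions of the patch
    (each candidate scored by an algebraic circle fit in its normal plane)
    and refined by Levenberg-Marquardt on the point-to-surface distance.
    ``reference_direction``, when given, flips the fitted axis so that
    dot(axis, reference_direction) > 0.  The reported ``centroid`` is the
    midpoint of the extremal projections of the patch vertices onto the
    fitted axis line.  A warning is issued when the patch subtends less
    than 30 degrees of arc about the axis (weakly identifiable fit).
    """
    p = _as_points(patch_vertices)
    if len(p) < 6:
        raise DegenerateGeometryError("cylinder fit needs at least 6 points")
    c0, s, vt = _pca(p)
    scale = max(s[0] / np.sqrt(len(p)), 1e-9)
    if s[2] < 1e-9 * max(s[0], 1.0):
        raise DegenerateGeometryError("cylinder fit: points are coplanar")
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise DegenerateGeometryError("cylinder fit: points are collinear")

    def unpack(x):
        theta, phi, a, b, r = x
        ax = _axis_from_angles(theta, phi)
        e1, e2 = _cylinder_frame(ax)
        point = c0 + a * e1 + b * e2
        return ax, point, r

    def resid(x):
        ax, point, r = unpack(x)
        d = p - point
        radial = d - np.outer(d @ ax, ax)
        return np.linalg.norm(radial, axis=1) - r

    # candidate axes: the three principal directions of the patch.  Each is
    # seeded with an algebraic circle fit in its normal plane and refined to
    # convergence; the lowest-residual refined solution wins.  Refining all
    # three (rather than trusting the algebraic score) keeps short, noisy
    # condyle-like patches out of perpendicular-axis local minima, and is
    # still fully deterministic.
    best = None
    for cand in vt:
        e1, e2 = _cylinder_frame(cand)
        xy = np.column_stack([(p - c0) @ e1, (p - c0) @ e2])
        c2, r0, _ = _circle_fit_2d(xy)
        theta0 = float(np.arccos(np.clip(cand[2], -1.0, 1.0)))
        phi0 = float(np.arctan2(cand[1], cand[0]))
        x0 = np.array([theta0, phi0, c2[0], c2[1], r0])
        res = least_squares(resid, x0, xtol=_XTOL, ftol=_FTOL, gtol=_GTOL,
                            max_nfev=_MAX_ITER * 5)
        rms = float(np.sqrt(np.mean(res.fun ** 2)))
        if best is None or rms < best[0]:
            best = (rms, res)
    rms, res = best
    if not res.success:  # pragma: no cover - scipy rarely reports failure here
        raise ConvergenceError(f"cylinder fit did not converge: {res.message}")
    axis, point, r = unpack(res.x)

    # angular spread of the patch about the fitted axis
    e1, e2 = _cylinder_frame(axis)
    d = p - point
    ang = np.arctan2(d @ e2, d @ e1)
    ref_ang = np.median(ang)
    spread = np.degrees(np.ptp((ang - ref_ang + np.pi) % (2 * np.pi) - np.pi))
    if spread < MIN_ARC_DEG:
        warnings.warn(
            f"cylinder patch subtends only {spread:.1f} deg of arc; the fitted "
            "axis may be poorly identified", stacklevel=2)

    if reference_direction is not None and axis @ np.asarray(reference_direction, float) < 0:
        axis = -axis
    proj = d @ axis
    centroid = point + 0.5 * (proj.min() + proj.max()) * axis
    return CylinderFit(centroid, axis, float(abs(r)), rms, float(spread))


def fit_plane(patch_vertices, patch_faces=None, reference_direction=None) -> PlaneFit:
    """Total-least-squares plane through >= 3 non-collinear vertices.

    The normal is the least-variance principal direction.  The reported
    centroid is the area-weighted centroid of the patch faces projected
    onto the plane (so sliver triangulation does not bias the origin);
    without faces it falls back to the projected vertex mean.
    """
    p = _as_points(patch_vertices)
    if len(p) < 3:
        raise DegenerateGeometryError("plane fit needs at least 3 points")
    c0, s, vt = _pca(p)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise DegenerateGeometryError("plane fit: points are collinear")
    normal = vt[2]
    rms = float(np.sqrt(np.mean(((p - c0) @ normal) ** 2)))

    if patch_faces is not None and len(patch_faces):
        f = np.asarray(patch_faces, dtype=np.int64).reshape(-1, 3)
        tri = p[f]
        areas = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
        if areas.sum() <= 0:
            raise DegenerateGeometryError("plane fit: zero total patch area")
        centroid = (tri.mean(axis=1) * areas[:, None]).sum(axis=0) / areas.sum()
    else:
        centroid = p.mean(axis=0)
    centroid = centroid - ((centroid - c0) @ normal) * normal

    if reference_direction is not None and normal @ np.asarray(reference_direction, float) < 0:
        normal = -normal
    return PlaneFit(centroid, normal, rms)


def fit_patch(mesh, patch, primitive: str):
    """Fit the named primitive type to a surface patch of ``mesh``."""
    verts = patch.vertices(mesh)
    ref = patch.reference_direction
    if primitive == "sphere":
        return fit_sphere(verts)
    if primitive == "cylinder":
        return fit_cylinder(verts, reference_direction=ref)
    if primitive == "plane":
        pv, pf = patch.faces_local(mesh)
        return fit_plane(pv, pf, reference_direction=ref)
    raise ValueError(f"unknown primitive type '{primitive}'")
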
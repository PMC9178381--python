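"""End-to-end pipeline: patches -> primitives -> ACSs -> JCS pose tables.

Thin orchestration over the library modules, driven by a declarative
:class:`~archopose.io.RunConfig`.  Each stage returns plain data and can
also write its artifact to disk; the CLI maps one command onto each stage.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from .acs import (build_crural_acs, build_femoral_acs, build_pedal_acs_dynamic,
                  build_pedal_acs_static, build_pelvic_acs,
                  check_anatomical_directions)
from .errors import ConfigError
from .geometry import ACS, unit
from .io import (RunConfig, read_landmarks, read_transforms,
                 write_transforms)
from .jcs import (CHAIN, JCS, assemble_reference_pose, decompose_frames,
                  decompose_pose, label_pose, make_ground_acs, pelvic_pose)
from .io import TransformSequence
from .fitting import fit_patch
from .mesh import STANDARD_PATCH_ROLES, read_mesh, read_patches

log = logging.getLogger("archopose")

__all__ = ["run_fit", "run_build", "run_refpose", "run_pose", "export_scene"]


def _load_segments(cfg: RunConfig):
    """Load (segment, side) -> (mesh, {role: patch}) from a config."""
    out = {}
    for key, seg in cfg.segments.items():
        segment = seg.get("segment", key.rsplit("_", 1)[0])
        side = seg.get("side", key.rsplit("_", 1)[-1]
                       if key != "pelvis" else "midline")
        mesh = read_mesh(cfg.path(seg["mesh"]))
        patches = read_patches(cfg.path(seg["patches"]), mesh)
        out[(segment, side)] = (mesh, {p.name: p for p in patches})
    return out


def run_fit(cfg: RunConfig):
    """Fit the standard's primitives to every configured patch.

    Returns ``{(segment, side): {role: fit}}`` and logs RMS residuals.
    """
    fits = {}
    for (segment, side), (mesh, patches) in _load_segments(cfg).items():
        fits[(segment, side)] = {}
        for role, patch in patches.items():
            primitive = STANDARD_PATCH_ROLES[role]
            fit = fit_patch(mesh, patch, primitive)
            fits[(segment, side)][role] = fit
            log.info("fit %-20s %s/%s: %s rms=%.4g mm",
                     role, segment, side, primitive, fit.rms_residual)
    return fits


def fits_to_json(fits) -> dict:
    out = {}
    for (segment, side), roles in fits.items():
        key = f"{segment}/{side}"
        out[key] = {}
        for role, fit in roles.items():
            d = {"rms_residual": fit.rms_residual,
                 "centroid": fit.centroid.tolist()}
            if hasattr(fit, "radius"):
                d["radius"] = fit.radius
            if hasattr(fit, "axis"):
                d["axis"] = fit.axis.tolist()
            if hasattr(fit, "normal"):
                d["normal"] = fit.normal.tolist()
            out[key][role] = d
    return out


def run_build(cfg: RunConfig, fits=None):
    """Build every ACS of the standard from fitted primitives.

    Returns ``(acs_sets, report)`` where ``acs_sets[side][segment][name]``
    is an :class:`ACS` in its segment's local frame and ``report`` carries
    the orthonormality and anatomical-direction assertions.
    """
    if fits is None:
        fits = run_fit(cfg)
    ptruth = fits[("pelvis", "midline")]
    pelvic_m, hip_f_r, hip_f_l = build_pelvic_acs(
        ptruth["acetabulum_right"], ptruth["acetabulum_left"],
        ptruth["sacral_centra"])
    acs_sets: dict = {}
    for side in cfg.sides:
        femur = fits[("femur", side)]
        hip_m, knee_f = build_femoral_acs(femur["femoral_head"],
                                          femur["femoral_condyles"], side)
        crus = fits[("crus", side)]
        knee_m, ankle_f = build_crural_acs(crus["crus_proximal"],
                                           crus["crus_distal"], side)
        pes = fits[("pes", side)]
        if cfg.pes_mode == "static":
            ankle_m = build_pedal_acs_static(pes["pes_proximal"],
                                             pes["pes_distal"], side)
        else:
            ankle_m = build_pedal_acs_dynamic(
                pes["pes_proximal"].centroid,
                pes["pes_distal_medial"].centroid,
                pes["pes_distal_lateral"].centroid, side)
        acs_sets[side] = {
            "pelvis": {"pelvicACSm": pelvic_m,
                       "hipACSf": hip_f_r if side == "right" else hip_f_l},
            "femur": {"hipACSm": hip_m, "kneeACSf": knee_f},
            "crus": {"kneeACSm": knee_m, "ankleACSf": ankle_f},
            "pes": {"ankleACSm": ankle_m},
        }
    report = _direction_report(cfg, acs_sets)
    return acs_sets, report


# expected signed agreement of each ACS axis with an anatomical proxy
# direction, per side (right, left), from the standard's stated conventions
_DIRECTION_EXPECTATIONS = {
    ("femur", "hipACSm", "X"): ("proximal", -1, +1),
    ("femur", "kneeACSf", "X"): ("proximal", +1, -1),
    ("femur", "kneeACSf", "Z"): ("lateral", +1, -1),
    ("femur", "hipACSm", "Z"): ("medial", +1, -1),
    ("femur", "hipACSm", "Y"): ("cranial", -1, +1),
    ("crus", "kneeACSm", "X"): ("proximal", -1, +1),
    ("crus", "ankleACSf", "X"): ("proximal", +1, -1),
    ("crus", "ankleACSf", "Z"): ("medial", +1, -1),
    ("crus", "kneeACSm", "Z"): ("lateral", +1, -1),
    ("crus", "kneeACSm", "Y"): ("cranial", +1, -1),
    ("pes", "ankleACSm", "X"): ("proximal", -1, +1),
    ("pes", "ankleACSm", "Y"): ("cranial", -1, +1),
    ("pes", "ankleACSm", "Z"): ("medial", +1, -1),
}


def _direction_report(cfg: RunConfig, acs_sets) -> dict:
    proxies_cfg = cfg.raw.get("anatomical_proxies", {})
    report: dict = {"checks": [], "all_ok": True}
    for side, segments in acs_sets.items():
        proxies = proxies_cfg.get(side, {})
        if not proxies:
            continue
        for (segment, acs_name, axis), (proxy, sr, sl) in \
                _DIRECTION_EXPECTATIONS.items():
            if proxy not in proxies or segment not in segments \
                    or acs_name not in segments[segment]:
                continue
            expected = sr if side == "right" else sl
            acs = segments[segment][acs_name]
            res = check_anatomical_directions(
                acs, {axis: (np.asarray(proxies[proxy], float), expected)})
            dot, ok = res[axis]
            report["checks"].append({
                "side": side, "acs": acs_name, "axis": axis,
                "proxy": proxy, "expected_sign": expected,
                "dot": dot, "ok": bool(ok)})
            report["all_ok"] = report["all_ok"] and bool(ok)
            if not ok:
                log.warning("direction check failed: %s %s_%s vs %s "
                            "(dot=%.3f, expected sign %+d)",
                            side, acs_name, axis, proxy, dot, expected)
    return report


def acs_sets_to_json(acs_sets) -> dict:
    return {side: {seg: {name: acs.to_dict() for name, acs in d.items()}
                   for seg, d in segments.items()}
            for side, segments in acs_sets.items()}


def _ground_acs(cfg: RunConfig, sequences=None) -> ACS:
    g = cfg.ground or {}
    origin = g.get("origin", [0.0, 0.0, 0.0])
    heading = g.get("heading", "auto")
    if heading == "auto":
        heading = [1.0, 0.0, 0.0]
        if sequences and ("pelvis", "midline") in sequences:
            seq = sequences[("pelvis", "midline")]
            if len(seq) >= 2:
                travel = (seq.frames[-1][1].translation
                          - seq.frames[0][1].translation)
                travel[2] = 0.0
                if np.linalg.norm(travel) > 1e-9:
                    # negated travel: pelvicACSm_X points caudally, so a
                    # forward-travelling level pelvis reads near-zero yaw
                    heading = (-unit(travel)).tolist()
    return make_ground_acs(origin, heading)


def run_refpose(cfg: RunConfig, acs_sets=None):
    """Assemble the zeroed reference pose and verify it decomposes to zero.

    Returns ``(transforms_by_side, report)``; the report contains the max
    |DOF| over all joints per side and right/left asymmetry diagnostics.
    """
    if acs_sets is None:
        acs_sets, _ = run_build(cfg)
    ground = _ground_acs(cfg)
    transforms_by_side = {}
    report: dict = {"ground": ground.to_dict(), "sides": {}}
    for side, segments in acs_sets.items():
        transforms = assemble_reference_pose(segments, ground, side)
        transforms_by_side[side] = transforms
        records = [pelvic_pose(ground,
                               segments["pelvis"]["pelvicACSm"].transformed(
                                   transforms["pelvis"]))]
        for parent, child, acsf, acsm, joint in CHAIN:
            jcs = JCS(joint, side, segments[parent][acsf],
                      segments[child][acsm])
            records.append(decompose_pose(jcs, transforms[parent],
                                          transforms[child]))
        max_dof = max(max(abs(r.rotations).max(), abs(r.translations).max())
                      for r in records)
        long_axes = {
            "femur": segments["femur"]["hipACSm"].transformed(
                transforms["femur"]).X,
            "crus": segments["crus"]["kneeACSm"].transformed(
                transforms["crus"]).X,
        }
        dorsal_angle = _dorsal_view_angle(long_axes["femur"], long_axes["crus"])
        report["sides"][side] = {
            "max_abs_dof": float(max_dof),
            "zeroed": bool(max_dof < 1e-9),
            "femur_crus_dorsal_angle_deg": dorsal_angle,
        }
    if {"right", "left"} <= set(report["sides"]):
        r = report["sides"]["right"]["femur_crus_dorsal_angle_deg"]
        l = report["sides"]["left"]["femur_crus_dorsal_angle_deg"]
        report["asymmetry_deg"] = abs(r - l)
    return transforms_by_side, report


def _dorsal_view_angle(a, b) -> float:
    """Angle between two axes projected onto the horizontal plane (deg)."""
    pa = np.array([a[0], a[1]])
    pb = np.array([b[0], b[1]])
    na, nb = np.linalg.norm(pa), np.linalg.norm(pb)
    if na < 1e-12 or nb < 1e-12:
        return float("nan")
    c = np.clip(abs(pa @ pb) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def run_pose(cfg: RunConfig, acs_sets=None):
    """Per-frame JCS decomposition of a tracked trial -> pose records.

    Dynamic pes mode rebuilds the pedal ACS each frame from tracked
    landmark world positions (outermost metatarsal condylar points).
    """
    if acs_sets is None:
        acs_sets, _ = run_build(cfg)
    if cfg.transforms is None:
        raise ConfigError("pose command requires a 'transforms' file")
    sequences = read_transforms(cfg.path(cfg.transforms))
    landmarks = (read_landmarks(cfg.path(cfg.landmarks))
                 if cfg.landmarks else {})
    ground = _ground_acs(cfg, sequences)
    records = []
    pelvis_seq = sequences.get(("pelvis", "midline"))
    if pelvis_seq is not None:
        pm = acs_sets[cfg.sides[0]]["pelvis"]["pelvicACSm"]  # side-invariant
        for frame, T in pelvis_seq.frames:
            records.append(pelvic_pose(ground, pm.transformed(T), frame))
    for side in cfg.sides:
        segments = acs_sets[side]
        for parent, child, acsf, acsm, joint in CHAIN:
            pside = "midline" if parent == "pelvis" else side
            seq_p = sequences.get((parent, pside))
            seq_c = sequences.get((child, side))
            if seq_p is None or seq_c is None:
                raise ConfigError(
                    f"pose: missing transforms for joint '{joint}' ({side})")
            for (frame, T_p), (frame_c, T_c) in zip(seq_p.frames, seq_c.frames):
                if frame != frame_c:
                    raise ConfigError(
                        f"pose: frame mismatch at joint '{joint}' ({side})")
                if child == "pes" and cfg.pes_mode == "dynamic":
                    fixed_world = segments[parent][acsf].transformed(T_p)
                    try:
                        med = landmarks[(frame, side, "mt_medial")]
                        lat = landmarks[(frame, side, "mt_lateral")]
                    except KeyError as exc:
                        raise ConfigError(
                            f"pose: missing pedal landmarks at frame {frame}"
                        ) from exc
                    plane = landmarks.get(
                        (frame, side, "pes_plane"),
                        T_c.apply(segments["pes"]["ankleACSm"].origin))
                    mobile_world = build_pedal_acs_dynamic(plane, med, lat, side)
                    rec = decompose_frames(fixed_world, mobile_world, joint,
                                           side, frame)
                else:
                    jcs = JCS(joint, side, segments[parent][acsf],
                              segments[child][acsm])
                    rec = decompose_pose(jcs, T_p, T_c, frame)
                records.append(label_pose(rec))
    records.sort(key=lambda r: (r.frame_index, r.joint, r.side))
    return records


def export_scene(acs_sets, transforms_by_side, path) -> None:
    """Write world-frame ACS origins/axes as JSON for external renderers."""
    scene = {}
    for side, segments in acs_sets.items():
        scene[side] = {}
        transforms = transforms_by_side[side]
        for seg, d in segments.items():
            T = transforms[seg]
            scene[side][seg] = {name: acs.transformed(T).to_dict()
                                for name, acs in d.items()}
    with open(path, "w") as fh:
        json.dump(scene, fh, indent=1)
        fh.write("\n")


def write_refpose_outputs(cfg: RunConfig, outdir, acs_sets=None) -> dict:
    """Reference-pose transforms CSV + zero-check report JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if acs_sets is None:
        acs_sets, _ = run_build(cfg)
    transforms_by_side, report = run_refpose(cfg, acs_sets)
    seqs = []
    for side, transforms in transforms_by_side.items():
        for seg, T in transforms.items():
            seqs.append(TransformSequence(
                seg, "midline" if seg == "pelvis" else side, [(0, T)]))
    write_transforms(seqs, outdir / "refpose_transforms.csv")
    with open(outdir / "refpose_report.json", "w") as fh:
        json.dump(report, fh, indent=1)
        fh.write("\n")
    export_scene(acs_sets, transforms_by_side, outdir / "refpose_scene.json")
    return report
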
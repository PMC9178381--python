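"""Tabular and configuration I/O.

File dialects:

* transforms CSV: one row per segment per frame with columns
  ``segment,side,frame,tx,ty,tz,qw,qx,qy,qz`` (unit quaternion, scalar
  first) or alternatively ``segment,side,frame,tx,ty,tz,r00..r22``
  (row-major rotation matrix).  Quaternions are the preferred on-disk
  form: they round-trip through text without drifting off the rotation
  manifold.
* pose CSV: ``frame,joint,side,FE_deg,ABAD_deg,LAR_deg,t_x_mm,t_y_mm,
  t_z_mm,gimbal_flag``; numbers are written with 17 significant digits so
  a write/read round trip is lossless to 1e-9.
* landmark CSV (dynamic pedal tracking): ``frame,side,name,x,y,z`` in
  world coordinates.
* run configuration: YAML or JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .geometry import RigidTransform
from .jcs import JointPoseRecord

__all__ = [
    "TransformSequence", "read_transforms", "write_transforms",
    "write_pose_table", "read_pose_table",
    "read_landmarks", "write_landmarks",
    "load_config", "RunConfig",
]

_QCOLS = ["qw", "qx", "qy", "qz"]
_RCOLS = [f"r{i}{j}" for i in range(3) for j in range(3)]
_POSE_HEADER = ["frame", "joint", "side", "FE_deg", "ABAD_deg", "LAR_deg",
                "t_x_mm", "t_y_mm", "t_z_mm", "gimbal_flag"]


@dataclass
class TransformSequence:
    """Ordered per-frame rigid transforms of one segment."""

    segment_name: str
    side: str
    frames: list  # list of (frame_index, RigidTransform)

    def __post_init__(self):
        idx = [f for f, _ in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ConfigError(
                f"{self.segment_name}: frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def transform(self, frame_index: int) -> RigidTransform:
        for f, T in self.frames:
            if f == frame_index:
                return T
        raise KeyError(frame_index)


def write_transforms(sequences: list[TransformSequence], path) -> None:
    rows = []
    for seq in sequences:
        for frame, T in seq.frames:
            q = T.to_quaternion()
            rows.append({"segment": seq.segment_name, "side": seq.side,
                         "frame": frame,
                         "tx": T.translation[0], "ty": T.translation[1],
                         "tz": T.translation[2],
                         "qw": q[0], "qx": q[1], "qy": q[2], "qz": q[3]})
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False, float_format="%.17g")


def read_transforms(path) -> dict:
    """Read a transforms CSV -> ``{(segment, side): TransformSequence}``.

    Accepts either the quaternion or the 9-element row-major rotation
    dialect.
    """
    df = pd.read_csv(path)
    if all(c in df.columns for c in _QCOLS):
        dialect = "quat"
    elif all(c in df.columns for c in _RCOLS):
        dialect = "matrix"
    else:
        raise ConfigError(
            f"{path}: expected quaternion columns {_QCOLS} or rotation "
            f"columns {_RCOLS}")
    out: dict[tuple[str, str], TransformSequence] = {}
    for (segment, side), grp in df.groupby(["segment", "side"], sort=False):
        grp = grp.sort_values("frame")
        frames = []
        for _, row in grp.iterrows():
            t = np.array([row["tx"], row["ty"], row["tz"]])
            if dialect == "quat":
                T = RigidTransform.from_quaternion(row["qw"], row["qx"],
                                                   row["qy"], row["qz"], t)
            else:
                R = np.array([row[c] for c in _RCOLS]).reshape(3, 3)
                T = RigidTransform(R, t)
            frames.append((int(row["frame"]), T))
        out[(segment, side)] = TransformSequence(segment, side, frames)
    return out


def write_pose_table(records: list[JointPoseRecord], path) -> None:
    """Write pose records to CSV (lossless to 1e-9 on read-back)."""
    if not records:
        raise ValueError("no pose records to write")
    rows = [{"frame": r.frame_index, "joint": r.joint, "side": r.side,
             "FE_deg": r.fe_deg, "ABAD_deg": r.abad_deg, "LAR_deg": r.lar_deg,
             "t_x_mm": r.t_x_mm, "t_y_mm": r.t_y_mm, "t_z_mm": r.t_z_mm,
             "gimbal_flag": r.gimbal_flag}
            for r in records]
    pd.DataFrame(rows, columns=_POSE_HEADER).to_csv(
        path, index=False, float_format="%.17g")


def read_pose_table(path) -> list[JointPoseRecord]:
    df = pd.read_csv(path)
    missing = [c for c in _POSE_HEADER if c not in df.columns]
    if missing:
        raise ConfigError(f"{path}: missing pose columns {missing}")
    return [JointPoseRecord(row["joint"], row["side"], int(row["frame"]),
                            float(row["FE_deg"]), float(row["ABAD_deg"]),
                            float(row["LAR_deg"]), float(row["t_x_mm"]),
                            float(row["t_y_mm"]), float(row["t_z_mm"]),
                            bool(row["gimbal_flag"]))
            for _, row in df.iterrows()]


def write_landmarks(rows: list[dict], path) -> None:
    """Write tracked landmark world positions (dynamic pedal ACS inputs)."""
    pd.DataFrame(rows, columns=["frame", "side", "name", "x", "y", "z"]).to_csv(
        path, index=False, float_format="%.17g")


def read_landmarks(path) -> dict:
    """Read landmark CSV -> ``{(frame, side, name): (3,) array}``."""
    df = pd.read_csv(path)
    return {(int(r["frame"]), r["side"], r["name"]):
            np.array([r["x"], r["y"], r["z"]])
            for _, r in df.iterrows()}


@dataclass
class RunConfig:
    """Declarative pipeline configuration (paths relative to its own file)."""

    root: Path
    sides: list[str]
    pes_mode: str
    segments: dict          # segment key -> {"mesh": path, "patches": path}
    transforms: Path | None
    landmarks: Path | None
    ground: dict
    units: str = "mm"
    seed: int | None = None
    raw: dict = field(default_factory=dict)

    def path(self, rel) -> Path:
        return (self.root / rel).resolve()


_UNIT_SCALE = {"mm": 1.0, "cm": 10.0, "m": 1000.0}


def load_config(path) -> RunConfig:
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) if path.suffix in {".yml", ".yaml"} else json.load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    sides = raw.get("sides", ["right"])
    for s in sides:
        if s not in ("right", "left"):
            raise ConfigError(f"{path}: unknown side '{s}'")
    pes_mode = raw.get("pes_mode", "static")
    if pes_mode not in ("static", "dynamic"):
        raise ConfigError(f"{path}: pes_mode must be 'static' or 'dynamic'")
    units = raw.get("units", "mm")
    if units not in _UNIT_SCALE:
        raise ConfigError(f"{path}: unsupported units '{units}'")
    segments = raw.get("segments")
    if not segments:
        raise ConfigError(f"{path}: no segments declared")
    cfg = RunConfig(
        root=path.parent,
        sides=list(sides),
        pes_mode=pes_mode,
        segments=segments,
        transforms=raw.get("transforms"),
        landmarks=raw.get("landmarks"),
        ground=raw.get("ground", {}),
        units=units,
        seed=raw.get("seed"),
        raw=raw,
    )
    for key, seg in segments.items():
        for role in ("mesh", "patches"):
            if role not in seg:
                raise ConfigError(f"{path}: segment '{key}' missing '{role}'")
            if not cfg.path(seg[role]).exists():
                raise ConfigError(
                    f"{path}: segment '{key}' {role} file not found: {seg[role]}")
    if pes_mode == "dynamic" and cfg.transforms is not None and cfg.landmarks is None:
        raise ConfigError(
            f"{path}: dynamic pes mode requires a 'landmarks' file for the "
            "outermost metatarsal condylar points")
    return cfg


def unit_scale(units: str) -> float:
    """Multiplier converting declared input units to mm."""
    return _UNIT_SCALE[units]
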
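"""Triangle meshes and articular surface patches.

Meshes are Wavefront OBJ on disk (triangles only) and 0-based index arrays
in memory; OBJ's 1-based face indices are converted at the file boundary.
The reader deliberately refuses non-triangular faces instead of
triangulating them, because patch selections refer to face indices and any
silent re-triangulation would invalidate them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh as _trimesh

from .errors import MeshFormatError, PatchError
from .geometry import unit

__all__ = ["TriMesh", "SurfacePatch", "read_mesh", "write_mesh",
           "read_patches", "write_patches", "STANDARD_PATCH_ROLES"]

#: patch roles of the hindlimb standard and the primitive fitted to each
STANDARD_PATCH_ROLES = {
    "acetabulum_right": "sphere",
    "acetabulum_left": "sphere",
    "sacral_centra": "cylinder",
    "femoral_head": "sphere",
    "femoral_condyles": "cylinder",
    "crus_proximal": "plane",
    "crus_distal": "cylinder",
    "pes_proximal": "plane",
    "pes_distal": "cylinder",
    "pes_distal_medial": "cylinder",
    "pes_distal_lateral": "cylinder",
}


@dataclass
class TriMesh:
    """A triangulated surface: ``vertices`` (n, 3) mm, ``faces`` (m, 3) ints."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        f = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if not np.all(np.isfinite(v)):
            raise MeshFormatError("mesh has non-finite vertex coordinates")
        if len(f) and (f.min() < 0 or f.max() >= len(v)):
            raise MeshFormatError(
                f"face index out of range (mesh has {len(v)} vertices)")
        degen = (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
        if degen.any():
            raise MeshFormatError(
                f"degenerate face(s) with repeated vertices: {np.where(degen)[0].tolist()}")
        self.vertices = v
        self.faces = f

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_areas(self) -> np.ndarray:
        a = self.vertices[self.faces[:, 1]] - self.vertices[self.faces[:, 0]]
        b = self.vertices[self.faces[:, 2]] - self.vertices[self.faces[:, 0]]
        return 0.5 * np.linalg.norm(np.cross(a, b), axis=1)

    def face_centroids(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    def to_trimesh(self) -> _trimesh.Trimesh:
        """View as a :class:`trimesh.Trimesh` (no processing/reordering)."""
        return _trimesh.Trimesh(vertices=self.vertices.copy(),
                                faces=self.faces.copy(), process=False)


@dataclass
class SurfacePatch:
    """A named subset of mesh faces representing one articular surface."""

    name: str
    face_indices: np.ndarray
    reference_direction: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.face_indices, dtype=np.int64))
        if idx.size == 0:
            raise PatchError(f"patch '{self.name}' is empty")
        self.face_indices = idx
        if self.reference_direction is not None:
            self.reference_direction = unit(self.reference_direction)

    def validate(self, mesh: TriMesh) -> None:
        if self.face_indices.min() < 0 or self.face_indices.max() >= mesh.n_faces:
            raise PatchError(
                f"patch '{self.name}': face index "
                f"{int(self.face_indices.max())} out of range for a mesh with "
                f"{mesh.n_faces} faces")

    def vertices(self, mesh: TriMesh) -> np.ndarray:
        """Unique vertex coordinates of the patch, in mesh order."""
        vids = np.unique(mesh.faces[self.face_indices].ravel())
        return mesh.vertices[vids]

    def faces_local(self, mesh: TriMesh) -> tuple[np.ndarray, np.ndarray]:
        """(vertices, reindexed faces) of the patch as a standalone mesh."""
        sub = mesh.faces[self.face_indices]
        vids, inv = np.unique(sub.ravel(), return_inverse=True)
        return mesh.vertices[vids], inv.reshape(-1, 3)

    def area(self, mesh: TriMesh) -> float:
        return float(mesh.face_areas()[self.face_indices].sum())


def read_mesh(path) -> TriMesh:
    """Read a triangles-only Wavefront OBJ.

    Only ``v`` and ``f`` records are interpreted; 1-based OBJ indices are
    converted to 0-based. A face with other than three vertices raises
    :class:`MeshFormatError` naming the offending face.
    """
    path = Path(path)
    vertices: list[list[float]] = []
    faces: list[list[int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            tag = parts[0]
            if tag == "v":
                if len(parts) < 4:
                    raise MeshFormatError(f"{path}:{lineno}: malformed vertex line")
                vertices.append([float(x) for x in parts[1:4]])
            elif tag == "f":
                refs = parts[1:]
                if len(refs) != 3:
                    raise MeshFormatError(
                        f"{path}:{lineno}: face {len(faces)} has {len(refs)} "
                        "vertices; only triangles are supported (re-export "
                        "without quads/polygons)")
                try:
                    idx = [int(r.split("/")[0]) for r in refs]
                except ValueError as exc:
                    raise MeshFormatError(
                        f"{path}:{lineno}: malformed face reference") from exc
                # OBJ allows negative (relative) indices
                idx = [i - 1 if i > 0 else len(vertices) + i for i in idx]
                faces.append(idx)
            # vn/vt/usemtl etc. are irrelevant to patch geometry: ignored
    if not vertices or not faces:
        raise MeshFormatError(f"{path}: no triangle mesh found")
    return TriMesh(np.array(vertices), np.array(faces))


def write_mesh(mesh: TriMesh, path) -> None:
    """Write a TriMesh as a minimal OBJ (v/f records, 1-based indices)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# archopose OBJ: {mesh.n_vertices} vertices, "
                 f"{mesh.n_faces} faces\n")
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        for f in mesh.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


def read_patches(path, mesh: TriMesh, known_roles=None) -> list[SurfacePatch]:
    """Read a patch-selection JSON and validate it against ``mesh``.

    Schema: ``{"<role>": {"faces": [...], "reference_direction": [x,y,z]?}}``;
    a bare list of faces is accepted as shorthand. ``known_roles`` (default:
    the hindlimb standard's roles) restricts the accepted patch names; pass
    ``known_roles=False`` to disable the check.
    """
    if known_roles is None:
        known_roles = STANDARD_PATCH_ROLES
    with open(path) as fh:
        raw = json.load(fh)
    patches = []
    for name, val in raw.items():
        if known_roles and name not in known_roles:
            raise PatchError(
                f"unknown patch role '{name}' (expected one of "
                f"{sorted(known_roles)})")
        if isinstance(val, dict):
            faces = val["faces"]
            ref = val.get("reference_direction")
        else:
            faces, ref = val, None
        patch = SurfacePatch(name, np.asarray(faces),
                             None if ref is None else np.asarray(ref, float))
        patch.validate(mesh)
        patches.append(patch)
    return patches


def write_patches(patches: list[SurfacePatch], path) -> None:
    out = {}
    for p in patches:
        entry: dict = {"faces": p.face_indices.tolist()}
        if p.reference_direction is not None:
            entry["reference_direction"] = p.reference_direction.tolist()
        out[p.name] = entry
    with open(path, "w") as fh:
        json.dump(out, fh, indent=1)
        fh.write("\n")
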
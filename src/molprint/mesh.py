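"""Indexed triangle mesh with an explicit unit tag.

All molecular geometry is built in angstroms; print preparation rescales to
millimetres exactly once (:func:`molprint.print_prep.apply_scale`). Carrying
the unit on the mesh makes double scaling and mixed-unit Booleans detectable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UnitError

ANGSTROM = "angstrom"
MM = "mm"
_UNITS = (ANGSTROM, MM)


@dataclass
class TriMesh:
    """Triangle mesh: ``vertices`` (n, 3) float, ``faces`` (m, 3) int.

    ``vertex_colors`` is an optional (n, 3) float array with RGB in [0, 1].
    """

    vertices: np.ndarray
    faces: np.ndarray
    unit: str = ANGSTROM
    vertex_colors: np.ndarray | None = None

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.unit not in _UNITS:
            raise UnitError(f"unknown unit tag {self.unit!r}; expected one of {_UNITS}")
        if len(self.faces):
            if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
                raise ValueError("face index out of range")
            same = (
                (self.faces[:, 0] == self.faces[:, 1])
                | (self.faces[:, 1] == self.faces[:, 2])
                | (self.faces[:, 0] == self.faces[:, 2])
            )
            if same.any():
                raise ValueError("face repeats a vertex index")
        if self.vertex_colors is not None:
            self.vertex_colors = np.asarray(self.vertex_colors, dtype=np.float64).reshape(-1, 3)
            if len(self.vertex_colors) != len(self.vertices):
                raise ValueError("vertex_colors length mismatch")

    # -- basic derived quantities -------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def bounds(self) -> np.ndarray:
        """(2, 3) array of [min; max] vertex coordinates."""
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    @property
    def extents(self) -> np.ndarray:
        b = self.bounds
        return b[1] - b[0]

    def signed_volume(self) -> float:
        """Enclosed volume by the divergence theorem (sign follows winding)."""
        v = self.vertices
        t0, t1, t2 = (v[self.faces[:, i]] for i in range(3))
        return float(np.einsum("ij,ij->i", t0, np.cross(t1, t2)).sum() / 6.0)

    def face_normals(self) -> np.ndarray:
        v = self.vertices
        n = np.cross(
            v[self.faces[:, 1]] - v[self.faces[:, 0]],
            v[self.faces[:, 2]] - v[self.faces[:, 0]],
        )
        lens = np.linalg.norm(n, axis=1)
        lens[lens == 0] = 1.0
        return n / lens[:, None]

    # -- transforms ----------------------------------------------------------

    def copy(self) -> "TriMesh":
        return TriMesh(
            self.vertices.copy(),
            self.faces.copy(),
            self.unit,
            None if self.vertex_colors is None else self.vertex_colors.copy(),
        )

    def transformed(self, rotation: np.ndarray | None = None, translation=(0.0, 0.0, 0.0)) -> "TriMesh":
        """Rigidly move the mesh: ``v -> R v + t``."""
        v = self.vertices
        if rotation is not None:
            v = v @ np.asarray(rotation, dtype=float).T
        v = v + np.asarray(translation, dtype=float)
        return TriMesh(v, self.faces.copy(), self.unit,
                       None if self.vertex_colors is None else self.vertex_colors.copy())

    def flipped(self) -> "TriMesh":
        """Reverse face winding (inverts normals and signed volume)."""
        return TriMesh(self.vertices.copy(), self.faces[:, ::-1].copy(), self.unit,
                       None if self.vertex_colors is None else self.vertex_colors.copy())

    # -- interop -------------------------------------------------------------

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    @classmethod
    def from_trimesh(cls, tm, unit: str = ANGSTROM) -> "TriMesh":
        return cls(np.asarray(tm.vertices, dtype=float), np.asarray(tm.faces, dtype=np.int64), unit)


def concatenate(meshes: list[TriMesh]) -> TriMesh:
    """Concatenate meshes (same unit) into one multi-component mesh."""
    if not meshes:
        raise ValueError("no meshes to concatenate")
    unit = meshes[0].unit
    if any(m.unit != unit for m in meshes):
        raise UnitError("cannot concatenate meshes with mixed unit tags")
    verts, faces, colors = [], [], []
    has_colors = all(m.vertex_colors is not None for m in meshes)
    offset = 0
    for m in meshes:
        verts.append(m.vertices)
        faces.append(m.faces + offset)
        if has_colors:
            colors.append(m.vertex_colors)
        offset += m.n_vertices
    return TriMesh(
        np.vstack(verts),
        np.vstack(faces),
        unit,
        np.vstack(colors) if has_colors else None,
    )
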
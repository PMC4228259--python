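"""Triangle surface meshes of the vascular lumen.

:class:`TriSurfaceMesh` is the common currency of the pipeline: the synthetic
generator emits one, morphometry measures it, surface repair edits it and the
volume mesher consumes it.  Coordinates are millimetres throughout.

The container is a thin validated wrapper over plain numpy arrays;
:mod:`trimesh` is used for file I/O and for the heavier geometric queries
(ray casting, closest-point, plane sections).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh


class MeshTopologyError(ValueError):
    """Raised when a surface fails the watertight/orientation contract."""


@dataclass
class TriSurfaceMesh:
    """Watertight, consistently wound triangle mesh in mm.

    Parameters
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array
        Vertex-index triples with consistent (outward) winding.
    """

    vertices: np.ndarray
    faces: np.ndarray
    _trimesh_cache: trimesh.Trimesh | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValueError("faces must be (m, 3)")

    # ------------------------------------------------------------------
    # topology / validation
    # ------------------------------------------------------------------
    def directed_edges(self) -> np.ndarray:
        """All directed edges (3 per face), shape (3m, 2)."""
        f = self.faces
        return np.concatenate([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])

    def validate(self, require_watertight: bool = True) -> None:
        """Check the TriSurfaceMesh invariants, raising on violation.

        Invariants: indices in range, no zero-area faces, and (if
        ``require_watertight``) every undirected edge shared by exactly two
        faces with opposite directed orientation.
        """
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise MeshTopologyError("face index out of range")
        if self.faces.size and self.faces.min() < 0:
            raise MeshTopologyError("negative face index")
        areas = self.face_areas()
        if np.any(areas <= 0):
            raise MeshTopologyError(
                f"{int(np.sum(areas <= 0))} zero-area faces present"
            )
        if require_watertight:
            de = self.directed_edges()
            # consistent winding: each directed edge appears exactly once
            keys = de[:, 0] * len(self.vertices) + de[:, 1]
            if len(np.unique(keys)) != len(keys):
                raise MeshTopologyError("repeated directed edge (folded winding)")
            # watertight: undirected edge count == 2 everywhere, i.e. the
            # reversed directed edge exists for every directed edge
            rev = de[:, 1] * len(self.vertices) + de[:, 0]
            if not np.isin(keys, rev).all():
                n_bad = int(np.sum(~np.isin(keys, rev)))
                raise MeshTopologyError(f"{n_bad} boundary/non-manifold edges")

    def is_watertight(self) -> bool:
        try:
            self.validate(require_watertight=True)
            return True
        except MeshTopologyError:
            return False

    def boundary_loops(self) -> list[np.ndarray]:
        """Ordered vertex loops of the open boundary (empty if watertight)."""
        de = self.directed_edges()
        keys = de[:, 0] * len(self.vertices) + de[:, 1]
        rev = de[:, 1] * len(self.vertices) + de[:, 0]
        boundary = de[~np.isin(keys, rev)]
        if len(boundary) == 0:
            return []
        starts = boundary[:, 0].tolist()
        if len(set(starts)) != len(starts):
            raise MeshTopologyError(
                "non-simple boundary: a vertex belongs to more than one "
                "boundary loop (pinch point)"
            )
        nxt = dict(zip(starts, boundary[:, 1].tolist()))
        loops = []
        remaining = set(nxt)
        cap = len(boundary) + 1
        while remaining:
            start = min(remaining)
            loop = [start]
            remaining.discard(start)
            cur = nxt[start]
            while cur != start:
                loop.append(cur)
                remaining.discard(cur)
                cur = nxt.get(cur)
                if cur is None or len(loop) > cap:
                    raise MeshTopologyError("boundary loop does not close")
            loops.append(np.asarray(loop, dtype=np.int64))
        return loops

    # ------------------------------------------------------------------
    # geometry
    # ------------------------------------------------------------------
    def face_areas(self) -> np.ndarray:
        v = self.vertices[self.faces]
        return 0.5 * np.linalg.norm(
            np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1
        )

    def face_normals(self) -> np.ndarray:
        v = self.vertices[self.faces]
        n = np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0])
        norm = np.linalg.norm(n, axis=1, keepdims=True)
        return n / np.maximum(norm, 1e-300)

    def face_centers(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted vertex normals."""
        fn = self.face_normals() * self.face_areas()[:, None]
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.faces[:, k], fn)
        norm = np.linalg.norm(vn, axis=1, keepdims=True)
        return vn / np.maximum(norm, 1e-300)

    def volume(self) -> float:
        """Enclosed volume (signed; positive for outward winding)."""
        v = self.vertices[self.faces]
        return float(np.einsum("ij,ij->", v[:, 0], np.cross(v[:, 1], v[:, 2])) / 6.0)

    def edge_lengths(self) -> np.ndarray:
        de = self.directed_edges()
        return np.linalg.norm(self.vertices[de[:, 1]] - self.vertices[de[:, 0]], axis=1)

    def vertex_adjacency(self) -> list[np.ndarray]:
        """Per-vertex array of neighbouring vertex indices."""
        de = self.directed_edges()
        order = np.argsort(de[:, 0], kind="stable")
        de = de[order]
        splits = np.searchsorted(de[:, 0], np.arange(len(self.vertices) + 1))
        return [
            np.unique(de[splits[i]: splits[i + 1], 1])
            for i in range(len(self.vertices))
        ]

    # ------------------------------------------------------------------
    # conversion / io
    # ------------------------------------------------------------------
    def to_trimesh(self) -> trimesh.Trimesh:
        if self._trimesh_cache is None:
            self._trimesh_cache = trimesh.Trimesh(
                vertices=self.vertices.copy(), faces=self.faces.copy(), process=False
            )
        return self._trimesh_cache

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh) -> "TriSurfaceMesh":
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces))

    @classmethod
    def load(cls, path: str | Path) -> "TriSurfaceMesh":
        tm = trimesh.load_mesh(str(path), process=False)
        if isinstance(tm, trimesh.Scene):  # multi-body files
            tm = tm.to_mesh()
        return cls.from_trimesh(tm)

    def save(self, path: str | Path, ascii_stl: bool = False) -> None:
        path = Path(path)
        tm = self.to_trimesh()
        if path.suffix.lower() == ".stl" and ascii_stl:
            path.write_text(
                trimesh.exchange.stl.export_stl_ascii(tm)
            )
        else:
            tm.export(str(path))

    def copy(self) -> "TriSurfaceMesh":
        return TriSurfaceMesh(self.vertices.copy(), self.faces.copy())

    def transformed(self, matrix: np.ndarray) -> "TriSurfaceMesh":
        """Apply a 4x4 homogeneous transform (rigid or affine)."""
        m = np.asarray(matrix, dtype=float)
        v = self.vertices @ m[:3, :3].T + m[:3, 3]
        return TriSurfaceMesh(v, self.faces.copy())
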
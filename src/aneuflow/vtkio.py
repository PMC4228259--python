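"""Minimal legacy-VTK (ASCII) writers for fields and wall surfaces.

Writes the two flavors the pipeline needs: an unstructured tetrahedral grid
with nodal vectors/scalars (velocity, pressure) and a triangle surface with
per-cell scalars (WSS, WSSG, pressure).  Legacy ASCII keeps the artifacts
plain text and viewable in ParaView.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def _header(f, title: str) -> None:
    f.write("# vtk DataFile Version 3.0\n")
    f.write(f"{title}\n")
    f.write("ASCII\n")


def write_tet_grid(path, nodes: np.ndarray, tets: np.ndarray,
                   point_scalars: dict[str, np.ndarray] | None = None,
                   point_vectors: dict[str, np.ndarray] | None = None,
                   title: str = "aneuflow field") -> None:
    """Unstructured tet grid with nodal data arrays."""
    path = Path(path)
    with path.open("w") as f:
        _header(f, title)
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {len(nodes)} float\n")
        for p in nodes:
            f.write("%.6g %.6g %.6g\n" % tuple(p))
        f.write(f"CELLS {len(tets)} {5 * len(tets)}\n")
        for t in tets:
            f.write("4 %d %d %d %d\n" % tuple(t))
        f.write(f"CELL_TYPES {len(tets)}\n")
        f.write("10\n" * len(tets))
        if point_scalars or point_vectors:
            f.write(f"POINT_DATA {len(nodes)}\n")
            for name, arr in (point_scalars or {}).items():
                f.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                for v in arr:
                    f.write("%.6g\n" % v)
            for name, arr in (point_vectors or {}).items():
                f.write(f"VECTORS {name} float\n")
                for v in arr:
                    f.write("%.6g %.6g %.6g\n" % tuple(v))


def write_tri_surface(path, nodes: np.ndarray, tris: np.ndarray,
                      cell_scalars: dict[str, np.ndarray] | None = None,
                      title: str = "aneuflow wall") -> None:
    """Triangle surface (POLYDATA) with per-cell data arrays."""
    path = Path(path)
    with path.open("w") as f:
        _header(f, title)
        f.write("DATASET POLYDATA\n")
        f.write(f"POINTS {len(nodes)} float\n")
        for p in nodes:
            f.write("%.6g %.6g %.6g\n" % tuple(p))
        f.write(f"POLYGONS {len(tris)} {4 * len(tris)}\n")
        for t in tris:
            f.write("3 %d %d %d\n" % tuple(t))
        if cell_scalars:
            f.write(f"CELL_DATA {len(tris)}\n")
            for name, arr in cell_scalars.items():
                f.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                for v in arr:
                    f.write("%.6g\n" % v)


def write_polylines(path, lines: list[np.ndarray],
                    title: str = "aneuflow streamlines") -> None:
    """Streamline bundle as POLYDATA line cells."""
    path = Path(path)
    pts = np.vstack(lines) if lines else np.zeros((0, 3))
    with path.open("w") as f:
        _header(f, title)
        f.write("DATASET POLYDATA\n")
        f.write(f"POINTS {len(pts)} float\n")
        for p in pts:
            f.write("%.6g %.6g %.6g\n" % tuple(p))
        total = sum(len(ln) + 1 for ln in lines)
        f.write(f"LINES {len(lines)} {total}\n")
        off = 0
        for ln in lines:
            ids = " ".join(str(off + i) for i in range(len(ln)))
            f.write(f"{len(ln)} {ids}\n")
            off += len(ln)
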
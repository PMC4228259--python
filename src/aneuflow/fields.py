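"""Time-resolved flow fields on tetrahedral meshes.

A :class:`FlowField` stores nodal velocity (mm/s) and pressure (Pa) for every
time step of a cardiac cycle, together with the step times and the index of
peak systole (the argmax of the inlet-speed waveform) at which all hemodynamic
readouts are taken.  Linear (P1) barycentric interpolation makes the field
evaluable at arbitrary points for streamline tracing and section sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree


class PointOutsideDomainError(ValueError):
    """Query point is not inside any tetrahedron of the mesh."""


class TetInterpolator:
    """Locate points in a tet mesh and interpolate nodal fields linearly.

    Point location uses a KD-tree over tet centroids followed by exact
    barycentric containment tests on the nearest candidates.
    """

    def __init__(self, nodes: np.ndarray, tets: np.ndarray):
        self.nodes = np.asarray(nodes, dtype=float)
        self.tets = np.asarray(tets, dtype=np.int64)
        p = self.nodes[self.tets]
        self.origins = p[:, 0]
        # columns of T are the tet edge vectors from vertex 0
        T = np.stack([p[:, 1] - p[:, 0], p[:, 2] - p[:, 0], p[:, 3] - p[:, 0]], axis=2)
        self.Tinv = np.linalg.inv(T)
        self.centroids = p.mean(axis=1)
        self.tree = cKDTree(self.centroids)
        # search radius: circumscribing scale of the largest tet
        self.max_extent = float(np.max(np.linalg.norm(p - self.centroids[:, None, :], axis=2)))

    def locate(self, points: np.ndarray, k: int = 24, tol: float = 1e-9):
        """Return (tet_index, barycentric (n,4)); index -1 where outside."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        n = len(points)
        k = min(k, len(self.tets))
        _, cand = self.tree.query(points, k=k)
        cand = np.atleast_2d(cand)
        tet_idx = np.full(n, -1, dtype=np.int64)
        bary = np.zeros((n, 4))
        pending = np.arange(n)
        for col in range(k):
            if len(pending) == 0:
                break
            c = cand[pending, col]
            d = points[pending] - self.origins[c]
            lam = np.einsum("nij,nj->ni", self.Tinv[c], d)
            lam0 = 1.0 - lam.sum(axis=1)
            ok = (lam.min(axis=1) >= -tol) & (lam0 >= -tol)
            hit = pending[ok]
            tet_idx[hit] = c[ok]
            bary[hit, 0] = lam0[ok]
            bary[hit, 1:] = lam[ok]
            pending = pending[~ok]
        return tet_idx, bary

    def interpolate(self, values: np.ndarray, points: np.ndarray,
                    outside: str = "raise") -> np.ndarray:
        """Interpolate nodal ``values`` (n_nodes, ...) at ``points``.

        ``outside`` is ``"raise"``, ``"nan"`` or ``"zero"``.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        tet_idx, bary = self.locate(points)
        miss = tet_idx < 0
        if miss.any() and outside == "raise":
            raise PointOutsideDomainError(
                f"{int(miss.sum())} of {len(points)} points outside the mesh"
            )
        safe = np.where(miss, 0, tet_idx)
        corners = values[self.tets[safe]]  # (n, 4, ...)
        out = np.einsum("nc,nc...->n...", bary, corners)
        if miss.any():
            out[miss] = np.nan if outside == "nan" else 0.0
        return out

    def inside(self, points: np.ndarray) -> np.ndarray:
        tet_idx, _ = self.locate(points)
        return tet_idx >= 0


@dataclass
class FlowField:
    """Velocity/pressure history on a tet mesh.

    velocities : (n_steps, n_nodes, 3) in mm/s
    pressures : (n_steps, n_nodes) in Pa
    times : (n_steps,) in s, strictly increasing
    peak_systole_index : argmax of the inlet speed waveform
    """

    nodes: np.ndarray
    tets: np.ndarray
    velocities: np.ndarray
    pressures: np.ndarray
    times: np.ndarray
    peak_systole_index: int
    _interp: TetInterpolator | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("step times must be strictly increasing")
        if not 0 <= self.peak_systole_index < len(self.times):
            raise ValueError("peak_systole_index out of range")

    @property
    def n_steps(self) -> int:
        return len(self.times)

    def interpolator(self) -> TetInterpolator:
        if self._interp is None:
            self._interp = TetInterpolator(self.nodes, self.tets)
        return self._interp

    def velocity_at(self, points: np.ndarray, step: int,
                    outside: str = "raise") -> np.ndarray:
        if not 0 <= step < self.n_steps:
            raise IndexError(f"step {step} out of range [0, {self.n_steps})")
        return self.interpolator().interpolate(
            self.velocities[step], points, outside=outside
        )

    def pressure_at(self, points: np.ndarray, step: int,
                    outside: str = "raise") -> np.ndarray:
        if not 0 <= step < self.n_steps:
            raise IndexError(f"step {step} out of range [0, {self.n_steps})")
        return self.interpolator().interpolate(
            self.pressures[step], points, outside=outside
        )


def box_tet_lattice(origin: np.ndarray, pitch: float, shape: tuple[int, int, int]):
    """Regular box lattice of nodes split into 6 tets per cube (Kuhn split).

    ``shape`` counts cells per axis; returns (nodes (n,3), tets (m,4)) with
    positively oriented tets, consistent across neighbouring cubes.
    """
    nx, ny, nz = shape
    ii, jj, kk = np.meshgrid(
        np.arange(nx + 1), np.arange(ny + 1), np.arange(nz + 1), indexing="ij"
    )
    nodes = origin + pitch * np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    ci, cj, ck = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    ci, cj, ck = ci.ravel(), cj.ravel(), ck.ravel()
    c = {}
    for di in (0, 1):
        for dj in (0, 1):
            for dk in (0, 1):
                c[(di, dj, dk)] = nid(ci + di, cj + dj, ck + dk)
    # Kuhn/Freudenthal: 6 tets around the main diagonal (0,0,0)-(1,1,1)
    paths = [
        [(0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1)],
        [(0, 0, 0), (1, 0, 0), (1, 0, 1), (1, 1, 1)],
        [(0, 0, 0), (0, 1, 0), (1, 1, 0), (1, 1, 1)],
        [(0, 0, 0), (0, 1, 0), (0, 1, 1), (1, 1, 1)],
        [(0, 0, 0), (0, 0, 1), (1, 0, 1), (1, 1, 1)],
        [(0, 0, 0), (0, 0, 1), (0, 1, 1), (1, 1, 1)],
    ]
    tets = np.concatenate(
        [np.stack([c[a], c[b], c[d], c[e]], axis=1) for a, b, d, e in paths]
    )
    # enforce positive orientation
    p = nodes[tets]
    vol6 = np.einsum(
        "ij,ij->i", np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), p[:, 3] - p[:, 0]
    )
    flip = vol6 < 0
    tets[flip][:, [0, 1]] = tets[flip][:, [1, 0]]
    if flip.any():
        t = tets[flip].copy()
        t[:, [0, 1]] = t[:, [1, 0]]
        tets[flip] = t
    return nodes, tets
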
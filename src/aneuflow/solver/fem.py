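"""Linear (P1) finite-element operators on tetrahedral meshes.

Assembles, in SI units (coordinates in metres), the sparse operators used by
the projection solver: stiffness K = int grad(phi_i) . grad(phi_j), lumped
mass M, and the first-derivative matrices C_d[i, j] = int phi_i d(phi_j)/dx_d,
from which the weak divergence of a nodal velocity and the nodal gradient of
pressure both follow.  P1 basis gradients are constant per tet, so everything
assembles in a few vectorized passes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp


@dataclass
class P1Operators:
    n_nodes: int
    volumes: np.ndarray          # (m,) tet volumes, m^3
    grads: np.ndarray            # (m, 4, 3) basis gradients, 1/m
    K: sp.csr_matrix             # stiffness
    M_lumped: np.ndarray         # (n,) lumped mass, m^3
    C: tuple[sp.csr_matrix, sp.csr_matrix, sp.csr_matrix]
    tets: np.ndarray
    scatter: sp.csr_matrix = None   # (n, m): V/4 per corner, cell -> node
    scatter4: sp.csr_matrix = None  # (n, 4m): unit entries, corner -> node

    def divergence(self, u: np.ndarray) -> np.ndarray:
        """Weak divergence: b_i = int phi_i div(u) for nodal u (n, 3)."""
        return self.C[0] @ u[:, 0] + self.C[1] @ u[:, 1] + self.C[2] @ u[:, 2]

    def nodal_gradient(self, p: np.ndarray) -> np.ndarray:
        """Mass-lumped L2 projection of grad(p) onto the nodes, (n, 3)."""
        g = np.stack([self.C[0] @ p, self.C[1] @ p, self.C[2] @ p], axis=1)
        return g / self.M_lumped[:, None]

    def cell_velocity_gradient(self, u: np.ndarray) -> np.ndarray:
        """Per-tet velocity gradient G[m, d, e] = d(u_e)/dx_d."""
        return np.einsum("mcd,mce->mde", self.grads, u[self.tets])

    def advection(self, u: np.ndarray, h_cell: np.ndarray | None = None,
                  upwind: float = 0.5) -> np.ndarray:
        """Nodal (u . grad) u via per-tet constant gradients, (n, 3).

        With ``h_cell`` given, adds streamline artificial viscosity
        nu_art = upwind * |u| * h per cell (first-order upwind equivalent),
        which makes the explicit sub-cycled transport dissipative and stable
        at CFL < 1.
        """
        un = u[self.tets]
        u_cell = un.mean(axis=1)                            # (m, 3)
        G = np.einsum("mcd,mce->mde", self.grads, un)
        adv_cell = np.einsum("md,mde->me", u_cell, G)       # (m, 3)
        r = self.scatter @ adv_cell
        if h_cell is not None:
            # streamline diffusion only: it damps the along-stream
            # oscillations of central advection but vanishes for fully
            # developed flow, so it does not act like extra viscosity
            speed = np.linalg.norm(u_cell, axis=1)
            nu = upwind * speed * h_cell
            s = np.einsum("mcd,md->mc", self.grads, u_cell)   # d-hat . grad
            with np.errstate(invalid="ignore", divide="ignore"):
                s = s / np.where(speed > 0, speed, 1.0)[:, None]
            t = np.einsum("mc,mce->me", s, un)                # (m, 3)
            corner = np.einsum(
                "m,mc,me->mce", nu * self.volumes, s, t
            )                                                  # (m, 4, 3)
            r = r + self.scatter4 @ corner.reshape(-1, 3)
        return r / self.M_lumped[:, None]


def assemble(nodes_m: np.ndarray, tets: np.ndarray) -> P1Operators:
    """Assemble P1 operators; ``nodes_m`` must be in metres."""
    tets = np.asarray(tets, dtype=np.int64)
    p = nodes_m[tets]
    e1 = p[:, 1] - p[:, 0]
    e2 = p[:, 2] - p[:, 0]
    e3 = p[:, 3] - p[:, 0]
    vol6 = np.einsum("ij,ij->i", np.cross(e1, e2), e3)
    if np.any(vol6 <= 0):
        raise ValueError("tet mesh contains non-positive volumes")
    V = vol6 / 6.0
    g1 = np.cross(e2, e3) / vol6[:, None]
    g2 = np.cross(e3, e1) / vol6[:, None]
    g3 = np.cross(e1, e2) / vol6[:, None]
    g0 = -(g1 + g2 + g3)
    grads = np.stack([g0, g1, g2, g3], axis=1)  # (m, 4, 3)

    n = int(tets.max()) + 1
    # COO index pattern: entry (m, i, j) -> row tets[m, i], col tets[m, j]
    rows = np.repeat(tets, 4, axis=1).ravel()
    cols = np.tile(tets, (1, 4)).ravel()

    kv = np.einsum("mid,mjd,m->mij", grads, grads, V)
    K = sp.coo_matrix((kv.ravel(), (rows, cols)), shape=(n, n)).tocsr()

    M = np.zeros(n)
    for c in range(4):
        np.add.at(M, tets[:, c], V / 4.0)

    C = []
    for d in range(3):
        # value for (i, j) is (V/4) * grads[j, d], independent of i
        vals = np.broadcast_to(
            ((V / 4.0)[:, None] * grads[:, :, d])[:, None, :],
            (len(V), 4, 4),
        )
        Cd = sp.coo_matrix(
            (np.ascontiguousarray(vals).ravel(), (rows, cols)), shape=(n, n)
        ).tocsr()
        C.append(Cd)

    m = len(tets)
    scatter = sp.coo_matrix(
        (np.repeat(V / 4.0, 4),
         (tets.ravel(), np.repeat(np.arange(m), 4))),
        shape=(n, m),
    ).tocsr()
    scatter4 = sp.coo_matrix(
        (np.ones(4 * m), (tets.ravel(), np.arange(4 * m))),
        shape=(n, 4 * m),
    ).tocsr()

    return P1Operators(
        n_nodes=n, volumes=V, grads=grads, K=K, M_lumped=M,
        C=(C[0], C[1], C[2]), tets=tets, scatter=scatter, scatter4=scatter4,
    )
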
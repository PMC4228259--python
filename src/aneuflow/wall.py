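"""Wall shear stress, its surface gradient, and cross-section statistics.

WSS is the tangential viscous traction mu (grad u + grad u^T) n at the lumen
wall, in Pa.  Per wall facet it is recovered from a quadratic fit of the
tangential velocity sampled along the inward wall normal (u_t(0) = 0 by
no-slip), which is markedly more accurate on unstructured tets than a
single-cell gradient.  WSSG is the magnitude of the surface-tangential
gradient of the WSS magnitude, in Pa/mm, computed exactly for facetwise
linear fields from the P1 surface gradient of vertex-averaged WSS.

Cross-section statistics sample ``n_points`` evenly spaced positions around
the wall intersection curve of a plane (WSS, pressure) and matching interior
positions (velocity), reported as mean +/- sample (n-1) standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fields import FlowField
from .solver.flow import FluidProperties
from .solver.volume import WALL, VolumeMesh


@dataclass
class WallField:
    """Per-wall-facet hemodynamic quantities at one time step."""

    facet_tris: np.ndarray       # (f, 3) node indices (outward winding)
    centers: np.ndarray          # (f, 3) mm
    normals: np.ndarray          # (f, 3) outward unit
    areas: np.ndarray            # (f,) mm^2
    wss_vec: np.ndarray          # (f, 3) Pa
    wss_mag: np.ndarray          # (f,) Pa
    pressure: np.ndarray         # (f,) Pa
    step_index: int
    wssg: np.ndarray | None = None   # (f,) Pa/mm

    def __post_init__(self) -> None:
        if np.any(self.wss_mag < 0):
            raise ValueError("WSS magnitude must be non-negative")


@dataclass
class SectionStats:
    """Mean +/- sample SD of wall and lumen quantities on one section."""

    label: str
    n_points: int
    wss_mean: float
    wss_sd: float
    pressure_mean: float
    pressure_sd: float
    velocity_mean: float
    velocity_sd: float

    def __post_init__(self) -> None:
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")
        for sd in (self.wss_sd, self.pressure_sd, self.velocity_sd):
            if sd < 0:
                raise ValueError("SD must be non-negative")

    def to_dict(self) -> dict:
        return {
            "label": self.label, "n_points": self.n_points,
            "wss_mean_Pa": self.wss_mean, "wss_sd_Pa": self.wss_sd,
            "pressure_mean_Pa": self.pressure_mean,
            "pressure_sd_Pa": self.pressure_sd,
            "velocity_mean_mm_s": self.velocity_mean,
            "velocity_sd_mm_s": self.velocity_sd,
        }


def _sample_sd(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.std(x, ddof=1)) if len(x) > 1 else 0.0


# ----------------------------------------------------------------------
# WSS
# ----------------------------------------------------------------------
def compute_wss(fieldf: FlowField, vmesh: VolumeMesh, fluid: FluidProperties,
                step: int) -> WallField:
    """Wall shear stress on every wall facet at ``step``.

    The tangential velocity is interpolated at two stations along the
    inward normal and fitted with u_t = a d + b d^2 (no-slip at d = 0);
    WSS = mu a.  Linear in viscosity, zero for zero flow.
    """
    if not 0 <= step < fieldf.n_steps:
        raise IndexError(f"step {step} out of range")
    tris = vmesh.boundary_tris[vmesh.boundary_tags == WALL]
    pts = vmesh.nodes[tris]
    centers = pts.mean(axis=1)
    nvec = np.cross(pts[:, 1] - pts[:, 0], pts[:, 2] - pts[:, 0])
    areas = 0.5 * np.linalg.norm(nvec, axis=1)
    normals = nvec / np.maximum(2 * areas[:, None], 1e-300)

    h = vmesh.pitch
    d1, d2 = 0.8 * h, 1.6 * h
    u1 = fieldf.velocity_at(centers - d1 * normals, step, outside="nan")
    u2 = fieldf.velocity_at(centers - d2 * normals, step, outside="nan")
    # stations outside the lumen (thin regions): fall back to half spacing
    miss = ~np.isfinite(u1[:, 0]) | ~np.isfinite(u2[:, 0])
    if miss.any():
        u1[miss] = fieldf.velocity_at(
            centers[miss] - 0.4 * h * normals[miss], step, outside="zero")
        u2[miss] = fieldf.velocity_at(
            centers[miss] - 0.8 * h * normals[miss], step, outside="zero")
    dd1 = np.where(miss, 0.4 * h, d1)
    dd2 = np.where(miss, 0.8 * h, d2)

    u1t = u1 - normals * np.einsum("ij,ij->i", u1, normals)[:, None]
    u2t = u2 - normals * np.einsum("ij,ij->i", u2, normals)[:, None]
    denom = (dd1 * dd2**2 - dd2 * dd1**2)[:, None]
    a = (u1t * (dd2**2)[:, None] - u2t * (dd1**2)[:, None]) / denom  # 1/s
    mu = fluid.dynamic_viscosity
    wss_vec = mu * a
    wss_mag = np.linalg.norm(wss_vec, axis=1)

    p_nodal = fieldf.pressures[step]
    pressure = p_nodal[tris].mean(axis=1)
    return WallField(
        facet_tris=tris, centers=centers, normals=normals, areas=areas,
        wss_vec=wss_vec, wss_mag=wss_mag, pressure=pressure, step_index=step,
    )


# ----------------------------------------------------------------------
# WSSG
# ----------------------------------------------------------------------
def compute_wssg(wall: WallField, vmesh: VolumeMesh,
                 vertex_values: np.ndarray | None = None) -> WallField:
    """Surface-tangential gradient magnitude of WSS magnitude (Pa/mm).

    Facet WSS is first area-averaged to the wall vertices (unless
    ``vertex_values`` supplies a nodal field directly), then the in-plane
    P1 gradient per facet gives WSSG — exact for linear wall fields,
    identically zero for uniform ones, and frame invariant.
    """
    tris = wall.facet_tris
    n_nodes = int(tris.max()) + 1
    if vertex_values is None:
        acc = np.zeros(n_nodes)
        wsum = np.zeros(n_nodes)
        for k in range(3):
            np.add.at(acc, tris[:, k], wall.wss_mag * wall.areas)
            np.add.at(wsum, tris[:, k], wall.areas)
        vertex_values = acc / np.maximum(wsum, 1e-300)

    p = vmesh.nodes[tris]
    f = vertex_values[tris]
    # in-plane gradient of the linear interpolant on each triangle
    e1 = p[:, 1] - p[:, 0]
    e2 = p[:, 2] - p[:, 0]
    n = np.cross(e1, e2)
    nn = np.einsum("ij,ij->i", n, n)
    # grad = ((f1 - f0) (n x e2) + (f2 - f0) (e1 x n)) / |n|^2
    grad = (
        (f[:, 1] - f[:, 0])[:, None] * np.cross(n, e2)
        + (f[:, 2] - f[:, 0])[:, None] * np.cross(e1, n)
    ) / np.maximum(nn, 1e-300)[:, None]
    wall.wssg = np.linalg.norm(grad, axis=1)
    return wall


# ----------------------------------------------------------------------
# sections
# ----------------------------------------------------------------------
class SectionError(ValueError):
    """The plane misses the lumen or the requested wall region."""


def _wall_plane_crossings(wall: WallField, origin, normal):
    """Wall facets crossed by the plane, with in-plane angular order."""
    d = (wall.centers - origin) @ normal
    h = np.sqrt(wall.areas).max()
    hit = np.abs(d) < 0.8 * h
    return np.flatnonzero(hit)


def section_stats(
    fieldf: FlowField,
    wall: WallField,
    vmesh: VolumeMesh,
    origin: np.ndarray,
    normal: np.ndarray,
    label: str,
    n_points: int = 4,
    region_mask: np.ndarray | None = None,
) -> SectionStats:
    """Statistics at ``n_points`` evenly spaced stations around a section.

    Wall quantities (WSS, pressure) are read from the wall facets nearest
    the evenly spaced angular stations of the plane's wall intersection;
    velocity is sampled inside the lumen at matching angular stations
    halfway between the section centroid and the wall.  ``region_mask``
    restricts the usable wall facets (e.g. the distal neck half).
    """
    origin = np.asarray(origin, dtype=float)
    normal = np.asarray(normal, dtype=float)
    normal = normal / np.linalg.norm(normal)
    idx = _wall_plane_crossings(wall, origin, normal)
    if region_mask is not None:
        idx = idx[region_mask[idx]]
    if len(idx) == 0:
        raise SectionError(f"plane misses the wall for section '{label}'")

    pts = wall.centers[idx]
    centroid = pts.mean(axis=0)
    a = np.array([1.0, 0.0, 0.0])
    if abs(normal @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(normal, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    rel = pts - centroid
    ang = np.arctan2(rel @ e2, rel @ e1)

    # evenly spaced angular stations (deterministic start at -pi)
    stations = -np.pi + 2 * np.pi * (np.arange(n_points) + 0.5) / n_points
    wss_s, p_s, v_s = [], [], []
    radius = np.linalg.norm(
        rel - np.outer(rel @ normal, normal), axis=1
    ).mean()
    for st in stations:
        dd = np.angle(np.exp(1j * (ang - st)))
        j = idx[int(np.argmin(np.abs(dd)))]
        wss_s.append(wall.wss_mag[j])
        p_s.append(wall.pressure[j])
        probe = centroid + 0.5 * radius * (np.cos(st) * e1 + np.sin(st) * e2)
        u = fieldf.velocity_at(probe[None, :], wall.step_index, outside="nan")[0]
        if not np.isfinite(u).all():
            u = fieldf.velocity_at(centroid[None, :], wall.step_index,
                                   outside="zero")[0]
        v_s.append(float(np.linalg.norm(u)))
    return SectionStats(
        label=label, n_points=n_points,
        wss_mean=float(np.mean(wss_s)), wss_sd=_sample_sd(wss_s),
        pressure_mean=float(np.mean(p_s)), pressure_sd=_sample_sd(p_s),
        velocity_mean=float(np.mean(v_s)), velocity_sd=_sample_sd(v_s),
    )


def region_stats(wall: WallField, mask: np.ndarray, fieldf: FlowField,
                 label: str, probe_offset: float = 1.0) -> SectionStats:
    """Stats over an arbitrary wall patch (facet mask), area-weighted.

    Velocity is sampled one ``probe_offset`` (mm) inside the wall at each
    selected facet.
    """
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        raise SectionError(f"empty wall region for '{label}'")
    w = wall.areas[idx]
    wss = wall.wss_mag[idx]
    p = wall.pressure[idx]
    probes = wall.centers[idx] - probe_offset * wall.normals[idx]
    u = fieldf.velocity_at(probes, wall.step_index, outside="zero")
    v = np.linalg.norm(u, axis=1)
    mean = lambda x: float(np.average(x, weights=w))  # noqa: E731
    return SectionStats(
        label=label, n_points=len(idx),
        wss_mean=mean(wss), wss_sd=_sample_sd(wss),
        pressure_mean=mean(p), pressure_sd=_sample_sd(p),
        velocity_mean=mean(v), velocity_sd=_sample_sd(v),
    )


# ----------------------------------------------------------------------
# comparison
# ----------------------------------------------------------------------
def compare_states(aneurysm_stats: dict[str, SectionStats],
                   preaneurysm_stats: dict[str, SectionStats]) -> dict:
    """Tabulate the aneurysm-state section ordering and the formation-site
    versus adjacent-artery ratios of the repaired state.

    Returns a plain dict report with the two qualitative flags mirroring
    the study's headline findings: WSS falls from (distal) neck to dome at
    aneurysm status, and the formation site carries elevated WSS relative
    to the adjacent parent wall at pre-aneurysm status.
    """
    if not aneurysm_stats or not preaneurysm_stats:
        raise ValueError("empty stats set")
    report: dict = {"aneurysm": {}, "preaneurysm": {}, "ratios": {}}
    for k, s in aneurysm_stats.items():
        report["aneurysm"][k] = s.to_dict()
    for k, s in preaneurysm_stats.items():
        report["preaneurysm"][k] = s.to_dict()

    def ratio(a, b):
        return float(a / b) if b != 0 else float("inf")

    if "dome" in aneurysm_stats and "neck" in aneurysm_stats:
        dome = aneurysm_stats["dome"]
        neck = aneurysm_stats["neck"]
        report["ratios"]["dome_over_neck_wss"] = ratio(
            dome.wss_mean, neck.wss_mean)
        report["ratios"]["dome_over_neck_velocity"] = ratio(
            dome.velocity_mean, neck.velocity_mean)
        report["dome_wss_below_neck"] = bool(dome.wss_mean < neck.wss_mean)
    if "dome" in aneurysm_stats and "distal_neck" in aneurysm_stats:
        dome = aneurysm_stats["dome"]
        dneck = aneurysm_stats["distal_neck"]
        report["ratios"]["dome_over_distal_neck_wss"] = ratio(
            dome.wss_mean, dneck.wss_mean)
        report["dome_wss_below_distal_neck"] = bool(
            dome.wss_mean < dneck.wss_mean)
    if ("formation_site" in preaneurysm_stats
            and "adjacent" in preaneurysm_stats):
        site = preaneurysm_stats["formation_site"]
        adj = preaneurysm_stats["adjacent"]
        report["ratios"]["site_over_adjacent_wss"] = ratio(
            site.wss_mean, adj.wss_mean)
        report["ratios"]["site_over_adjacent_velocity"] = ratio(
            site.velocity_mean, adj.velocity_mean)
        report["site_wss_above_adjacent"] = bool(
            site.wss_mean > adj.wss_mean)
    return report
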
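"""Parametric vessel + sidewall-aneurysm geometry and constructed flow fields.

Patient lumen reconstructions are not available, so this module emulates them:
a tubular parent artery (optionally with a localized bend) carrying a saccular
sidewall aneurysm with controllable maximum diameter D, height H and neck
diameter N, all with analytically known ground truth.  The surface is built as
the smooth union (polynomial smooth-min fillet) of an exact tube and sphere
signed-distance field, triangulated by marching cubes, and every vertex is then
Newton-projected back onto the analytic zero level set, so mesh error is pure
piecewise-linear chord sag.

The constructed velocity fields are divergence-free superpositions of
Lamb-Oseen vortices and an inclined inflow-jet band of prescribed width and
direction schedule; their vortex census and jet width are known by
construction, which makes them exact fixtures for the flow-pattern
classifier.

All lengths are millimetres, consistent with how aneurysm morphometry is
reported clinically.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree
from skimage import measure

from .fields import FlowField, box_tet_lattice
from .mesh import MeshTopologyError, TriSurfaceMesh
from .patterns import SacRegion

DEFAULT_FILLET_FRACTION = 0.25  # fillet radius as a fraction of neck_radius


class GeometryError(ValueError):
    """Invalid or self-intersecting synthetic geometry."""


# ----------------------------------------------------------------------
# specs
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class SyntheticVesselSpec:
    """Parameters of a parent tube with an optional sidewall sac (mm).

    ``centerline_curvature`` (1/mm) bends the central third of the vessel as
    a circular arc (0 = straight); the sac sits on the outer wall of the
    bend, which is where sidewall aneurysms arise.  ``sac_height_offset``
    shifts the sac sphere centre outward along the wall normal beyond its
    default tangency position.  ``mesh_edge_target`` sets the marching-cubes
    pitch and thereby the triangle edge scale.
    """

    parent_radius: float = 2.0
    parent_length: float = 30.0
    centerline_curvature: float = 0.0
    sac_radius: float = 3.0
    neck_radius: float = 1.5
    sac_height_offset: float = 0.0
    mesh_edge_target: float = 0.35
    seed: int = 0
    fillet_fraction: float = DEFAULT_FILLET_FRACTION

    def validate(self) -> None:
        if self.parent_radius <= 0 or self.parent_length <= 0:
            raise GeometryError("parent_radius and parent_length must be > 0")
        if self.mesh_edge_target <= 0:
            raise GeometryError("mesh_edge_target must be > 0")
        if self.mesh_edge_target >= self.parent_radius:
            raise GeometryError("mesh_edge_target must be < parent_radius")
        if self.sac_radius < 0 or self.neck_radius < 0:
            raise GeometryError("radii must be >= 0")
        if self.sac_radius > 0:
            if not 0 < self.neck_radius <= self.sac_radius:
                raise GeometryError("need 0 < neck_radius <= sac_radius")
        if self.centerline_curvature < 0:
            raise GeometryError("centerline_curvature must be >= 0")
        if self.centerline_curvature * self.parent_radius >= 0.9:
            raise GeometryError("bend radius must exceed the parent radius")

    @property
    def has_sac(self) -> bool:
        return self.sac_radius > 0

    def without_sac(self) -> "SyntheticVesselSpec":
        """The sac-free twin: identical parent vessel, no aneurysm."""
        return dataclasses.replace(self, sac_radius=0.0, neck_radius=0.0)


@dataclass(frozen=True)
class ConstructedFieldSpec:
    """Constructed intra-saccular field with known vortex/jet structure."""

    n_vortices_per_step: tuple[int, ...] = (1,)
    jet_direction_changes: bool = False
    jet_width_fraction: float = 1.0
    grid_resolution: int = 40
    seed: int = 0

    def validate(self) -> None:
        counts = tuple(self.n_vortices_per_step)
        if len(counts) < 1:
            raise ValueError("need at least one time step")
        if any(c < 0 for c in counts):
            raise ValueError("vortex counts must be non-negative")
        if max(counts) > 6:
            raise ValueError("at most 6 concurrent vortices supported")
        if not 0.0 < self.jet_width_fraction <= 1.0:
            raise ValueError("jet_width_fraction must be in (0, 1]")
        if self.grid_resolution < max(8, 8 * max(counts, default=0)):
            raise ValueError(
                f"grid_resolution {self.grid_resolution} too coarse to resolve "
                f"{max(counts)} vortices; need >= {max(8, 8 * max(counts))}"
            )


# ----------------------------------------------------------------------
# ground truth record
# ----------------------------------------------------------------------
@dataclass
class VesselGroundTruth:
    """Analytic morphometry and bookkeeping for a generated vessel.

    D/H/N come from the unblended sphere + neck-plane closed forms; the
    fillet only perturbs the surface near the junction.  ``sac_face_mask``
    marks faces with any vertex strictly above the neck plane, the same rule
    the excision step uses, so removed-face counts are directly comparable.
    """

    has_sac: bool
    D: float | None
    H: float | None
    N: float | None
    neck_center: np.ndarray | None
    neck_normal: np.ndarray | None
    neck_contour: np.ndarray | None
    sac_center: np.ndarray | None
    sac_radius: float | None
    centerline_points: np.ndarray
    centerline_radius: float
    inlet_center: np.ndarray
    inlet_normal: np.ndarray  # outward
    outlet_center: np.ndarray
    outlet_normal: np.ndarray
    sac_face_mask: np.ndarray | None

    def to_dict(self) -> dict:
        def conv(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            return x

        d = {k: conv(v) for k, v in dataclasses.asdict(self).items()
             if k not in ("sac_face_mask", "centerline_points", "neck_contour")}
        d["n_sac_faces"] = (
            int(self.sac_face_mask.sum()) if self.sac_face_mask is not None else 0
        )
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


# ----------------------------------------------------------------------
# centerline curve
# ----------------------------------------------------------------------
def centerline_curve(spec: SyntheticVesselSpec, spacing: float):
    """Sample the parent centerline at ~``spacing`` arc-length intervals.

    Returns (points, tangents, attach_point, attach_normal) where the
    attachment is the sac anchor on the vessel wall at mid-length, on the
    outer side of the bend (straight case: the +z generator line).
    """
    L = spec.parent_length
    n = max(int(np.ceil(L / spacing)) + 1, 9)
    s = np.linspace(0.0, L, n)
    kappa = spec.centerline_curvature
    pts = np.zeros((n, 3))
    tans = np.zeros((n, 3))
    if kappa == 0.0:
        pts[:, 0] = s
        tans[:, 0] = 1.0
        attach_c = np.array([L / 2.0, 0.0, 0.0])
        attach_n = np.array([0.0, 0.0, 1.0])
    else:
        R = 1.0 / kappa
        s1, s2 = L / 3.0, 2.0 * L / 3.0
        theta = kappa * (s2 - s1)
        A = np.array([s1, 0.0, 0.0])
        center = A + np.array([0.0, 0.0, -R])
        for i, si in enumerate(s):
            if si <= s1:
                pts[i] = [si, 0.0, 0.0]
                tans[i] = [1.0, 0.0, 0.0]
            elif si <= s2:
                phi = kappa * (si - s1)
                pts[i] = center + R * np.array([np.sin(phi), 0.0, np.cos(phi)])
                tans[i] = [np.cos(phi), 0.0, -np.sin(phi)]
            else:
                phi = theta
                p_end = center + R * np.array([np.sin(phi), 0.0, np.cos(phi)])
                t_end = np.array([np.cos(phi), 0.0, -np.sin(phi)])
                pts[i] = p_end + (si - s2) * t_end
                tans[i] = t_end
        phi_mid = theta / 2.0
        c_mid = center + R * np.array([np.sin(phi_mid), 0.0, np.cos(phi_mid)])
        attach_n = np.array([np.sin(phi_mid), 0.0, np.cos(phi_mid)])
        attach_c = c_mid
    attach_point = attach_c + spec.parent_radius * attach_n
    return pts, tans, attach_point, attach_n


class _VesselSDF:
    """Signed distance style level-set of the capped tube + sac solid."""

    def __init__(self, spec: SyntheticVesselSpec, curve_spacing: float):
        self.spec = spec
        pts, tans, attach_pt, attach_n = centerline_curve(spec, curve_spacing)
        self.curve = pts
        self.tans = tans
        self.attach_point = attach_pt
        self.attach_normal = attach_n
        self.tree = cKDTree(pts)
        self.p_in, self.t_in = pts[0], tans[0]
        self.p_out, self.t_out = pts[-1], tans[-1]
        if spec.has_sac:
            d_center = np.sqrt(spec.sac_radius**2 - spec.neck_radius**2)
            d_center += spec.sac_height_offset
            if d_center >= spec.sac_radius:
                raise GeometryError(
                    "sac sphere detached from the parent wall: centre height "
                    f"{d_center:.3f} mm >= sac_radius {spec.sac_radius:.3f} mm"
                )
            if spec.parent_radius + d_center - spec.sac_radius <= 0.15 * spec.parent_radius:
                raise GeometryError(
                    "sac/parent self-intersection: sphere (centre height "
                    f"{d_center:.3f} mm above wall, radius {spec.sac_radius:.3f} mm) "
                    "reaches the parent lumen axis"
                )
            if spec.sac_radius + spec.parent_radius > spec.parent_length / 2.5:
                raise GeometryError(
                    "sac too large for the vessel length: the sphere approaches "
                    "the inlet/outlet caps"
                )
            self.d_center = d_center
            self.sac_center = attach_pt + d_center * attach_n
            self.fillet = spec.fillet_fraction * spec.neck_radius
        else:
            self.d_center = None
            self.sac_center = None
            self.fillet = 0.0

    def dist_to_curve(self, p: np.ndarray) -> np.ndarray:
        """Exact distance from points to the sampled centerline polyline."""
        _, idx = self.tree.query(p)
        pts = self.curve
        n = len(pts)
        best = np.full(len(p), np.inf)
        for lo in (np.maximum(idx - 1, 0), idx):
            hi = np.minimum(lo + 1, n - 1)
            a, b = pts[lo], pts[hi]
            ab = b - a
            denom = np.einsum("ij,ij->i", ab, ab)
            t = np.einsum("ij,ij->i", p - a, ab) / np.maximum(denom, 1e-300)
            t = np.clip(t, 0.0, 1.0)
            proj = a + t[:, None] * ab
            d = np.linalg.norm(p - proj, axis=1)
            best = np.minimum(best, d)
        return best

    def __call__(self, p: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(p)
        f_side = self.dist_to_curve(p) - self.spec.parent_radius
        f_in = -np.einsum("ij,j->i", p - self.p_in, self.t_in)
        f_out = np.einsum("ij,j->i", p - self.p_out, self.t_out)
        f_tube = np.maximum(f_side, np.maximum(f_in, f_out))
        if self.sac_center is None:
            return f_tube
        f_sac = np.linalg.norm(p - self.sac_center, axis=1) - self.spec.sac_radius
        return _smooth_min(f_tube, f_sac, self.fillet)


def _smooth_min(a: np.ndarray, b: np.ndarray, k: float) -> np.ndarray:
    """Polynomial smooth minimum (union with fillet of scale ``k``)."""
    if k <= 0:
        return np.minimum(a, b)
    h = np.clip(0.5 + 0.5 * (b - a) / k, 0.0, 1.0)
    return b + (a - b) * h - k * h * (1.0 - h)


# ----------------------------------------------------------------------
# vessel generation
# ----------------------------------------------------------------------
def generate_vessel(spec: SyntheticVesselSpec):
    """Generate the triangulated vessel surface and its ground truth.

    Returns ``(mesh, truth)``.  The mesh is watertight and consistently
    wound; identical spec + seed yields a byte-identical vertex array.
    """
    spec.validate()
    pitch = spec.mesh_edge_target
    sdf = _VesselSDF(spec, curve_spacing=pitch / 4.0)

    # sampling grid with a deterministic sub-voxel origin jitter: shifts the
    # lattice (hence vertex placement) without touching the analytic surface
    rng = np.random.default_rng(spec.seed)
    jitter = rng.uniform(0.07, 0.43, 3) * pitch

    lo = sdf.curve.min(axis=0) - spec.parent_radius
    hi = sdf.curve.max(axis=0) + spec.parent_radius
    if sdf.sac_center is not None:
        lo = np.minimum(lo, sdf.sac_center - spec.sac_radius)
        hi = np.maximum(hi, sdf.sac_center + spec.sac_radius)
    margin = 2.5 * pitch
    origin = lo - margin - jitter
    shape = np.ceil((hi + margin - origin) / pitch).astype(int) + 1

    xs = origin[0] + pitch * np.arange(shape[0])
    ys = origin[1] + pitch * np.arange(shape[1])
    zs = origin[2] + pitch * np.arange(shape[2])
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    grid_pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
    F = sdf(grid_pts).reshape(shape)

    verts, faces, _, _ = measure.marching_cubes(
        F, level=0.0, spacing=(pitch, pitch, pitch)
    )
    verts = verts + origin

    # Newton-project vertices onto the analytic zero level set
    h = 1e-3
    for _ in range(3):
        f0 = sdf(verts)
        grad = np.empty_like(verts)
        for ax in range(3):
            e = np.zeros(3)
            e[ax] = h
            grad[:, ax] = (sdf(verts + e) - sdf(verts - e)) / (2 * h)
        g2 = np.einsum("ij,ij->i", grad, grad)
        verts = verts - (f0 / np.maximum(g2, 1e-12))[:, None] * grad

    mesh = TriSurfaceMesh(verts, faces.astype(np.int64))
    if mesh.volume() < 0:
        mesh = TriSurfaceMesh(verts, faces[:, ::-1].astype(np.int64))
    # degenerate-face cleanup: collapse faces whose area vanished in projection
    areas = mesh.face_areas()
    tiny = areas < 1e-12
    if tiny.any():
        mesh = _collapse_degenerate(mesh, tiny)
    try:
        mesh.validate()
    except MeshTopologyError as exc:
        raise MeshTopologyError(f"generator produced a non-manifold surface: {exc}")

    truth = _ground_truth(spec, sdf, mesh)
    return mesh, truth


def _collapse_degenerate(mesh: TriSurfaceMesh, tiny: np.ndarray) -> TriSurfaceMesh:
    """Weld the vertices of near-zero-area faces and drop collapsed faces."""
    verts = mesh.vertices.copy()
    parent = np.arange(len(verts))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for f in mesh.faces[tiny]:
        v = verts[f]
        d01 = np.linalg.norm(v[0] - v[1])
        d12 = np.linalg.norm(v[1] - v[2])
        d20 = np.linalg.norm(v[2] - v[0])
        pairs = [(f[0], f[1], d01), (f[1], f[2], d12), (f[2], f[0], d20)]
        a, b, _ = min(pairs, key=lambda t: t[2])
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
    root = np.array([find(i) for i in range(len(verts))])
    uniq, new_idx = np.unique(root, return_inverse=True)
    new_verts = verts[uniq]
    new_faces = new_idx[mesh.faces]
    keep = (
        (new_faces[:, 0] != new_faces[:, 1])
        & (new_faces[:, 1] != new_faces[:, 2])
        & (new_faces[:, 2] != new_faces[:, 0])
    )
    return TriSurfaceMesh(new_verts, new_faces[keep])


def _ground_truth(spec, sdf: _VesselSDF, mesh: TriSurfaceMesh) -> VesselGroundTruth:
    pts = sdf.curve
    common = dict(
        centerline_points=pts,
        centerline_radius=spec.parent_radius,
        inlet_center=sdf.p_in.copy(),
        inlet_normal=-sdf.t_in.copy(),
        outlet_center=sdf.p_out.copy(),
        outlet_normal=sdf.t_out.copy(),
    )
    if not spec.has_sac:
        return VesselGroundTruth(
            has_sac=False, D=None, H=None, N=None, neck_center=None,
            neck_normal=None, neck_contour=None, sac_center=None,
            sac_radius=None, sac_face_mask=None, **common,
        )
    p0 = sdf.attach_point
    n = sdf.attach_normal
    d = sdf.d_center
    Rs = spec.sac_radius
    rn_eff = float(np.sqrt(Rs**2 - d**2))
    # orthonormal in-plane basis for the analytic neck circle
    e1 = np.cross(n, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(n, e1)
    th = np.linspace(0, 2 * np.pi, 128, endpoint=False)
    contour = p0 + rn_eff * (np.outer(np.cos(th), e1) + np.outer(np.sin(th), e2))
    height = (mesh.vertices - p0) @ n
    sac_face_mask = (height[mesh.faces] > 0).any(axis=1)
    return VesselGroundTruth(
        has_sac=True,
        D=2.0 * Rs,
        H=float(d + Rs),
        N=2.0 * rn_eff,
        neck_center=p0.copy(),
        neck_normal=n.copy(),
        neck_contour=contour,
        sac_center=sdf.sac_center.copy(),
        sac_radius=Rs,
        sac_face_mask=sac_face_mask,
        **common,
    )


# ----------------------------------------------------------------------
# constructed flow fields
# ----------------------------------------------------------------------
BOX_SIZE = 10.0          # mm, side of the boxed sac region
JET_PEAK_SPEED = 500.0   # mm/s
VORTEX_PEAK_SPEED = 300.0  # mm/s tangential peak of each Lamb-Oseen vortex
JET_EDGE_SHARPNESS = 0.02  # tanh edge width as a fraction of the box
JET_TILT_DEG = 20.0        # half-swing of the jet when direction changes

# (x, y) vortex slots as fractions of the box, kept clear of the fan swept
# by the tilted jet (pivot at the neck centre) for widths up to ~0.4
_VORTEX_SLOTS = np.array(
    [
        (0.08, 0.35),
        (0.92, 0.35),
        (0.13, 0.62),
        (0.87, 0.62),
        (0.06, 0.80),
        (0.94, 0.80),
    ]
)


@dataclass
class ConstructedField:
    """A constructed field plus its sac-region frame and ground truth."""

    field: FlowField
    region: SacRegion
    truth: dict


def generate_constructed_field(spec: ConstructedFieldSpec) -> ConstructedField:
    """Build a divergence-free vortex + inflow-jet field on a boxed sac.

    The jet enters through the neck plane y=0 as a tanh-edged band of width
    ``jet_width_fraction * BOX_SIZE``; vortices are Lamb-Oseen cores at fixed
    seeded slots, the first ``n_k`` of which are active at step k.  The field
    is invariant along z, so any z-slice shows the full vortex census.
    """
    spec.validate()
    counts = tuple(spec.n_vortices_per_step)
    n_steps = len(counts)
    L = BOX_SIZE
    res = spec.grid_resolution
    res_z = max(4, res // 5)
    pitch = L / res
    nodes, tets = box_tet_lattice(
        np.array([0.0, 0.0, 0.0]), pitch, (res, res, res_z)
    )

    rng = np.random.default_rng(spec.seed)
    slots = _VORTEX_SLOTS * L
    slots = slots + rng.uniform(-0.02, 0.02, slots.shape) * L
    rc = 0.08 * L
    gamma = VORTEX_PEAK_SPEED * 2 * np.pi * rc / 0.6382

    w = spec.jet_width_fraction * L
    tau = JET_EDGE_SHARPNESS * L
    pivot = np.array([L / 2.0, 0.0])

    T = 0.76  # s, nominal cardiac period for the fixture
    times = np.arange(n_steps) * T / n_steps
    amp = 1.0 + 0.1 * np.cos(2 * np.pi * (np.arange(n_steps) / n_steps - 0.2))
    angles = np.zeros(n_steps)
    if spec.jet_direction_changes:
        half = n_steps // 2
        angles[:half] = -np.deg2rad(JET_TILT_DEG)
        angles[half:] = +np.deg2rad(JET_TILT_DEG)

    xy = nodes[:, :2]
    velocities = np.zeros((n_steps, len(nodes), 3))
    for k in range(n_steps):
        phi = angles[k]
        d_hat = np.array([np.sin(phi), np.cos(phi)])
        e_hat = np.array([np.cos(phi), -np.sin(phi)])
        xi = (xy - pivot) @ e_hat
        prof = 0.5 * (np.tanh((xi + w / 2) / tau) - np.tanh((xi - w / 2) / tau))
        u2 = JET_PEAK_SPEED * amp[k] * prof[:, None] * d_hat
        for c in slots[: counts[k]]:
            rel = xy - c
            r2 = np.einsum("ij,ij->i", rel, rel)
            swirl = gamma / (2 * np.pi * np.maximum(r2, 1e-12)) * (
                1.0 - np.exp(-r2 / rc**2)
            )
            u2 += swirl[:, None] * np.stack([-rel[:, 1], rel[:, 0]], axis=1)
        velocities[k, :, 0] = u2[:, 0]
        velocities[k, :, 1] = u2[:, 1]

    field = FlowField(
        nodes=nodes,
        tets=tets,
        velocities=velocities,
        pressures=np.zeros((n_steps, len(nodes))),
        times=times,
        peak_systole_index=int(np.argmax(amp)),
    )
    region = SacRegion(
        neck_point=np.array([L / 2.0, 0.0, res_z * pitch / 2.0]),
        neck_normal=np.array([0.0, 1.0, 0.0]),
        transverse_dir=np.array([1.0, 0.0, 0.0]),
        slice_normal=np.array([0.0, 0.0, 1.0]),
        height=L,
        half_width=L / 2.0,
    )
    # peak tanh-profile value (slightly below 1) for exact width bookkeeping
    truth = dict(
        vortex_counts=list(counts),
        jet_direction_changed=bool(spec.jet_direction_changes),
        jet_width_fraction=spec.jet_width_fraction,
        jet_angles_deg=np.rad2deg(angles).tolist(),
        vortex_centers=slots.tolist(),
    )
    return ConstructedField(field=field, region=region, truth=truth)
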
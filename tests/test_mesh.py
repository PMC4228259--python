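"""Surface-mesh container invariants."""

import numpy as np
import pytest
import trimesh

from aneuflow.mesh import MeshTopologyError, TriSurfaceMesh


@pytest.fixture()
def icosphere():
    s = trimesh.creation.icosphere(subdivisions=2, radius=3.0)
    return TriSurfaceMesh(np.asarray(s.vertices), np.asarray(s.faces))


def test_watertight_sphere_passes_validation(icosphere):
    icosphere.validate()
    assert icosphere.is_watertight()
    # faceted sphere volume sits a few % below the analytic ball
    assert icosphere.volume() == pytest.approx(4 / 3 * np.pi * 27, rel=0.05)


def test_open_mesh_is_rejected_and_reports_boundary(icosphere):
    # open a clean hole: remove the star of one vertex
    keep = ~(icosphere.faces == 10).any(axis=1)
    open_mesh = TriSurfaceMesh(icosphere.vertices, icosphere.faces[keep])
    with pytest.raises(MeshTopologyError):
        open_mesh.validate()
    loops = open_mesh.boundary_loops()
    assert len(loops) == 1
    assert len(loops[0]) >= 3


def test_folded_winding_is_rejected(icosphere):
    faces = icosphere.faces.copy()
    faces[0] = faces[0][::-1]  # flip one face
    with pytest.raises(MeshTopologyError):
        TriSurfaceMesh(icosphere.vertices, faces).validate()


def test_rigid_transform_preserves_volume_and_areas(icosphere):
    angle = 0.7
    rot = np.eye(4)
    rot[:3, :3] = np.array([
        [np.cos(angle), -np.sin(angle), 0],
        [np.sin(angle), np.cos(angle), 0],
        [0, 0, 1],
    ])
    rot[:3, 3] = [5.0, -2.0, 1.0]
    moved = icosphere.transformed(rot)
    assert moved.volume() == pytest.approx(icosphere.volume(), rel=1e-12)
    assert moved.face_areas().sum() == pytest.approx(
        icosphere.face_areas().sum(), rel=1e-12)
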
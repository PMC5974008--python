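import numpy as np
import pytest
import trimesh

from contourreg.bench import make_liver_mesh
from contourreg.geometry import SurfaceMesh, compute_normals


def build_flat_grid(nx: int = 21, spacing: float = 1.0) -> SurfaceMesh:
    """Regular right-triangulated grid in the z=0 plane."""
    xs, ys = np.meshgrid(np.arange(nx) * spacing, np.arange(nx) * spacing,
                         indexing="ij")
    verts = np.column_stack([xs.ravel(), ys.ravel(), np.zeros(nx * nx)])
    faces = []
    for i in range(nx - 1):
        for j in range(nx - 1):
            a = i * nx + j
            faces.append([a, a + 1, a + nx + 1])
            faces.append([a, a + nx + 1, a + nx])
    return SurfaceMesh(verts, np.asarray(faces))


@pytest.fixture(scope="session")
def flat_grid() -> SurfaceMesh:
    return build_flat_grid()


@pytest.fixture(scope="session")
def unit_sphere() -> SurfaceMesh:
    sp = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
    return SurfaceMesh(np.asarray(sp.vertices),
                       np.asarray(sp.faces, dtype=np.int64))


@pytest.fixture(scope="session")
def liver_small():
    """Coarse liver-like phantom (642 vertices) for fast pipeline tests."""
    mesh, ridge = make_liver_mesh(subdivisions=3)
    return mesh, ridge


@pytest.fixture(scope="session")
def liver():
    """Benchmark-resolution liver-like phantom (2562 vertices)."""
    mesh, ridge = make_liver_mesh(subdivisions=4)
    return mesh, ridge


@pytest.fixture(scope="session")
def sphere_mm() -> SurfaceMesh:
    sp = trimesh.creation.icosphere(subdivisions=3, radius=50.0)
    return compute_normals(SurfaceMesh(np.asarray(sp.vertices),
                                       np.asarray(sp.faces, dtype=np.int64)))
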
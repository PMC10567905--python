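"""Shared fixtures: generated meshes only, no stored binary data."""

import numpy as np
import pytest
import trimesh

from crownfit.meshkit import TriangleMesh
from crownfit.synthetic import Abutment, AbutmentSpec, make_abutment

#: coarse default for tests: keeps suites fast while staying well below the
#: chamfer-representation limit
TEST_RESOLUTION = 0.2


@pytest.fixture(scope="session")
def abutment() -> Abutment:
    return make_abutment(AbutmentSpec(mesh_resolution=TEST_RESOLUTION))


@pytest.fixture(scope="session")
def ellipsoid() -> TriangleMesh:
    """Asymmetric closed surface: every rigid displacement is identifiable."""
    ico = trimesh.creation.icosphere(subdivisions=3)
    return TriangleMesh(ico.vertices * np.array([4.0, 3.0, 2.2]), ico.faces)


def open_cylinder(radius: float, height: float, n_theta: int = 128,
                  n_z: int = 26) -> TriangleMesh:
    """Open lateral cylinder surface with the base rim as a vertex ring."""
    theta = np.arange(n_theta) * (2 * np.pi / n_theta)
    zs = np.linspace(0.0, height, n_z)
    verts = np.array([
        [radius * np.cos(t), radius * np.sin(t), z] for z in zs for t in theta
    ])
    faces = []
    nxt = (np.arange(n_theta) + 1) % n_theta
    for i in range(n_z - 1):
        a, b = i * n_theta, (i + 1) * n_theta
        for k in range(n_theta):
            faces.append([a + k, a + nxt[k], b + nxt[k]])
            faces.append([a + k, b + nxt[k], b + k])
    return TriangleMesh(verts, np.asarray(faces))


def planar_grid(width: float, z: float, n: int = 12,
                center=(0.0, 0.0)) -> TriangleMesh:
    """Square planar mesh in the z-plane, wound so normals point up (+z)."""
    xs = np.linspace(-width / 2 + center[0], width / 2 + center[0], n)
    ys = np.linspace(-width / 2 + center[1], width / 2 + center[1], n)
    verts = np.array([[x, y, z] for y in ys for x in xs])
    faces = []
    for j in range(n - 1):
        for i in range(n - 1):
            a = j * n + i
            faces.append([a, a + 1, a + n + 1])
            faces.append([a, a + n + 1, a + n])
    return TriangleMesh(verts, np.asarray(faces))


def random_hull_mesh(rng: np.random.Generator, n_points: int = 30) -> TriangleMesh:
    """Random convex closed mesh (~50 faces) for oracle comparisons."""
    pts = rng.normal(size=(n_points, 3)) * rng.uniform(0.5, 2.0, size=3)
    hull = trimesh.Trimesh(vertices=pts).convex_hull
    return TriangleMesh(hull.vertices, hull.faces)
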
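"""Shared fixtures: small constructed meshes and cached synthetic arches.

The synthetic arch pipeline runs take seconds, so anything reused across
tests is session-scoped.
"""

from __future__ import annotations

import numpy as np
import pytest

from dentmark.mesh_core import TriangleMesh, build_adjacency, make_mesh
from dentmark.pipeline import default_training_set, run_recognition
from dentmark.synthetic_arch import ArchSpec, generate_arch


def make_cube(size: float = 1.0) -> TriangleMesh:
    """Unit cube as 12 triangles with outward winding."""
    import trimesh

    box = trimesh.creation.box(extents=(size, size, size))
    return make_mesh(np.asarray(box.vertices), np.asarray(box.faces))


def make_sphere(subdivisions: int = 2, radius: float = 1.0) -> TriangleMesh:
    import trimesh

    s = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return make_mesh(np.asarray(s.vertices), np.asarray(s.faces))


def make_grid_surface(heights: np.ndarray, spacing: float = 1.0) -> TriangleMesh:
    """Triangulated height-field z = heights[i, j] over a regular grid."""
    n, m = heights.shape
    xs, ys = np.meshgrid(np.arange(n) * spacing, np.arange(m) * spacing, indexing="ij")
    verts = np.column_stack([xs.ravel(), ys.ravel(), heights.ravel()])
    faces = []
    for i in range(n - 1):
        for j in range(m - 1):
            a = i * m + j
            b = a + 1
            c = a + m
            d = c + 1
            faces.append([a, b, c])
            faces.append([b, d, c])
    return make_mesh(verts, np.array(faces))


def make_vgroove(angle_deg: float = 90.0, n: int = 8) -> TriangleMesh:
    """Two planar strips meeting in a concave V crease along the y axis."""
    half = np.radians(angle_deg) / 2.0
    slope = 1.0 / np.tan(half)
    ys = np.arange(n, dtype=float)
    verts = []
    for x in (-2.0, -1.0, 0.0, 1.0, 2.0):
        for y in ys:
            verts.append([x, y, abs(x) * slope])
    verts = np.array(verts)
    faces = []
    for c in range(4):
        for j in range(n - 1):
            a = c * n + j
            b = a + 1
            cc = a + n
            d = cc + 1
            faces.append([a, cc, b])
            faces.append([b, cc, d])
    return make_mesh(verts, np.array(faces))


@pytest.fixture(scope="session")
def training():
    return default_training_set()


@pytest.fixture(scope="session")
def arch1():
    """Default mandibular permanent arch, seed 1, with ground truth."""
    return generate_arch(ArchSpec(jaw="L", seed=1))


@pytest.fixture(scope="session")
def arch1_adjacency(arch1):
    mesh, _ = arch1
    return build_adjacency(mesh)


@pytest.fixture(scope="session")
def rec1(arch1, training):
    """Full recognition result for arch1."""
    mesh, _ = arch1
    return run_recognition(mesh, "L", "permanent", training=training)


@pytest.fixture(scope="session")
def cube():
    return make_cube()


@pytest.fixture(scope="session")
def sphere():
    return make_sphere()
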
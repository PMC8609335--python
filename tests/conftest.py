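import numpy as np
import pytest

from hyperdecode import pipeline, surface


def path_mesh(n: int = 5, spacing: float = 1.0) -> surface.SurfaceMesh:
    """Degenerate 1-D chain mesh: n vertices on a line, unit edges.

    Triangles are zero-area (i, i+1, i+1); only edge connectivity matters
    for geodesic tests.
    """
    coords = np.column_stack(
        [np.arange(n) * spacing, np.zeros(n), np.zeros(n)]
    )
    tris = np.array([[i, i + 1, i + 1] for i in range(n - 1)])
    return surface.SurfaceMesh(coords, tris)


@pytest.fixture
def chain5():
    return path_mesh(5)


@pytest.fixture(scope="session")
def ico42():
    """Single 42-vertex icosphere, ~3 mm spacing."""
    return surface.icosphere_mesh(subdivisions=1)


@pytest.fixture(scope="session")
def hemis42():
    """Two 42-vertex hemispheres with medial-wall masks."""
    return surface.two_hemisphere_mesh(subdivisions=1)


@pytest.fixture(scope="session")
def tiny_fixture():
    """Full tiny pipeline run: 4 subjects, 2 runs per condition."""
    return pipeline.make_fixture("tiny", seed=0)


def brute_force_distances(mesh: surface.SurfaceMesh) -> np.ndarray:
    """Independent all-pairs geodesic oracle via Bellman-Ford-style
    relaxation on the explicit edge list (no csgraph)."""
    n = mesh.n_vertices
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    edges = []
    for tri in mesh.triangles:
        for a, b in [(0, 1), (1, 2), (2, 0)]:
            i, j = int(tri[a]), int(tri[b])
            if i == j:
                continue
            if mesh.medial_wall[i] or mesh.medial_wall[j]:
                continue
            w = float(np.linalg.norm(mesh.coords[i] - mesh.coords[j]))
            edges.append((i, j, w))
    masked = np.flatnonzero(mesh.medial_wall)
    dist[masked, :] = np.inf
    dist[:, masked] = np.inf
    dist[masked, masked] = 0.0
    for _ in range(n):
        changed = False
        for i, j, w in edges:
            nd = dist[:, i] + w
            better = nd < dist[:, j]
            if np.any(better):
                dist[better, j] = nd[better]
                changed = True
            nd = dist[:, j] + w
            better = nd < dist[:, i]
            if np.any(better):
                dist[better, i] = nd[better]
                changed = True
        if not changed:
            break
    return dist
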
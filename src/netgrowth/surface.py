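"""Synthetic spherical cortical surfaces.

A single hemisphere is modelled as a triangulated unit sphere.  Vertices are
placed with a Fibonacci lattice (near-uniform area per vertex) and the
triangulation is the convex hull of the vertex cloud, which for points on a
sphere coincides with the spherical Delaunay triangulation.  This gives a
connected mesh with symmetric vertex adjacency, the only properties the
parcellation generators and the spin test rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull


@dataclass
class SurfaceMesh:
    """Triangulated mesh on the unit sphere.

    Attributes
    ----------
    coordinates : (n_vertices, 3) float array
        Unit-norm vertex positions.
    faces : (n_faces, 3) int array
        Vertex indices of each triangle.
    neighbors : list of int arrays
        Sorted neighbor indices of each vertex (symmetric adjacency).
    """

    coordinates: np.ndarray
    faces: np.ndarray
    neighbors: list = field(repr=False)

    @property
    def n_vertices(self) -> int:
        return self.coordinates.shape[0]

    def validate(self) -> None:
        """Check the mesh invariants: unit norms, symmetry, connectivity."""
        norms = np.linalg.norm(self.coordinates, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("vertex coordinates must lie on the unit sphere")
        for i, nb in enumerate(self.neighbors):
            for j in nb:
                if i not in self.neighbors[j]:
                    raise ValueError("adjacency is not symmetric")
        # connectivity by BFS from vertex 0
        seen = np.zeros(self.n_vertices, dtype=bool)
        stack = [0]
        seen[0] = True
        while stack:
            v = stack.pop()
            for w in self.neighbors[v]:
                if not seen[w]:
                    seen[w] = True
                    stack.append(w)
        if not seen.all():
            raise ValueError("mesh graph is not connected")


def fibonacci_sphere(n_vertices: int) -> np.ndarray:
    """Near-uniform points on the unit sphere via the golden-angle spiral."""
    if n_vertices < 4:
        raise ValueError("need at least 4 vertices for a spherical mesh")
    i = np.arange(n_vertices, dtype=float)
    # offset 0.5 avoids the poles and keeps the hull non-degenerate
    z = 1.0 - 2.0 * (i + 0.5) / n_vertices
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    golden = np.pi * (3.0 - np.sqrt(5.0))
    theta = golden * i
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def make_sphere_mesh(n_vertices: int) -> SurfaceMesh:
    """Build a triangulated unit-sphere mesh with ``n_vertices`` vertices."""
    coords = fibonacci_sphere(n_vertices)
    hull = ConvexHull(coords)
    faces = hull.simplices
    nb_sets: list[set] = [set() for _ in range(n_vertices)]
    for a, b, c in faces:
        nb_sets[a].update((b, c))
        nb_sets[b].update((a, c))
        nb_sets[c].update((a, b))
    neighbors = [np.array(sorted(s), dtype=np.intp) for s in nb_sets]
    return SurfaceMesh(coordinates=coords, faces=faces, neighbors=neighbors)
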
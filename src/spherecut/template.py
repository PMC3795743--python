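"""Spherical template: ray directions from a subdivided icosahedron.

The segmentation graph is built on rays cast from a seed point through the
surface points of a spherical polyhedron.  We use an icosphere: a regular
icosahedron whose triangles are recursively subdivided, every new vertex
being projected back onto the unit sphere.  This gives near-uniform angular
ray density; the triangulation's edges define which rays are "neighbors"
for the smoothness constraint (two rays are adjacent iff their surface
points share a triangle edge).

The construction is fully deterministic: the canonical golden-ratio
icosahedron plus a midpoint cache keyed on sorted vertex-index pairs means
equal subdivision levels always produce bitwise-identical direction lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

__all__ = ["SphericalTemplate", "build_template", "neighbors_of"]

#: Practical upper bound on the subdivision level (level 6 = 40962 rays).
MAX_SUBDIVISION_LEVEL = 6


@dataclass(frozen=True)
class SphericalTemplate:
    """Unit ray directions plus the triangle adjacency among them.

    Attributes
    ----------
    directions : (R, 3) float array
        Unit vectors, one per ray.  R = 10 * 4**n + 2 at subdivision
        level n.
    triangles : (F, 3) int array
        Vertex-index triples of the closed triangulation.
    neighbor_pairs : frozenset of (int, int)
        Unordered ray-index pairs sharing a triangle edge; exactly the
        edge set of the triangulation.
    subdivision_level : int
    """

    directions: np.ndarray
    triangles: np.ndarray
    neighbor_pairs: frozenset
    subdivision_level: int
    _adjacency: tuple = field(repr=False, default=())

    @property
    def n_rays(self) -> int:
        return self.directions.shape[0]

    def __post_init__(self):
        if not self._adjacency:
            adj: list[set[int]] = [set() for _ in range(self.n_rays)]
            for a, b in self.neighbor_pairs:
                adj[a].add(b)
                adj[b].add(a)
            object.__setattr__(
                self, "_adjacency", tuple(frozenset(s) for s in adj)
            )


def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    """Canonical regular icosahedron from the golden-ratio construction."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=np.float64,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    return verts, faces


def build_template(subdivision_level: int) -> SphericalTemplate:
    """Build the icosphere template at the given subdivision level.

    Parameters
    ----------
    subdivision_level : int
        Number of 1-to-4 triangle subdivisions of the regular
        icosahedron; the result has ``10 * 4**n + 2`` rays.

    Raises
    ------
    ParameterError
        If the level is negative or exceeds the practical cap.
    """
    n = int(subdivision_level)
    if n < 0 or n != subdivision_level:
        raise ParameterError(
            f"subdivision_level must be a nonnegative integer, got {subdivision_level!r}"
        )
    if n > MAX_SUBDIVISION_LEVEL:
        raise ParameterError(
            f"subdivision_level {n} exceeds the cap of {MAX_SUBDIVISION_LEVEL}"
        )

    verts, faces = _icosahedron()
    verts_list = [tuple(v) for v in verts]

    for _ in range(n):
        midpoint_cache: dict[tuple[int, int], int] = {}

        def midpoint(i: int, j: int) -> int:
            key = (i, j) if i < j else (j, i)
            idx = midpoint_cache.get(key)
            if idx is None:
                m = np.asarray(verts_list[i]) + np.asarray(verts_list[j])
                m /= np.linalg.norm(m)
                idx = len(verts_list)
                verts_list.append(tuple(m))
                midpoint_cache[key] = idx
            return idx

        new_faces = []
        for a, b, c in faces:
            ab = midpoint(a, b)
            bc = midpoint(b, c)
            ca = midpoint(c, a)
            new_faces.extend(
                [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
            )
        faces = np.asarray(new_faces, dtype=np.int64)

    directions = np.asarray(verts_list, dtype=np.float64)
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)

    pairs = set()
    for a, b, c in faces:
        for i, j in ((a, b), (b, c), (c, a)):
            pairs.add((int(i), int(j)) if i < j else (int(j), int(i)))

    return SphericalTemplate(
        directions=directions,
        triangles=faces,
        neighbor_pairs=frozenset(pairs),
        subdivision_level=n,
    )


def neighbors_of(template: SphericalTemplate, r: int) -> frozenset:
    """Rays sharing a triangle edge with ray ``r``.

    The relation is symmetric; icosahedron-original vertices have 5
    neighbors, subdivision-created vertices 6.
    """
    if not 0 <= r < template.n_rays:
        raise IndexError(f"ray index {r} out of range [0, {template.n_rays})")
    return template._adjacency[r]
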
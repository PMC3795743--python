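"""Turn a cut surface into a world-space mesh and a voxel mask.

The cut assigns each ray a boundary node; placing a vertex at every
boundary node and reusing the template's triangulation yields a closed
triangulated surface in world millimetres.  Voxelization exploits the
fact that the surface is star-shaped about the seed by construction: a
voxel is inside iff its center's distance from the seed does not exceed
the surface radius in the center's direction, obtained by barycentric
interpolation of the three incident rays' cut radii over the template
triangle containing that direction.  For the surfaces this graph can
produce, the radial test is exact and fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConsistencyError
from .graph import CutSurface
from .rays import RayGrid
from .volume import BinaryMask, ImageVolume

__all__ = ["SurfaceMesh", "surface_to_mesh", "voxelize"]

_BARY_TOL = 1e-9


@dataclass(frozen=True)
class SurfaceMesh:
    """Closed triangle mesh: one vertex per ray, template triangulation."""

    vertices: np.ndarray  # (R, 3) world mm
    triangles: np.ndarray  # (F, 3) indices


def _cut_radii(surface: CutSurface, grid: RayGrid) -> np.ndarray:
    return (surface.k + 1.0) * grid.step


def surface_to_mesh(surface: CutSurface, grid: RayGrid) -> SurfaceMesh:
    """Place each ray's vertex at its cut node; copy the triangulation."""
    if surface.k.shape[0] != grid.n_rays:
        raise ConsistencyError(
            f"surface has {surface.k.shape[0]} rays, grid has {grid.n_rays}"
        )
    radii = _cut_radii(surface, grid)
    vertices = grid.seed.position + grid.template.directions * radii[:, None]
    return SurfaceMesh(vertices=vertices, triangles=grid.template.triangles.copy())


def voxelize(
    surface: CutSurface, grid: RayGrid, volume: ImageVolume
) -> BinaryMask:
    """Rasterize the cut surface onto the volume's voxel grid.

    A voxel center at distance rho from the seed, in unit direction u, is
    inside iff ``rho <= s(u)`` where s interpolates the cut radii
    barycentrically over the template triangle containing u (rho = 0,
    the seed voxel itself, is always inside).  Triangle lookup walks the
    triangles incident to the template vertex nearest to u and falls back
    to a global scan for the rare borderline direction; ties on edges
    resolve toward the lowest triangle index.
    """
    if surface.k.shape[0] != grid.n_rays:
        raise ConsistencyError(
            f"surface has {surface.k.shape[0]} rays, grid has {grid.n_rays}"
        )
    tpl = grid.template
    radii = _cut_radii(surface, grid)
    max_radius = float(radii.max())
    seed = grid.seed.position

    # Restrict to the index-space bounding box of the reach sphere.
    corners = seed[None, :] + max_radius * np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
    )
    idx_corners = volume.world_to_index(corners)
    lo = np.maximum(np.floor(idx_corners.min(axis=0)).astype(int), 0)
    hi = np.minimum(
        np.ceil(idx_corners.max(axis=0)).astype(int),
        np.asarray(volume.shape) - 1,
    )

    mask = np.zeros(volume.shape, dtype=bool)
    if np.any(lo > hi):
        return BinaryMask(
            mask, volume.spacing.copy(), volume.origin.copy(), volume.direction.copy()
        )

    ii, jj, kk = np.meshgrid(
        np.arange(lo[0], hi[0] + 1),
        np.arange(lo[1], hi[1] + 1),
        np.arange(lo[2], hi[2] + 1),
        indexing="ij",
    )
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    centers = volume.index_to_world(idx)
    rel = centers - seed
    rho = np.linalg.norm(rel, axis=1)

    inside = np.zeros(len(idx), dtype=bool)
    at_seed = rho == 0.0
    inside[at_seed] = True

    candidates = ~at_seed & (rho <= max_radius + _BARY_TOL)
    if np.any(candidates):
        u = rel[candidates] / rho[candidates, None]
        s_u = _interp_radius(tpl, radii, u)
        inside_c = rho[candidates] <= s_u + _BARY_TOL
        inside[candidates] = inside_c

    mask[idx[inside, 0], idx[inside, 1], idx[inside, 2]] = True
    return BinaryMask(
        mask, volume.spacing.copy(), volume.origin.copy(), volume.direction.copy()
    )


def _interp_radius(tpl, radii: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Surface radius in each unit direction u, via barycentric interpolation."""
    n = len(u)
    out = np.empty(n)
    assigned = np.zeros(n, dtype=bool)

    tri_verts = tpl.directions[tpl.triangles]  # (F, 3, 3)
    # u = M @ bary with M's columns the triangle's vertex directions.
    inv = np.linalg.inv(tri_verts.transpose(0, 2, 1))  # (F, 3, 3)

    incident: list[list[int]] = [[] for _ in range(tpl.n_rays)]
    for f, tri in enumerate(tpl.triangles):
        for v in tri:
            incident[int(v)].append(f)

    nearest = np.argmax(u @ tpl.directions.T, axis=1)
    order = np.argsort(nearest, kind="stable")
    grouped = np.split(order, np.searchsorted(nearest[order], np.arange(1, tpl.n_rays)))

    for v, pts in enumerate(grouped):
        if len(pts) == 0:
            continue
        uv = u[pts]
        # lowest incident triangle index wins on edge ties
        for f in sorted(incident[v]):
            todo = ~assigned[pts]
            if not np.any(todo):
                break
            bary = uv[todo] @ inv[f].T
            ok = np.all(bary >= -_BARY_TOL, axis=1)
            if not np.any(ok):
                continue
            w = bary[ok]
            w = w / w.sum(axis=1, keepdims=True)
            sel = pts[todo][ok]
            out[sel] = w @ radii[tpl.triangles[f]]
            assigned[sel] = True

    # Rare numerical stragglers: pick the triangle with the best worst
    # barycentric coordinate (global scan, lowest index on exact ties).
    missing = np.flatnonzero(~assigned)
    for i in missing:
        bary_all = inv @ u[i]  # (F, 3)
        f = int(np.argmax(bary_all.min(axis=1)))
        w = np.maximum(bary_all[f], 0.0)
        w = w / w.sum()
        out[i] = w @ radii[tpl.triangles[f]]
    return out
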
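"""Ray sampling and node costs.

The template is placed with its center at the seed point and every ray is
sampled at Z equidistant radial positions, the innermost node one step
away from the seed (the seed itself is not a node, which avoids a
degenerate node shared by all rays at radius zero).  Each node's cost is
the absolute difference between the trilinearly interpolated image
intensity at the node and the mean gray value of the object, estimated
from a small cube of voxels around the seed.  Low cost therefore means
"looks like the object interior"; the optimal surface will run just
inside the steep cost rise at the object boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .template import SphericalTemplate
from .volume import ImageVolume, SeedPoint

__all__ = ["RayGrid", "CostField", "estimate_mean", "sample_rays", "compute_costs"]


@dataclass(frozen=True)
class RayGrid:
    """The R x Z lattice of graph nodes sampled along rays.

    ``intensities[r, z]`` is the image value at world position
    ``seed + (z + 1) * step * direction(r)``; ``oob[r, z]`` flags samples
    outside the volume, whose intensity is undefined (stored as NaN).
    """

    seed: SeedPoint
    template: SphericalTemplate
    n_samples: int
    step: float
    intensities: np.ndarray
    oob: np.ndarray

    @property
    def n_rays(self) -> int:
        return self.template.n_rays

    def node_position(self, r: int, z: int) -> np.ndarray:
        return self.seed.position + (z + 1) * self.step * self.template.directions[r]

    def node_positions(self) -> np.ndarray:
        """(R, Z, 3) world positions of all nodes."""
        radii = (np.arange(self.n_samples) + 1.0) * self.step
        return (
            self.seed.position
            + self.template.directions[:, None, :] * radii[None, :, None]
        )


@dataclass(frozen=True)
class CostField:
    """Per-node costs ``c[r, z] >= 0`` and the seed-region mean estimate."""

    c: np.ndarray
    mean_estimate: float

    @property
    def n_rays(self) -> int:
        return self.c.shape[0]

    @property
    def n_samples(self) -> int:
        return self.c.shape[1]


def estimate_mean(
    volume: ImageVolume, seed: SeedPoint, radius_voxels: int = 3
) -> float:
    """Mean intensity of a voxel cube around the seed.

    The cube has half-width ``radius_voxels`` in index space, centered on
    the seed's nearest voxel, clipped to the grid.  This estimates the
    object's average gray value from the seed's immediate surroundings.
    """
    if radius_voxels < 0:
        raise ParameterError("radius_voxels must be nonnegative")
    seed.require_inside(volume)
    center = np.rint(volume.world_to_index(seed.position)).astype(int)
    lo = np.maximum(center - radius_voxels, 0)
    hi = np.minimum(center + radius_voxels, np.asarray(volume.shape) - 1)
    block = volume.voxels[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1]
    return float(block.mean())


def sample_rays(
    volume: ImageVolume,
    seed: SeedPoint,
    template: SphericalTemplate,
    n_samples: int,
    step: float,
) -> RayGrid:
    """Trilinearly sample the volume along every template ray.

    Parameters
    ----------
    n_samples : int
        Z, the number of nodes per ray (>= 2).
    step : float
        Radial distance between consecutive nodes, mm (> 0).
    """
    if n_samples < 2:
        raise ParameterError(f"n_samples must be >= 2, got {n_samples}")
    if step <= 0:
        raise ParameterError(f"step must be positive, got {step}")
    seed.require_inside(volume)

    radii = (np.arange(n_samples) + 1.0) * step
    positions = (
        seed.position + template.directions[:, None, :] * radii[None, :, None]
    )  # (R, Z, 3)
    idx = volume.world_to_index(positions.reshape(-1, 3))  # (R*Z, 3) continuous

    dims = np.asarray(volume.shape, dtype=np.float64)
    oob = np.any((idx < 0) | (idx > dims - 1), axis=1)

    values = ndimage.map_coordinates(
        volume.voxels, idx.T, order=1, mode="nearest"
    )
    values = values.astype(np.float64)
    values[oob] = np.nan

    R, Z = template.n_rays, n_samples
    return RayGrid(
        seed=seed,
        template=template,
        n_samples=Z,
        step=float(step),
        intensities=values.reshape(R, Z),
        oob=oob.reshape(R, Z),
    )


def compute_costs(grid: RayGrid, mean_estimate: float) -> CostField:
    """Node costs: |intensity - mean| in bounds, a high constant out of bounds.

    Out-of-bounds nodes get ``OOB_COST = 1 + max(intensity range,
    max in-bounds cost)`` over the in-bounds samples — a finite constant
    strictly exceeding every attainable in-bounds cost, which keeps the
    optimal surface inside the volume without infinities in the
    arithmetic.
    """
    c = np.abs(grid.intensities - float(mean_estimate))
    inb = ~grid.oob
    if np.any(inb):
        vals = grid.intensities[inb]
        oob_cost = 1.0 + max(
            float(vals.max() - vals.min()), float(c[inb].max())
        )
    else:
        oob_cost = 1.0
    c[grid.oob] = oob_cost
    return CostField(c=c, mean_estimate=float(mean_estimate))
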
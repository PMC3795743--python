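"""End-to-end segmentation pipeline.

Orchestrates: mean estimation around the seed -> ray sampling ->
node costs -> telescoped weights -> graph construction -> min-cut ->
mesh + mask reconstruction.  Deterministic: identical volume, seed and
configuration give bitwise-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import graph as _graph
from . import rays as _rays
from .errors import ParameterError
from .reconstruct import SurfaceMesh, surface_to_mesh, voxelize
from .template import build_template
from .volume import BinaryMask, ImageVolume, SeedPoint

__all__ = ["SegmentationConfig", "SegmentationResult", "segment"]


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunable parameters of one segmentation run.

    Attributes
    ----------
    subdivision_level : int
        Icosphere subdivision; level 3 casts 642 rays.
    n_samples : int
        Z, nodes per ray.  With the default step this sets the radial
        reach to ``n_samples * step`` mm; the object boundary must fall
        within it.
    step_mm : float or None
        Radial node spacing; None means the volume's smallest voxel
        spacing.
    delta_r : int
        Smoothness: neighboring rays' boundary indices may differ by at
        most this many layers.  0 forces a sphere.
    mean_radius_voxels : int
        Half-width of the seed-centered cube used to estimate the
        object's mean gray value.
    """

    subdivision_level: int = 3
    n_samples: int = 60
    step_mm: Optional[float] = None
    delta_r: int = 2
    mean_radius_voxels: int = 3

    def __post_init__(self):
        if self.n_samples < 2:
            raise ParameterError("n_samples must be >= 2")
        if self.step_mm is not None and self.step_mm <= 0:
            raise ParameterError("step_mm must be positive")
        if self.delta_r < 0:
            raise ParameterError("delta_r must be nonnegative")
        if self.mean_radius_voxels < 0:
            raise ParameterError("mean_radius_voxels must be nonnegative")

    def resolved_step(self, volume: ImageVolume) -> float:
        return (
            float(self.step_mm)
            if self.step_mm is not None
            else float(volume.spacing.min())
        )

    def to_dict(self) -> dict:
        return {
            "subdivision_level": self.subdivision_level,
            "n_samples": self.n_samples,
            "step_mm": self.step_mm,
            "delta_r": self.delta_r,
            "mean_radius_voxels": self.mean_radius_voxels,
        }


@dataclass(frozen=True)
class SegmentationResult:
    """Mask, mesh and run report of one segmentation."""

    mask: BinaryMask
    mesh: SurfaceMesh
    report: dict
    surface: _graph.CutSurface = field(repr=False, default=None)
    ray_grid: _rays.RayGrid = field(repr=False, default=None)
    costs: _rays.CostField = field(repr=False, default=None)


def segment(
    volume: ImageVolume, seed: SeedPoint, config: SegmentationConfig = None
) -> SegmentationResult:
    """Segment the object containing the seed point.

    Returns the voxelized mask on the input grid, the triangulated cut
    surface in world mm, and a report with the configuration, the mean
    gray-value estimate, the optimal surface cost and a per-ray boundary
    summary.
    """
    if config is None:
        config = SegmentationConfig()
    seed.require_inside(volume)

    step = config.resolved_step(volume)
    template = build_template(config.subdivision_level)
    mean = _rays.estimate_mean(volume, seed, config.mean_radius_voxels)
    grid = _rays.sample_rays(volume, seed, template, config.n_samples, step)
    costs = _rays.compute_costs(grid, mean)
    weights = _graph.node_weights(costs)
    seg_graph = _graph.build_graph(weights, template, config.delta_r)
    surface = _graph.min_cut_surface(seg_graph, costs)

    mesh = surface_to_mesh(surface, grid)
    mask = voxelize(surface, grid, volume)

    radii = (surface.k + 1.0) * step
    report = {
        "config": {**config.to_dict(), "step_mm_resolved": step},
        "seed_world_mm": seed.position.tolist(),
        "mean_estimate": mean,
        "total_cost": surface.total_cost,
        "n_rays": template.n_rays,
        "cut_layers": {
            "min": int(surface.k.min()),
            "max": int(surface.k.max()),
            "mean": float(surface.k.mean()),
        },
        "cut_radius_mm": {
            "min": float(radii.min()),
            "max": float(radii.max()),
            "mean": float(radii.mean()),
        },
        "mask_voxels": mask.n_voxels,
        "mask_volume_mm3": mask.n_voxels * mask.voxel_volume_mm3,
    }
    return SegmentationResult(
        mask=mask, mesh=mesh, report=report,
        surface=surface, ray_grid=grid, costs=costs,
    )
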
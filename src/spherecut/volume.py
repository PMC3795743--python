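"""In-memory 3D image volume and binary mask with world geometry.

Voxel indices are 0-based with axis order (x, y, z); the center of voxel
(i, j, k) sits at ``origin + direction @ (spacing * (i, j, k))`` in world
millimetres, matching the NRRD/NIfTI header convention of the input file.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, ParameterError

__all__ = ["ImageVolume", "BinaryMask", "SeedPoint"]


def _validate_geometry(voxels, spacing, origin, direction, min_dim=2):
    if voxels.ndim != 3:
        raise ParameterError(f"expected a 3D grid, got ndim={voxels.ndim}")
    if min(voxels.shape) < min_dim:
        raise ParameterError(
            f"grid dimensions must be >= {min_dim} per axis, got {voxels.shape}"
        )
    if spacing.shape != (3,) or np.any(spacing <= 0):
        raise ParameterError(f"spacing must be 3 positive values, got {spacing}")
    if origin.shape != (3,):
        raise ParameterError("origin must be a 3-vector")
    if direction.shape != (3, 3) or not np.allclose(
        direction @ direction.T, np.eye(3), atol=1e-6
    ):
        raise ParameterError("direction must be a 3x3 orthonormal matrix")


@dataclass
class _Grid:
    """Shared geometry behaviour of volumes and masks."""

    voxels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    direction: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        self.spacing = np.asarray(self.spacing, dtype=np.float64)
        self.origin = np.asarray(self.origin, dtype=np.float64)
        self.direction = np.asarray(self.direction, dtype=np.float64)
        _validate_geometry(self.voxels, self.spacing, self.origin, self.direction)

    @property
    def shape(self) -> tuple:
        return self.voxels.shape

    def index_to_world(self, index) -> np.ndarray:
        """World position (mm) of a (possibly fractional) voxel index."""
        index = np.asarray(index, dtype=np.float64)
        return (index * self.spacing) @ self.direction.T + self.origin

    def world_to_index(self, position) -> np.ndarray:
        """Continuous voxel index of a world position (mm)."""
        position = np.asarray(position, dtype=np.float64)
        return ((position - self.origin) @ self.direction) / self.spacing

    def contains_world(self, position) -> bool:
        """Whether the position falls strictly inside the voxel lattice."""
        idx = self.world_to_index(position)
        return bool(
            np.all(idx >= 0) and np.all(idx <= np.asarray(self.shape) - 1)
        )

    def same_grid(self, other: "_Grid", atol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.direction, other.direction, atol=atol)
        )

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class ImageVolume(_Grid):
    """Scalar 3D image with spacing (mm/voxel), origin (mm) and direction."""

    def __post_init__(self):
        super().__post_init__()
        self.voxels = self.voxels.astype(np.float64, copy=False)


@dataclass
class BinaryMask(_Grid):
    """Boolean 3D mask sharing an :class:`ImageVolume`'s grid geometry."""

    def __post_init__(self):
        super().__post_init__()
        self.voxels = self.voxels.astype(bool, copy=False)

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.voxels))


@dataclass(frozen=True)
class SeedPoint:
    """A single user-chosen point inside the target object, world mm."""

    position: np.ndarray

    def __post_init__(self):
        object.__setattr__(
            self, "position", np.asarray(self.position, dtype=np.float64)
        )
        if self.position.shape != (3,):
            raise ParameterError("seed position must be a 3-vector")

    def require_inside(self, volume: ImageVolume) -> None:
        if not volume.contains_world(self.position):
            raise GeometryError(
                f"seed point {self.position.tolist()} lies outside the volume"
            )
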
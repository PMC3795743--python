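"""Synthetic sphere/ellipsoid phantoms with known ground truth.

A phantom is a hard-edged two-intensity volume — foreground inside an
analytic sphere or ellipsoid, background elsewhere — plus i.i.d. Gaussian
noise from a seeded generator, and the exact noise-free truth mask.  It
stands in for real scan data so that every pipeline stage can be tested
against an analytically known answer.  Gaussian (not Rician) noise and a
hard edge are deliberate simplifications; an optional one-voxel linear
partial-volume shell can soften the boundary to mimic scanner blur.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .volume import BinaryMask, ImageVolume

__all__ = ["PhantomSpec", "make_phantom"]


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one phantom volume.

    ``radius_mm`` is a scalar for a sphere or a 3-vector of semi-axes
    (mm) for an ellipsoid.  ``center_mm`` is in world coordinates with
    the volume's origin at zero and identity orientation.
    """

    shape: str  # "sphere" | "ellipsoid"
    dims: tuple
    spacing_mm: tuple
    center_mm: tuple
    radius_mm: tuple  # (r,) or (a, b, c)
    fg_intensity: float = 150.0
    bg_intensity: float = 50.0
    noise_sd: float = 0.0
    rng_seed: int = 0
    partial_volume: bool = False
    origin_mm: tuple = (0.0, 0.0, 0.0)

    def semi_axes(self) -> np.ndarray:
        r = np.atleast_1d(np.asarray(self.radius_mm, dtype=np.float64))
        if self.shape == "sphere":
            if r.size != 1:
                raise ParameterError("a sphere takes a single radius")
            return np.repeat(r, 3)
        if self.shape == "ellipsoid":
            if r.size != 3:
                raise ParameterError("an ellipsoid takes three semi-axes")
            return r
        raise ParameterError(f"unknown phantom shape {self.shape!r}")


def make_phantom(spec: PhantomSpec) -> tuple[ImageVolume, BinaryMask]:
    """Generate the noisy volume and its noise-free truth mask.

    Identical spec + seed gives bitwise-identical output.  The truth mask
    is the analytic inside test on voxel centers and never sees noise.
    """
    dims = np.asarray(spec.dims, dtype=np.int64)
    spacing = np.asarray(spec.spacing_mm, dtype=np.float64)
    origin = np.asarray(spec.origin_mm, dtype=np.float64)
    center = np.asarray(spec.center_mm, dtype=np.float64)
    axes = spec.semi_axes()

    if dims.shape != (3,) or np.any(dims < 2):
        raise ParameterError(f"dims must be three values >= 2, got {spec.dims}")
    if np.any(axes <= 0):
        raise ParameterError("radius/semi-axes must be positive")
    if spec.noise_sd < 0:
        raise ParameterError("noise_sd must be nonnegative")

    extent_lo = origin
    extent_hi = origin + spacing * (dims - 1)
    if np.any(center - axes < extent_lo) or np.any(center + axes > extent_hi):
        raise ParameterError(
            "object must lie fully inside the grid "
            f"(center {center.tolist()}, semi-axes {axes.tolist()})"
        )

    grids = np.meshgrid(
        origin[0] + spacing[0] * np.arange(dims[0]),
        origin[1] + spacing[1] * np.arange(dims[1]),
        origin[2] + spacing[2] * np.arange(dims[2]),
        indexing="ij",
    )
    # normalized squared radius: 1 on the surface
    s2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, axes))
    truth = s2 <= 1.0

    if spec.partial_volume:
        # approximate signed distance to the surface in voxel units
        s = np.sqrt(s2)
        d_mm = (s - 1.0) * float(axes.min())
        frac = np.clip(0.5 - d_mm / float(spacing.min()), 0.0, 1.0)
        voxels = spec.bg_intensity + (spec.fg_intensity - spec.bg_intensity) * frac
    else:
        voxels = np.where(truth, spec.fg_intensity, spec.bg_intensity).astype(
            np.float64
        )

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.rng_seed)
        voxels = voxels + rng.normal(0.0, spec.noise_sd, size=voxels.shape)

    direction = np.eye(3)
    volume = ImageVolume(voxels, spacing, origin, direction)
    mask = BinaryMask(truth, spacing.copy(), origin.copy(), direction.copy())
    return volume, mask
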
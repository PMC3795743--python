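"""Volume, mask and mesh file I/O.

Volumes and masks are read and written as NRRD or NIfTI-1 through
SimpleITK, which preserves spacing, origin and direction; the format is
chosen from the file extension (``.nrrd``, ``.nhdr``, ``.nii``,
``.nii.gz``).  Array axis order is converted between SimpleITK's
(z, y, x) memory layout and this package's (x, y, z) convention on the
way in and out, so world geometry is unchanged.  Masks are written as
unsigned 8-bit 0/1 with the source volume's header geometry.  Meshes go
out as binary STL (or PLY) in world millimetres via trimesh.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import trimesh

from .errors import FormatError
from .reconstruct import SurfaceMesh
from .volume import BinaryMask, ImageVolume

__all__ = [
    "read_volume",
    "read_mask",
    "write_volume",
    "write_mask",
    "write_mesh",
    "write_report",
]

_VOLUME_SUFFIXES = (".nrrd", ".nhdr", ".nii", ".nii.gz")


def _check_path(path: Path, for_reading: bool) -> Path:
    path = Path(path)
    name = path.name.lower()
    if not any(name.endswith(s) for s in _VOLUME_SUFFIXES):
        raise FormatError(
            f"unsupported volume format for {path}; expected one of {_VOLUME_SUFFIXES}"
        )
    if for_reading and not path.is_file():
        raise FormatError(f"no such file: {path}")
    return path


def _read_sitk(path: Path) -> sitk.Image:
    try:
        return sitk.ReadImage(str(path))
    except RuntimeError as exc:
        raise FormatError(f"could not read {path}: {exc}") from exc


def read_volume(path) -> ImageVolume:
    """Load a 3D NRRD or NIfTI-1 scalar volume as float."""
    path = _check_path(path, for_reading=True)
    img = _read_sitk(path)
    if img.GetDimension() != 3:
        raise FormatError(f"{path} is {img.GetDimension()}-D; expected a 3D volume")
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)  # (z,y,x) -> (x,y,z)
    return ImageVolume(
        arr.astype(np.float64),
        np.asarray(img.GetSpacing()),
        np.asarray(img.GetOrigin()),
        np.asarray(img.GetDirection()).reshape(3, 3),
    )


def read_mask(path) -> BinaryMask:
    """Load a mask volume; any nonzero voxel counts as foreground."""
    vol = read_volume(path)
    return BinaryMask(vol.voxels != 0, vol.spacing, vol.origin, vol.direction)


def _to_sitk(voxels: np.ndarray, grid) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(voxels.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in grid.spacing))
    img.SetOrigin(tuple(float(o) for o in grid.origin))
    img.SetDirection(tuple(float(d) for d in grid.direction.ravel()))
    return img


def write_volume(path, volume: ImageVolume) -> None:
    """Write a scalar volume as NRRD or NIfTI-1 (from the extension)."""
    path = _check_path(path, for_reading=False)
    sitk.WriteImage(_to_sitk(volume.voxels, volume), str(path))


def write_mask(path, mask: BinaryMask) -> None:
    """Write a mask as 0/1 unsigned 8-bit, grid geometry copied verbatim."""
    path = _check_path(path, for_reading=False)
    sitk.WriteImage(_to_sitk(mask.voxels.astype(np.uint8), mask), str(path))


def write_mesh(path, mesh: SurfaceMesh) -> None:
    """Write the cut surface as binary STL (or PLY), world millimetres."""
    path = Path(path)
    if path.suffix.lower() not in (".stl", ".ply"):
        raise FormatError(f"unsupported mesh format for {path}; use .stl or .ply")
    tm = trimesh.Trimesh(
        vertices=mesh.vertices, faces=mesh.triangles, process=False
    )
    tm.export(str(path))


def write_report(path, report: dict) -> None:
    """Write a run or evaluation report as indented JSON."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
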